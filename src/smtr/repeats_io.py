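"""Reading repeat catalogs and applying the preprocessing filters.

Tandem Repeats Finder (TRF) ``.dat`` tables are the expected catalog
format: per-chromosome ``Sequence:`` headers followed by whitespace-
separated rows (start, end, period size, copy number, consensus size,
percent matches, percent indels, score, A, C, G, T, entropy, consensus
pattern, repeat sequence; coordinates 1-based inclusive).

The preprocessing applied before estimation removes records with
unknown (N) bases, copy number below 2 and nonzero indel percentage
(the model has no insertions/deletions), and keeps a single record per
overlap cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatRecord:
    """One tandem repeat from a repeat-finder table (1-based inclusive)."""

    id: str
    chromosome: str
    start: int
    end: int
    d: int  # pattern (period) length
    copy_number: float
    indel_pct: float
    sequence: str
    score: float | None = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.id}: end < start")
        if self.d < 1:
            raise ValueError(f"{self.id}: pattern length must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "RepeatRecord") -> bool:
        """Any intersection of the two intervals on the same chromosome."""
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs in file order; wrapped lines are joined."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# column counts of a TRF data row: 13 numeric fields + consensus + sequence
_TRF_FIELDS = 15


def read_trf_table(path) -> list[RepeatRecord]:
    """Parse a Tandem Repeats Finder .dat table into RepeatRecords.

    Non-data lines (program banner, parameters, blank lines) are passed
    over; a row that looks like data but fails to parse is reported with
    its line number and skipped.
    """
    records: list[RepeatRecord] = []
    chromosome = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                chromosome = line.split(None, 1)[1].split()[0]
                continue
            fields = line.split()
            if not fields[0].lstrip("-").isdigit():
                continue  # banner / parameter lines
            try:
                if len(fields) != _TRF_FIELDS:
                    raise ValueError(f"expected {_TRF_FIELDS} fields, got {len(fields)}")
                start, end = int(fields[0]), int(fields[1])
                d = int(fields[2])
                copy_number = float(fields[3])
                indel_pct = float(fields[6])
                score = float(fields[7])
                sequence = fields[14].upper()
                records.append(
                    RepeatRecord(
                        id=f"{chromosome}:{start}-{end}",
                        chromosome=chromosome,
                        start=start,
                        end=end,
                        d=d,
                        copy_number=copy_number,
                        indel_pct=indel_pct,
                        sequence=sequence,
                        score=score,
                    )
                )
            except (ValueError, IndexError) as exc:
                logger.warning("%s line %d: unparseable row skipped (%s)",
                               path, lineno, exc)
    return records


def preprocess_repeats(records) -> list[RepeatRecord]:
    """Apply the catalog filters used before estimation.

    Drops records containing N, with copy number < 2, or with nonzero
    indel percentage; then keeps exactly one record per cluster of
    overlapping intervals (highest score, then longest, then earliest
    start). Removal counts per rule are logged.
    """
    records = list(records)
    no_n = [r for r in records if "N" not in r.sequence.upper()]
    enough_copies = [r for r in no_n if r.copy_number >= 2.0]
    no_indels = [r for r in enough_copies if r.indel_pct == 0.0]
    logger.info(
        "preprocess: %d with N bases, %d with copy number < 2, "
        "%d with nonzero indel pct",
        len(records) - len(no_n),
        len(no_n) - len(enough_copies),
        len(enough_copies) - len(no_indels),
    )

    kept: list[RepeatRecord] = []
    removed_overlap = 0
    by_chrom: dict[str, list[RepeatRecord]] = {}
    for r in no_indels:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom_records in by_chrom.values():
        chrom_records.sort(key=lambda r: (r.start, r.end))
        cluster: list[RepeatRecord] = []
        cluster_end = None
        for r in chrom_records:
            if cluster and r.start <= cluster_end:
                cluster.append(r)
                cluster_end = max(cluster_end, r.end)
            else:
                if cluster:
                    kept.append(_best(cluster))
                    removed_overlap += len(cluster) - 1
                cluster = [r]
                cluster_end = r.end
        if cluster:
            kept.append(_best(cluster))
            removed_overlap += len(cluster) - 1
    logger.info("preprocess: %d removed as overlapping", removed_overlap)
    kept.sort(key=lambda r: (r.chromosome, r.start))
    return kept


def _best(cluster: list[RepeatRecord]) -> RepeatRecord:
    """Overlap tie-break: highest score, then longest, then earliest start."""
    return max(
        cluster,
        key=lambda r: (
            r.score if r.score is not None else float("-inf"),
            r.length,
            -r.start,
        ),
    )
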