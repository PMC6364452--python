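import numpy as np
import pytest

# Handcrafted TRF .dat dialect fixture: banner lines, two chromosomes,
# rows covering every preprocessing rule (N bases, low copy number,
# nonzero indel pct, overlapping pair). Columns: start end period
# copies consensus pctmatch pctindel score A C G T entropy consensus seq.
TRF_FIXTURE = """\
Tandem Repeats Finder Program written by some author

Version 4.09
Sequence: chr1 test assembly

Parameters: 2 7 7 80 10 50 500

101 120 4 5.0 4 100 0 40 25 25 25 25 2.0 ACGT ACGTACGTACGTACGTACGT
150 250 10 10.1 10 95 2.5 88 25 25 25 25 2.0 ACGTACGTAC ACGTACGTACACGTACGTACACGTACGTACACGTACGTACACGTACGTACACGTACGTACACGTACGTACACGTACGTACACGTACGTACACGTACGTACA
300 311 6 2.0 6 100 0 24 25 25 25 25 2.0 ACGTAN ACGTANACGTAN
400 405 3 2.0 3 100 0 12 25 25 25 25 2.0 ACG ACGACG
404 415 3 4.0 3 100 0 24 25 25 25 25 2.0 ACG ACGACGACGACG
Sequence: chr2
500 505 3 1.9 3 100 0 11 25 25 25 25 2.0 ACG ACGACG
600 611 4 3.0 4 100 0 24 25 25 25 25 2.0 ACGT ACGTACGTACGT
"""


@pytest.fixture
def trf_path(tmp_path):
    p = tmp_path / "repeats.dat"
    p.write_text(TRF_FIXTURE)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
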