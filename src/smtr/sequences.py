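"""Circular DNA sequences and their autocorrelation profiles.

The evolving object in the tandem-repeat model is a *circular* sequence:
indices are taken modulo the length, which removes boundary effects from
the analysis. The statistic that summarises its repetitiveness is the
normalized circular autocorrelation

    rho^r = (1/L) * sum_i [ s_i == s_{i+r mod L} ],   r = 0 .. m-1,

i.e. the fraction of positions whose symbol matches the symbol ``r``
places downstream. rho^0 == 1 always; for an i.i.d.-uniform sequence over
the 4-letter alphabet the expected value at any other lag is 1/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE.update({c.lower(): i for i, c in enumerate(ALPHABET)})


class CircularSequence:
    """A circular sequence over {A, C, G, T} with modular indexing.

    Accepts a string (case-insensitive) or an integer code array
    (A,C,G,T -> 0..3). Symbols outside the alphabet are rejected rather
    than silently mapped; inputs containing N must be filtered upstream.
    """

    __slots__ = ("codes",)

    def __init__(self, symbols):
        if isinstance(symbols, CircularSequence):
            codes = symbols.codes.copy()
        elif isinstance(symbols, str):
            try:
                codes = np.fromiter(
                    (_CODE[c] for c in symbols), dtype=np.int8, count=len(symbols)
                )
            except KeyError as exc:
                raise ValueError(
                    f"symbol {exc.args[0]!r} is not one of A,C,G,T"
                ) from None
        else:
            codes = np.asarray(symbols, dtype=np.int8)
            if codes.ndim != 1:
                raise ValueError("code array must be one-dimensional")
            if codes.size and (codes.min() < 0 or codes.max() > 3):
                raise ValueError("codes must lie in 0..3")
        if codes.size == 0:
            raise ValueError("circular sequence must have length >= 1")
        self.codes = codes

    @classmethod
    def from_codes(cls, codes) -> "CircularSequence":
        return cls(np.asarray(codes, dtype=np.int8))

    def __len__(self) -> int:
        return int(self.codes.size)

    def __getitem__(self, i: int) -> str:
        return ALPHABET[self.codes[i % len(self)]]

    def __str__(self) -> str:
        return "".join(ALPHABET[c] for c in self.codes)

    def __repr__(self) -> str:
        s = str(self)
        if len(s) > 40:
            s = s[:37] + "..."
        return f"CircularSequence({s!r}, L={len(self)})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, CircularSequence):
            return NotImplemented
        return np.array_equal(self.codes, other.codes)

    def rotate(self, k: int) -> "CircularSequence":
        """Rotation by ``k`` positions; represents the same circular object."""
        return CircularSequence(np.roll(self.codes, -k))

    def reverse_complement(self) -> "CircularSequence":
        # A<->T (0<->3), C<->G (1<->2): complement code is 3 - code.
        return CircularSequence((3 - self.codes[::-1]).astype(np.int8))


@dataclass(frozen=True)
class AutocorrelationProfile:
    """Normalized circular autocorrelation rho at lags 0..m-1.

    ``L`` is the length of the source sequence (``None`` for analytic
    profiles such as stationary limits, which have no generating
    sequence). Negative lags resolve by the circular symmetry
    rho^{-k} = rho^{k}.
    """

    rho: np.ndarray
    L: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))

    @property
    def m(self) -> int:
        return int(self.rho.size)

    def at(self, lag: int) -> float:
        """rho at a (possibly negative) lag, via rho^{-k} == rho^{k}."""
        lag = abs(int(lag))
        if lag >= self.m:
            raise ValueError(
                f"lag {lag} not available (profile holds lags 0..{self.m - 1})"
            )
        return float(self.rho[lag])

    def __getitem__(self, lag: int) -> float:
        return self.at(lag)


def circular_autocorrelation(
    s: CircularSequence | str, m: int | None = None
) -> AutocorrelationProfile:
    """Normalized circular autocorrelation of ``s`` at lags 0..m-1.

    The default ``m = floor(L/2) + 1`` keeps every reported lag an average
    of at least L/2 independent position pairs; lags beyond L/2 mirror the
    first half (rho^r == rho^{L-r}).

    Computed as a sum of per-letter circular cross-correlations via FFT
    (O(L log L)); counts are integers, so the FFT result is rounded back
    to exact values.
    """
    if isinstance(s, str):
        s = CircularSequence(s)
    L = len(s)
    if m is None:
        m = L // 2 + 1
    if not 1 <= m <= L:
        raise ValueError(f"need 1 <= m <= L, got m={m}, L={L}")
    counts = np.zeros(L)
    for c in range(4):
        x = (s.codes == c).astype(float)
        f = np.fft.rfft(x)
        counts += np.fft.irfft(f * np.conj(f), n=L)
    counts = np.rint(counts)
    rho = counts[:m] / L
    return AutocorrelationProfile(rho=rho, L=L)
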