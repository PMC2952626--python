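"""Cumulative composition curves and the windowless z' curve.

The composition curve stores cumulative A/C/G/T/N counts so that base
frequencies, GC content and disparity series over any interval are O(1)
or O(interval) lookups with no windowing.  The z' curve is the
AT-vs-GC disparity component of the Z curve,

    z_i = (#A + #T) - (#C + #G)   over the first i bases of an interval,

with the straight line through the interval endpoints removed.  Its
local slope encodes GC content: GC-rich stretches run downhill,
AT-rich stretches uphill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lhgr.errors import DegenerateIntervalError


@dataclass
class ZPrimeSeries:
    """Endpoint-detrended disparity series over an interval.

    ``values[i]`` is the detrended disparity after the first ``i`` bases
    of the interval; ``values[0] == values[-1] == 0`` by construction.
    ``slope_removed`` is the removed linear trend (disparity per base).
    """

    values: np.ndarray
    slope_removed: float


class CompositionCurve:
    """Cumulative nucleotide counts along a chromosome.

    Index ``i`` of each array holds the count over the first ``i``
    residues (index 0 is zero), so counts over ``[start, end)`` are
    differences of two entries.
    """

    def __init__(self, chrom_id: str, residues: str):
        self.chrom_id = chrom_id
        arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
        self.n = len(arr)
        self.cum = {}
        for base in "ACGTN":
            mask = (arr == ord(base)).astype(np.int64)
            self.cum[base] = np.concatenate(([0], np.cumsum(mask)))
        counted = sum(self.cum[b][-1] for b in "ACGTN")
        if counted != self.n:
            raise ValueError(
                f"{chrom_id}: sequence contains characters outside A/C/G/T/N"
            )

    @property
    def cumA(self) -> np.ndarray:  # noqa: N802 - field names mirror the bases
        return self.cum["A"]

    @property
    def cumC(self) -> np.ndarray:  # noqa: N802
        return self.cum["C"]

    @property
    def cumG(self) -> np.ndarray:  # noqa: N802
        return self.cum["G"]

    @property
    def cumT(self) -> np.ndarray:  # noqa: N802
        return self.cum["T"]

    @property
    def cumN(self) -> np.ndarray:  # noqa: N802
        return self.cum["N"]

    def _check_interval(self, start: int, end: int) -> None:
        if not (0 <= start < end <= self.n):
            raise ValueError(
                f"invalid interval [{start}, {end}) on curve of length {self.n}"
            )

    def counts(self, start: int, end: int) -> tuple[int, int, int, int, int]:
        """(A, C, G, T, N) counts over ``[start, end)``."""
        self._check_interval(start, end)
        return tuple(int(self.cum[b][end] - self.cum[b][start]) for b in "ACGTN")

    def frequencies(self, start: int, end: int) -> tuple[float, float, float, float]:
        """Base frequencies over non-N residues of ``[start, end)``."""
        a, c, g, t, _ = self.counts(start, end)
        total = a + c + g + t
        if total == 0:
            raise DegenerateIntervalError(
                f"[{start}, {end}) contains no non-N bases"
            )
        return a / total, c / total, g / total, t / total


def build_curve(seq) -> CompositionCurve:
    """Build a :class:`CompositionCurve` from a sequence object or string."""
    if isinstance(seq, str):
        return CompositionCurve("seq", seq)
    return CompositionCurve(seq.chrom_id, seq.residues)


def gc_content(curve: CompositionCurve, start: int, end: int) -> float:
    """GC proportion over ``[start, end)``, N residues excluded.

    Raises :class:`DegenerateIntervalError` for an all-N interval.
    """
    a, c, g, t, _ = curve.counts(start, end)
    total = a + c + g + t
    if total == 0:
        raise DegenerateIntervalError(f"[{start}, {end}) contains no non-N bases")
    return (g + c) / total


def z_series(curve: CompositionCurve, start: int, end: int) -> np.ndarray:
    """Raw disparity series (#A+#T)-(#C+#G) measured from ``start``.

    Length ``end - start + 1``; entry 0 is 0.  N residues contribute
    nothing (the series is flat across them).
    """
    curve._check_interval(start, end)
    sl = slice(start, end + 1)
    at = (curve.cumA[sl] - curve.cumA[start]) + (curve.cumT[sl] - curve.cumT[start])
    gc = (curve.cumC[sl] - curve.cumC[start]) + (curve.cumG[sl] - curve.cumG[start])
    return (at - gc).astype(np.float64)


def z_prime(curve: CompositionCurve, start: int, end: int) -> ZPrimeSeries:
    """Endpoint-detrended z' series over ``[start, end)``.

    The linear trend through the interval's endpoints is removed, so a
    segment of constant composition maps to a (noisy) horizontal run and
    composition boundaries appear as slope breaks.  A GC-rich region
    relative to the trend is a downward excursion.
    """
    if end - start < 2:
        raise ValueError("z_prime requires an interval of at least 2 bp")
    z = z_series(curve, start, end)
    m = end - start
    slope = z[-1] / m
    values = z - slope * np.arange(m + 1, dtype=np.float64)
    return ZPrimeSeries(values=values, slope_removed=float(slope))


def write_z_prime_tsv(series: ZPrimeSeries, path, stride: int = 1000) -> None:
    """Export z' values at a fixed stride for plotting (columns: position, z_prime)."""
    import pandas as pd

    idx = np.arange(0, len(series.values), stride)
    pd.DataFrame({"position": idx, "z_prime": series.values[idx]}).to_csv(
        path, sep="\t", index=False
    )
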