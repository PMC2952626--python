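"""Recursive divergence-maximising segmentation into LHGRs.

Each gap-delimited contig is partitioned by recursive binary splitting.
A candidate split point divides an interval into left and right halves
with base frequencies (a, c, g, t); the genome order index

    S = a^2 + c^2 + g^2 + t^2

summarises each half's composition, and the quadratic divergence of a
split is the weighted between-half gain

    delta = w * [ (n_l/n) S_left + (n_r/n) S_right - S_whole ],

which is non-negative by convexity and zero only when both halves share
the whole interval's composition.  The split maximising delta is
accepted when the halting statistic n * delta reaches the threshold t0
and both children are at least l_min long; otherwise the interval is
emitted as one segment.  n counts non-N bases; the halting statistic is
scaled by n because delta itself shrinks as 1/n under homogeneity, so a
fixed threshold is meaningful across scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from lhgr.errors import DegenerateIntervalError
from lhgr.io import GenomeSequence, split_into_contigs
from lhgr.zcurve import CompositionCurve, build_curve

# candidate split positions are evaluated in blocks to bound peak memory
# on chromosome-scale contigs
_BLOCK = 1 << 21


@dataclass(frozen=True)
class SegmentationParams:
    """Stopping controls of the recursive segmentation.

    t0:    halting threshold compared against n * delta (default 100).
    l_min: minimum segment length in bp, counted on coordinates
           (retained short gaps included; default 300,000).
    w:     weight coefficient multiplying the divergence (default 1).
    stride: spacing of candidate split positions in bp (default 1,
           i.e. every base is a candidate).
    """

    t0: float = 100.0
    l_min: int = 300_000
    w: float = 1.0
    stride: int = 1

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError(f"t0 must be positive, got {self.t0}")
        if self.l_min < 2:
            raise ValueError(f"l_min must be >= 2, got {self.l_min}")
        if self.w <= 0:
            raise ValueError(f"w must be positive, got {self.w}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")


@dataclass(frozen=True)
class SplitCandidate:
    """The best split of an interval: position, raw divergence, halting statistic."""

    position: int
    delta: float
    halting_stat: float


def genome_order_index(a: float, c: float, g: float, t: float) -> float:
    """Genome order index S = a^2 + c^2 + g^2 + t^2 of base frequencies.

    S is 0.25 for the uniform composition and 1 for a single-letter
    sequence.  The frequencies must be non-negative and sum to 1.
    """
    for name, x in zip("acgt", (a, c, g, t)):
        if x < 0:
            raise ValueError(f"frequency {name} is negative: {x}")
    if abs(a + c + g + t - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {a + c + g + t}")
    return a * a + c * c + g * g + t * t


def quadratic_divergence(
    curve: CompositionCurve, start: int, end: int, i: int, w: float = 1.0
) -> SplitCandidate:
    """Quadratic divergence of splitting ``[start, end)`` at position ``i``.

    ``i`` is a 0-based boundary: left half ``[start, i)``, right half
    ``[i, end)``.  Frequencies are over non-N bases; a half with no
    non-N bases is a degenerate split.
    """
    if not start < i < end:
        raise ValueError(f"split {i} outside the open interval ({start}, {end})")
    s_left = genome_order_index(*curve.frequencies(start, i))
    s_right = genome_order_index(*curve.frequencies(i, end))
    s_whole = genome_order_index(*curve.frequencies(start, end))
    nl = sum(curve.counts(start, i)[:4])
    nr = sum(curve.counts(i, end)[:4])
    n = nl + nr
    delta = w * ((nl / n) * s_left + (nr / n) * s_right - s_whole)
    delta = max(delta, 0.0)  # clip float round-off on homogeneous input
    return SplitCandidate(position=i, delta=delta, halting_stat=n * delta)


def _divergence_profile(
    curve: CompositionCurve, start: int, end: int, positions: np.ndarray, w: float
) -> np.ndarray:
    """delta at each candidate position (NaN where a side has no non-N base)."""
    counts_whole = np.array(curve.counts(start, end)[:4], dtype=np.float64)
    n = counts_whole.sum()
    if n == 0:
        raise DegenerateIntervalError(f"[{start}, {end}) contains no non-N bases")
    s_whole = float(np.square(counts_whole / n).sum())

    contiguous = len(positions) > 1 and positions[1] - positions[0] == 1
    out = np.empty(len(positions), dtype=np.float64)
    for lo in range(0, len(positions), _BLOCK):
        idx = positions[lo : lo + _BLOCK]
        ssq_l = np.zeros(len(idx))
        ssq_r = np.zeros(len(idx))
        nl = np.zeros(len(idx))
        # a slice view avoids fancy indexing on the stride-1 hot path
        sl = slice(int(idx[0]), int(idx[-1]) + 1) if contiguous else idx
        for b, whole in zip("ACGT", counts_whole):
            cl = (curve.cum[b][sl] - curve.cum[b][start]).astype(np.float64)
            ssq_l += cl * cl
            cr = whole - cl
            ssq_r += cr * cr
            nl += cl
        nr = n - nl
        with np.errstate(divide="ignore", invalid="ignore"):
            block = w * ((ssq_l / nl + ssq_r / nr) / n - s_whole)
        block[(nl == 0) | (nr == 0)] = np.nan
        out[lo : lo + _BLOCK] = block
    return np.maximum(out, 0.0, out=out, where=~np.isnan(out))


def best_split(
    curve: CompositionCurve,
    start: int,
    end: int,
    params: SegmentationParams,
) -> SplitCandidate | None:
    """Argmax-divergence split of ``[start, end)`` respecting ``l_min``.

    Candidates run over ``[start + l_min, end - l_min]`` at ``stride``
    spacing; ties in delta are broken by the leftmost position.  Returns
    None when the candidate window is empty (interval shorter than
    ``2 * l_min``) or every candidate is degenerate.
    """
    lo, hi = start + params.l_min, end - params.l_min
    if hi < lo:
        return None
    positions = np.arange(lo, hi + 1, params.stride, dtype=np.int64)
    deltas = _divergence_profile(curve, start, end, positions, params.w)
    if np.all(np.isnan(deltas)):
        return None
    best = int(np.nanargmax(deltas))  # nanargmax returns the first maximum
    n = sum(curve.counts(start, end)[:4])
    delta = float(deltas[best])
    return SplitCandidate(
        position=int(positions[best]), delta=delta, halting_stat=n * delta
    )


def segment_contig(
    curve: CompositionCurve,
    start: int,
    end: int,
    params: SegmentationParams,
) -> list[tuple[int, int]]:
    """Recursively partition ``[start, end)`` into LHGR intervals.

    A split is accepted when its halting statistic reaches ``t0`` (the
    l_min constraint is built into the candidate window).  The returned
    intervals are sorted, adjacent and tile the input exactly.
    """
    segments: list[tuple[int, int]] = []
    stack = [(start, end)]
    while stack:
        s, e = stack.pop()
        cand = best_split(curve, s, e, params)
        if cand is not None and cand.halting_stat >= params.t0:
            # push right first so the left child is processed next:
            # emission order stays left-to-right
            stack.append((cand.position, e))
            stack.append((s, cand.position))
        else:
            segments.append((s, e))
    return segments


class RecursiveSegmenter(BaseEstimator):
    """Divergence-maximising change-point segmenter for chromosome sequences.

    Splits each gap-delimited contig of a chromosome into long
    homogeneous genome regions by recursive binary segmentation on the
    genome order index (see the module docstring for the criterion).

    Parameters
    ----------
    t0 : float, default 100
        Halting threshold on the scaled divergence ``n * delta``.
    l_min : int, default 300000
        Minimum segment length (bp).
    w : float, default 1
        Weight coefficient of the divergence.
    stride : int, default 1
        Candidate split spacing (bp); 1 evaluates every base.
    gap_fraction : float, default 0.01
        N-runs at least this fraction of the chromosome split it into
        contigs; shorter N-runs are retained but excluded from all base
        counts.

    Attributes
    ----------
    curve_ : CompositionCurve
        Cumulative composition profile of the fitted chromosome.
    contigs_ : list of (start, end)
        Gap-delimited contig intervals, 0-based half-open chromosomal.
    segments_ : list of (start, end)
        LHGR intervals across all contigs, sorted.
    segments_by_contig_ : list of list of (start, end)
        The same intervals grouped by contig (neighbour statistics such
        as delta-GC are only defined within a contig).
    breakpoints_ : list of int
        Accepted internal split positions.
    gap_track_ : GapTrack
        All N-runs of the chromosome.
    short_contigs_ : list of (start, end)
        Contigs shorter than ``l_min``, emitted whole and flagged.

    Examples
    --------
    >>> seg = RecursiveSegmenter(t0=50, l_min=1000)
    >>> seg.fit("AT" * 2000 + "GC" * 2000).segments_
    [(0, 4000), (4000, 8000)]
    """

    def __init__(
        self,
        t0: float = 100.0,
        l_min: int = 300_000,
        w: float = 1.0,
        stride: int = 1,
        gap_fraction: float = 0.01,
    ):
        self.t0 = t0
        self.l_min = l_min
        self.w = w
        self.stride = stride
        self.gap_fraction = gap_fraction

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            t0=self.t0, l_min=self.l_min, w=self.w, stride=self.stride
        )

    def fit(self, X, y=None):
        """Segment one chromosome.

        Parameters
        ----------
        X : GenomeSequence or str
            Normalized chromosome sequence (A/C/G/T/N).
        y : ignored
            Present for scikit-learn API compatibility.
        """
        params = self._params()
        seq = X if isinstance(X, GenomeSequence) else GenomeSequence("seq", X)
        self.curve_ = build_curve(seq)
        self.gap_track_, contigs = split_into_contigs(seq, self.gap_fraction)
        self.contigs_ = [(c.offset, c.end) for c in contigs]
        self.segments_by_contig_ = []
        self.short_contigs_ = []
        self.breakpoints_ = []
        for cs, ce in self.contigs_:
            segs = segment_contig(self.curve_, cs, ce, params)
            if ce - cs < params.l_min:
                self.short_contigs_.append((cs, ce))
            self.segments_by_contig_.append(segs)
            self.breakpoints_.extend(e for _, e in segs[:-1])
        self.segments_ = [s for segs in self.segments_by_contig_ for s in segs]
        return self
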