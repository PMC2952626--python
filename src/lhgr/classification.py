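"""Segment annotation: GC family, AT/GC type, homogeneity index, isochore status.

Family boundaries follow Bernardi's isochore families on GC percent:
L1 < 37, L2 37-41, H1 41-46, H2 46-53, H3 > 53 (bins lower-inclusive).

The homogeneity index h of a segment is the ratio of residual variances
of the raw AT-GC disparity series after least-squares linear detrending,
segment over host chromosome:

    h = s2(segment) / s2(chromosome),

so h = 1 for the chromosome itself, h << 1 for a segment whose
composition is much more constant than its host, and h > 1 for a
segment that is locally the most heterogeneous part.  Segments with
h below the cutoff (default 0.2, the empirical bound separating
isochores from isochore-like regions) are isochores.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from lhgr.errors import DegenerateIntervalError
from lhgr.zcurve import CompositionCurve, gc_content, z_series

FAMILY_BOUNDARIES: tuple[float, ...] = (37.0, 41.0, 46.0, 53.0)
FAMILY_LABELS: tuple[str, ...] = ("L1", "L2", "H1", "H2", "H3")

DEFAULT_H_CUT = 0.2


def assign_family(
    gc: float, boundaries: Sequence[float] = FAMILY_BOUNDARIES
) -> str:
    """Map a GC percentage to its isochore family (lower-inclusive bins)."""
    if not 0 <= gc <= 100:
        raise ValueError(f"GC percent out of range: {gc}")
    return FAMILY_LABELS[int(np.searchsorted(boundaries, gc, side="right"))]


def assign_gc_type(segment_gc: float, chrom_gc: float) -> str:
    """AT-LHGR or GC-LHGR relative to the chromosome's mean GC (ties -> AT)."""
    for x in (segment_gc, chrom_gc):
        if not 0 <= x <= 100:
            raise ValueError(f"GC percent out of range: {x}")
    return "GC-LHGR" if segment_gc > chrom_gc else "AT-LHGR"


def _residual_variance(curve: CompositionCurve, start: int, end: int) -> float:
    """Mean squared residual of the raw z series about its least-squares line."""
    if end - start < 2:
        raise ValueError("interval must span at least 2 bp")
    z = z_series(curve, start, end)
    m = len(z)
    x = np.arange(m, dtype=np.float64)
    x -= x.mean()
    zc = z - z.mean()
    denom = float(x @ x)
    slope = float(x @ zc) / denom
    resid = zc - slope * x
    return float(resid @ resid) / m


def homogeneity_index(
    curve: CompositionCurve,
    segment: tuple[int, int],
    chromosome: tuple[int, int] | None = None,
) -> float:
    """Homogeneity index h of a segment within its host chromosome.

    Both intervals are 0-based half-open.  ``chromosome`` defaults to
    the full curve.  Raises for a constant-disparity chromosome (zero
    reference variance), which cannot arise on real sequence data.
    """
    cs, ce = chromosome if chromosome is not None else (0, curve.n)
    ss, se = segment
    if not (cs <= ss < se <= ce):
        raise ValueError(f"segment {segment} not inside chromosome {(cs, ce)}")
    s2_chrom = _residual_variance(curve, cs, ce)
    if s2_chrom == 0.0:
        raise DegenerateIntervalError(
            "host chromosome has zero disparity variance; h is undefined"
        )
    return _residual_variance(curve, ss, se) / s2_chrom


def is_isochore(h: float, h_cut: float = DEFAULT_H_CUT) -> bool:
    """Isochore rule: h strictly below the cutoff (default 0.2)."""
    if h < 0:
        raise ValueError(f"h must be non-negative, got {h}")
    return h < h_cut


def delta_gc(gc_values: Sequence[float]) -> list[float]:
    """Unsigned GC differences between adjacent segments of one contig.

    Entry i is |gc_i - gc_{i+1}|; the list is one shorter than the
    input (empty for a single segment).
    """
    arr = np.asarray(gc_values, dtype=np.float64)
    return np.abs(np.diff(arr)).tolist()


def classify_segments(
    curve: CompositionCurve,
    segments_by_contig: Sequence[Sequence[tuple[int, int]]],
    h_cut: float = DEFAULT_H_CUT,
    boundaries: Sequence[float] = FAMILY_BOUNDARIES,
) -> pd.DataFrame:
    """Annotate segmentation output as a 1-based inclusive segment table.

    Segments must be grouped by contig: delta-GC is only attached to
    pairs adjacent in sequence, never across a splitting gap.  Columns:
    chrom, start, stop, length, gc (%), family, gc_type, h,
    klass (isochore / isochore-like), delta_gc (NaN on the last segment
    of each contig).
    """
    chrom_gc = gc_content(curve, 0, curve.n) * 100.0
    s2_chrom = _residual_variance(curve, 0, curve.n)
    if s2_chrom == 0.0:
        raise DegenerateIntervalError(
            "host chromosome has zero disparity variance; h is undefined"
        )
    rows = []
    for contig_segs in segments_by_contig:
        gcs = [gc_content(curve, s, e) * 100.0 for s, e in contig_segs]
        dgc = delta_gc(gcs) + [np.nan]
        for (s, e), gc, d in zip(contig_segs, gcs, dgc):
            h = _residual_variance(curve, s, e) / s2_chrom
            rows.append(
                {
                    "chrom": curve.chrom_id,
                    "start": s + 1,
                    "stop": e,
                    "length": e - s,
                    "gc": gc,
                    "family": assign_family(gc, boundaries),
                    "gc_type": assign_gc_type(gc, chrom_gc),
                    "h": h,
                    "klass": "isochore" if is_isochore(h, h_cut) else "isochore-like",
                    "delta_gc": d,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "stop",
            "length",
            "gc",
            "family",
            "gc_type",
            "h",
            "klass",
            "delta_gc",
        ],
    )
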