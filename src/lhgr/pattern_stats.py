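"""Pattern-level summaries of an LHGR map.

Per-family relative amounts, mean GC and mean size; count histograms in
0.5%-GC bins; size histograms in 0.2-Mb bins; delta-GC distribution
summaries; and the (t0, l_min) parameter sweep scored by the per-family
standard deviation of segment GC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from lhgr.classification import FAMILY_LABELS
from lhgr.segmentation import SegmentationParams, segment_contig
from lhgr.zcurve import CompositionCurve, gc_content


@dataclass
class FamilySummary:
    """Per-family pattern summary of a segment table.

    ``table`` is indexed by family with columns count, relative_amount
    (percent), mean_gc (percent), mean_size_mb.  ``count_histogram``
    bins segment counts by GC (left-inclusive bins of ``gc_bin_width``
    percent); ``size_histogram`` bins segment counts by length
    (left-inclusive bins of ``size_bin_mb`` Mb), both per family.
    """

    table: pd.DataFrame
    count_histogram: pd.DataFrame
    size_histogram: pd.DataFrame
    gc_bin_width: float
    size_bin_mb: float
    weight: str


def family_summary(
    segments: pd.DataFrame,
    weight: str = "count",
    gc_bin_width: float = 0.5,
    size_bin_mb: float = 0.2,
) -> FamilySummary:
    """Summarise a classified segment table per GC family.

    ``weight='count'`` reports relative amounts as percentages of the
    number of segments; ``weight='bp'`` weights by segment length.
    """
    if segments.empty:
        raise ValueError("cannot summarise an empty segment table")
    if weight not in ("count", "bp"):
        raise ValueError(f"weight must be 'count' or 'bp', got {weight!r}")
    fam = pd.Categorical(segments["family"], categories=list(FAMILY_LABELS))
    g = segments.groupby(fam, observed=False)
    counts = g.size()
    if weight == "count":
        rel = 100.0 * counts / counts.sum()
    else:
        bp = g["length"].sum()
        rel = 100.0 * bp / bp.sum()
    table = pd.DataFrame(
        {
            "count": counts,
            "relative_amount": rel,
            "mean_gc": g["gc"].mean(),
            "mean_size_mb": g["length"].mean() / 1e6,
        }
    )
    table.index.name = "family"

    gc_edges = np.arange(0.0, 100.0 + gc_bin_width, gc_bin_width)
    size_mb = segments["length"].to_numpy() / 1e6
    size_edges = np.arange(0.0, size_mb.max() + 2 * size_bin_mb, size_bin_mb)
    count_rows, size_rows = {}, {}
    for label in FAMILY_LABELS:
        sel = segments["family"] == label
        count_rows[label], _ = np.histogram(
            segments.loc[sel, "gc"], bins=gc_edges
        )
        size_rows[label], _ = np.histogram(size_mb[sel.to_numpy()], bins=size_edges)
    count_hist = pd.DataFrame(count_rows, index=pd.Index(gc_edges[:-1], name="gc_bin"))
    size_hist = pd.DataFrame(
        size_rows, index=pd.Index(size_edges[:-1].round(6), name="size_bin_mb")
    )
    # drop all-zero leading/trailing rows of the GC histogram for readability
    nz = count_hist.sum(axis=1).to_numpy().nonzero()[0]
    count_hist = count_hist.iloc[nz.min() : nz.max() + 1]
    return FamilySummary(
        table=table,
        count_histogram=count_hist,
        size_histogram=size_hist,
        gc_bin_width=gc_bin_width,
        size_bin_mb=size_bin_mb,
        weight=weight,
    )


def delta_gc_summary(segments: pd.DataFrame) -> pd.DataFrame:
    """Mean and median of unsigned neighbour delta-GC, per family and overall."""
    d = segments.dropna(subset=["delta_gc"])
    rows = []
    for label in FAMILY_LABELS:
        vals = d.loc[d["family"] == label, "delta_gc"]
        if len(vals):
            rows.append(
                {"family": label, "n": len(vals), "mean": vals.mean(), "median": vals.median()}
            )
    rows.append(
        {"family": "all", "n": len(d), "mean": d["delta_gc"].mean(), "median": d["delta_gc"].median()}
    )
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Grid of per-family GC standard deviations over (t0, l_min).

    ``grid`` has one row per cell with columns t0, l_min, n_segments,
    sd_<family> for each family (NaN where the family is empty) and
    mean_sd, the unweighted mean of the non-missing per-family SDs.
    ``selected`` is the (t0, l_min) pair minimising mean_sd; ties and
    all-NaN cells resolve to the earliest cell in grid order.
    """

    grid: pd.DataFrame
    selected: tuple[float, int]


def parameter_sweep(
    curve: CompositionCurve,
    contigs: Sequence[tuple[int, int]],
    t0_grid: Sequence[float],
    lmin_grid: Sequence[int],
    w: float = 1.0,
    stride: int = 1,
) -> SweepResult:
    """Segment the contigs under every (t0, l_min) combination.

    For each cell the contigs are re-segmented, segments classified into
    GC families, and the standard deviation of member-segment GC
    computed per family.  The selected cell minimises the mean of the
    per-family SDs — a quantitative stand-in for picking the settings
    where the per-family SD curves dip.
    """
    from lhgr.classification import assign_family

    rows = []
    for t0 in t0_grid:
        for l_min in lmin_grid:
            params = SegmentationParams(t0=t0, l_min=l_min, w=w, stride=stride)
            gcs: list[float] = []
            fams: list[str] = []
            n_seg = 0
            for cs, ce in contigs:
                for s, e in segment_contig(curve, cs, ce, params):
                    gc = gc_content(curve, s, e) * 100.0
                    gcs.append(gc)
                    fams.append(assign_family(gc))
                    n_seg += 1
            df = pd.DataFrame({"gc": gcs, "family": fams})
            row: dict = {"t0": t0, "l_min": l_min, "n_segments": n_seg}
            sds = []
            for label in FAMILY_LABELS:
                vals = df.loc[df["family"] == label, "gc"]
                sd = float(vals.std(ddof=1)) if len(vals) >= 2 else (0.0 if len(vals) == 1 else np.nan)
                row[f"sd_{label}"] = sd
                if not np.isnan(sd):
                    sds.append(sd)
            row["mean_sd"] = float(np.mean(sds)) if sds else np.nan
            rows.append(row)
    grid = pd.DataFrame(rows)
    means = grid["mean_sd"].to_numpy()
    if np.all(np.isnan(means)):
        best = 0
    else:
        best = int(np.nanargmin(means))
    selected = (float(grid.loc[best, "t0"]), int(grid.loc[best, "l_min"]))
    return SweepResult(grid=grid, selected=selected)
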