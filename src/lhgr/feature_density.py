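"""Gene and repeat density along the LHGR map.

Gene density is genes per 1-Mb non-overlapping window, profiled either
by the genes' own GC3 (GC at third codon positions, binned by the
classical GC3 family criteria) or by the GC content of the host LHGR
(1%-wide bins).  A one-sided Welch t-test compares per-window gene
counts of a focal GC range against all other windows to test for local
density peaks.  LINE density is LINEs per Mb window grouped by host
family, with an ordinary least-squares line of density against family
mean GC.

All features (genes, repeats, windows) are assigned to segments by
their midpoints; windows are full-size only (a trailing partial window
is dropped), and features falling into splitting gaps or dropped
windows are excluded and counted in the exclusion report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lhgr.classification import FAMILY_LABELS, assign_family
from lhgr.errors import DataError

GC3_BOUNDARIES: tuple[float, ...] = (37.5, 50.0, 65.0, 80.0)

WINDOW_SIZE = 1_000_000


def gc3(cds_sequence: str) -> float:
    """GC percentage at third codon positions of an in-frame CDS.

    N third positions are excluded from the denominator.  Raises for a
    length not divisible by 3 or an all-N third-position set.
    """
    seq = cds_sequence.upper()
    if len(seq) == 0 or len(seq) % 3:
        raise ValueError(
            f"CDS length {len(seq)} is not a positive multiple of 3"
        )
    third = seq[2::3]
    n_gc = third.count("G") + third.count("C")
    n_valid = len(third) - third.count("N")
    if n_valid == 0:
        raise DataError("all third codon positions are N; GC3 undefined")
    return 100.0 * n_gc / n_valid


def assign_gc3_family(gc3_percent: float) -> str:
    """GC3 family under the classical criteria (37.5 / 50 / 65 / 80)."""
    if not 0 <= gc3_percent <= 100:
        raise ValueError(f"GC3 percent out of range: {gc3_percent}")
    return FAMILY_LABELS[int(np.searchsorted(GC3_BOUNDARIES, gc3_percent, side="right"))]


def assign_points_to_segments(
    positions: np.ndarray, segments: pd.DataFrame
) -> np.ndarray:
    """Index of the segment containing each 0-based position, -1 if none.

    ``segments`` must be a sorted single-chromosome table with 1-based
    inclusive ``start``/``stop`` columns.
    """
    starts = segments["start"].to_numpy() - 1
    stops = segments["stop"].to_numpy()
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx = idx.astype(np.int64)
    valid = (idx >= 0) & (positions < stops[np.clip(idx, 0, None)])
    return np.where(valid, idx, -1)


def assign_gene_to_segment(
    gene: pd.Series, segments: pd.DataFrame
) -> int | None:
    """Host segment index for one gene by its midpoint, None if in a gap."""
    mid = (int(gene["start"]) - 1 + int(gene["end"])) // 2
    idx = assign_points_to_segments(np.array([mid]), segments)[0]
    return None if idx < 0 else int(idx)


@dataclass
class DensityResult:
    """Binned feature density plus the per-window assignments behind it.

    ``table`` has one row per bin: bin label (or left edge), window_count,
    feature_count, density (features per Mb window).  ``windows`` has one
    row per retained 1-Mb window with its bin and feature count — the
    input of :func:`peak_test`.  ``excluded`` maps exclusion reasons to
    feature counts.
    """

    table: pd.DataFrame
    windows: pd.DataFrame
    excluded: dict[str, int]


def _windows_with_hosts(
    segments: pd.DataFrame, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Full 1-Mb windows per chromosome with host-segment GC (NaN in gaps)."""
    rows = []
    for chrom in sorted(chrom_lengths):
        n_win = chrom_lengths[chrom] // WINDOW_SIZE
        if n_win == 0:
            continue
        segs = segments[segments["chrom"] == chrom].sort_values("start")
        starts = np.arange(n_win, dtype=np.int64) * WINDOW_SIZE
        mids = starts + WINDOW_SIZE // 2
        host = (
            assign_points_to_segments(mids, segs)
            if len(segs)
            else np.full(n_win, -1)
        )
        gc = np.where(host >= 0, segs["gc"].to_numpy()[np.clip(host, 0, None)], np.nan)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "win_start": starts, "host_gc": gc}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _count_features_per_window(
    features: pd.DataFrame, windows: pd.DataFrame
) -> tuple[np.ndarray, dict[str, int]]:
    """Feature counts per window row (midpoint rule) and exclusion tally."""
    counts = np.zeros(len(windows), dtype=np.int64)
    excluded = {"beyond_last_window": 0, "window_in_gap": 0, "no_chromosome": 0}
    key = {
        (c, int(s)): i
        for i, (c, s) in enumerate(zip(windows["chrom"], windows["win_start"]))
    }
    in_gap = windows["host_gc"].isna().to_numpy()
    known_chroms = set(windows["chrom"])
    for chrom, start, end in zip(features["chrom"], features["start"], features["end"]):
        mid = (int(start) - 1 + int(end)) // 2
        i = key.get((chrom, (mid // WINDOW_SIZE) * WINDOW_SIZE))
        if i is None:
            if chrom in known_chroms:
                excluded["beyond_last_window"] += 1
            else:
                excluded["no_chromosome"] += 1
        elif in_gap[i]:
            excluded["window_in_gap"] += 1
        else:
            counts[i] += 1
    return counts, excluded


def gene_density_profile(
    genes: pd.DataFrame,
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    mode: str = "host_gc",
    bin_width: float = 1.0,
) -> DensityResult:
    """Gene density per GC bin under the GC3 or host-GC index.

    ``mode='host_gc'``: windows are binned by the GC of their midpoint's
    host segment in ``bin_width``-percent bins; density is genes per Mb
    window per bin.  ``mode='gc3'``: genes are binned by their own GC3
    under the classical GC3 family criteria and windows by their host
    segment's GC family, giving density per family.
    """
    if mode not in ("host_gc", "gc3"):
        raise ValueError(f"unknown mode: {mode!r}")
    if genes.empty or segments.empty:
        raise DataError("gene density requires non-empty genes and segments")
    windows = _windows_with_hosts(segments, chrom_lengths)
    counts, excluded = _count_features_per_window(genes, windows)
    windows = windows.assign(count=counts)
    kept = windows.dropna(subset=["host_gc"]).copy()
    excluded["gap_windows_dropped"] = int(len(windows) - len(kept))

    if mode == "host_gc":
        kept["bin"] = np.floor(kept["host_gc"] / bin_width) * bin_width
        g = kept.groupby("bin")
        table = pd.DataFrame(
            {
                "window_count": g.size(),
                "feature_count": g["count"].sum(),
            }
        ).reset_index()
    else:
        kept["bin"] = [assign_family(gc) for gc in kept["host_gc"]]
        if "gc3" in genes.columns:
            gvals = genes["gc3"]
        else:
            gvals = genes["cds"].map(gc3)
        gene_fam = gvals.map(assign_gc3_family)
        feature_count = gene_fam.value_counts()
        window_count = kept.groupby("bin").size()
        table = pd.DataFrame(
            {
                "window_count": window_count.reindex(FAMILY_LABELS, fill_value=0),
                "feature_count": feature_count.reindex(FAMILY_LABELS, fill_value=0),
            }
        )
        table.index.name = "bin"
        table = table.reset_index()
    table["density"] = table["feature_count"] / table["window_count"].replace(0, np.nan)
    return DensityResult(
        table=table, windows=kept[["chrom", "win_start", "host_gc", "bin", "count"]], excluded=excluded
    )


def peak_test(
    windows: pd.DataFrame, focal_bin: tuple[float, float]
) -> tuple[float, float]:
    """One-sided Welch t-test for excess gene density in a GC range.

    ``windows`` is the per-window table of a host-GC
    :class:`DensityResult` (columns ``host_gc`` and ``count``);
    ``focal_bin`` is a half-open GC range such as ``(50, 51)``.  Tests
    whether per-window counts inside the range are higher than in all
    other windows; returns (t, p).
    """
    lo, hi = focal_bin
    sel = (windows["host_gc"] >= lo) & (windows["host_gc"] < hi)
    focal = windows.loc[sel, "count"].to_numpy(dtype=float)
    rest = windows.loc[~sel, "count"].to_numpy(dtype=float)
    if len(focal) < 2 or len(rest) < 2:
        raise DataError(
            f"peak test needs >= 2 windows on each side, got {len(focal)} focal "
            f"and {len(rest)} background"
        )
    t, p = stats.ttest_ind(focal, rest, equal_var=False, alternative="greater")
    return float(t), float(p)


def correlation_gc3_host(
    genes: pd.DataFrame, segments: pd.DataFrame
) -> tuple[float, float]:
    """Squared Pearson correlation of gene GC3 vs host-LHGR GC.

    Genes whose midpoint falls outside every segment are excluded.
    Returns (r^2, p); raises for fewer than 3 hosted genes or constant
    vectors.
    """
    if "gc3" in genes.columns:
        gvals = genes["gc3"].to_numpy(dtype=float)
    else:
        gvals = genes["cds"].map(gc3).to_numpy(dtype=float)
    host_gc = np.full(len(genes), np.nan)
    for chrom, sub in genes.groupby("chrom"):
        segs = segments[segments["chrom"] == chrom].sort_values("start")
        if segs.empty:
            continue
        mids = ((sub["start"].to_numpy() - 1) + sub["end"].to_numpy()) // 2
        idx = assign_points_to_segments(mids, segs)
        vals = np.where(idx >= 0, segs["gc"].to_numpy()[np.clip(idx, 0, None)], np.nan)
        host_gc[genes.index.get_indexer(sub.index)] = vals
    ok = ~np.isnan(host_gc)
    if ok.sum() < 3:
        raise DataError("need at least 3 genes with host segments")
    x, y = gvals[ok], host_gc[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("constant GC3 or host-GC vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float


def filter_lines(repeats: pd.DataFrame) -> pd.DataFrame:
    """Keep repeat records whose class starts with LINE (e.g. LINE/L1)."""
    return repeats[repeats["repeat_class"].str.startswith("LINE")].copy()


def line_density_profile(
    repeats: pd.DataFrame,
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
) -> tuple[DensityResult, RegressionResult | None]:
    """LINE density per host family with its regression on family GC.

    ``repeats`` must already be filtered to LINE classes (see
    :func:`filter_lines`).  Density is LINEs per Mb window grouped by
    the window's host-segment family; the regression is OLS of density
    against the mean host GC of each occupied family bin.  With a single
    occupied bin the regression is undefined and None is returned.
    """
    if repeats.empty:
        raise DataError("no LINE records")
    windows = _windows_with_hosts(segments, chrom_lengths)
    counts, excluded = _count_features_per_window(repeats, windows)
    windows = windows.assign(count=counts)
    kept = windows.dropna(subset=["host_gc"]).copy()
    kept["bin"] = [assign_family(gc) for gc in kept["host_gc"]]
    g = kept.groupby("bin")
    table = pd.DataFrame(
        {
            "window_count": g.size(),
            "feature_count": g["count"].sum(),
            "mean_gc": g["host_gc"].mean(),
        }
    ).reindex(FAMILY_LABELS)
    table.index.name = "bin"
    table = table.dropna(subset=["window_count"]).reset_index()
    table["density"] = table["feature_count"] / table["window_count"]
    result = DensityResult(
        table=table[["bin", "window_count", "feature_count", "density"]],
        windows=kept[["chrom", "win_start", "host_gc", "bin", "count"]],
        excluded=excluded,
    )
    if len(table) < 2:
        return result, None
    reg = stats.linregress(table["mean_gc"], table["density"])
    return result, RegressionResult(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        pvalue=float(reg.pvalue),
    )
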