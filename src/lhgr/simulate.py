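"""Synthetic mosaic chromosomes with known LHGR structure.

Generates a chromosome as a concatenation of segments drawn from the
five GC families with right-skewed (lognormal) length distributions,
i.i.d. bases within each segment at the segment's GC target, optional
assembly gaps (N-runs), genes whose GC3 tracks the host segment's GC
with tunable coupling noise, and LINE placements whose rate decreases
linearly with host GC.  Every emitted file parses with :mod:`lhgr.io`,
and the ground truth (breakpoints, per-segment family and GC, gene and
repeat placements) is returned alongside so parameter recovery can be
scored exactly.

Default family mixture, GC targets and mean sizes follow the published
pig LHGR pattern summary; the gene and LINE rate functions reproduce
its qualitative density profiles (gene density rising with GC with an
optional local bump, LINE density falling linearly with GC) at
genome-realistic average rates (~1.2 genes/Mb, ~53 LINEs/Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from lhgr.classification import FAMILY_BOUNDARIES, FAMILY_LABELS, assign_family
from lhgr.io import GenomeSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MosaicSpec:
    """Generative description of a synthetic mosaic chromosome.

    Segment structure
    -----------------
    n_segments / total_length : exactly one must be set; with
        ``total_length`` segments are drawn until the target is reached
        and the last one truncated.
    family_mix : five proportions over L1..H3 (must sum to 1).
    gc_targets : per-family GC percent means.
    size_means_mb : per-family mean segment size (Mb); sizes are
        lognormal with shape ``size_sigma``.
    gc_jitter_sd : per-segment Gaussian jitter (GC points) around the
        family target, clamped inside the family's GC bin.
    gc_drift : within-segment linear GC gradient amplitude (GC points
        from segment start to end, random sign per segment).  0 gives
        i.i.d. bases — maximally homogeneous segments with very low h;
        positive drift probes the homogeneity index.
    gc_range : optional (lo, hi); when set, segment GC is uniform on the
        range and the family follows from the GC (family_mix ignored) —
        useful for populating narrow GC bins evenly.
    min_adjacent_delta_gc : optional; when set, each segment is redrawn
        until its GC differs from its left neighbour's by at least this
        many points, guaranteeing compositional contrast at every
        breakpoint.

    Gaps
    ----
    gap_count / gap_length : number and typical length (bp) of N-runs
        overwritten onto the sequence at random non-overlapping spots.

    Genes
    -----
    gene_rate_base, gene_rate_k : expected genes/Mb in a segment of GC
        g is ``gene_rate_base * exp(gene_rate_k * (g - 42))``.
    gene_bump_bins / gene_bump_rate : extra genes/Mb added when the host
        segment's GC falls in one of the half-open bins.
    cds_codons : codons per generated CDS.
    gc3_slope, gc3_intercept : linear map from host GC to the mean gene
        GC3; the default (GC3 = 2.66 * hostGC - 60.8) reproduces the
        classical amplification in which host families L1..H3 align
        with the GC3 criteria bins (37.5 / 50 / 65 / 80).
    gc3_noise_sd : sd (GC3 points) of the Gaussian coupling noise around
        that mean; 0 makes the coupling deterministic up to codon-count
        rounding.

    Repeats
    -------
    line_rate_intercept, line_rate_slope : LINEs/Mb at host GC g is
        ``max(0, intercept + slope * g)`` — decreasing for negative slope.
    sine_rate : constant SINEs/Mb mixed in so repeat files exercise
        class filtering.
    """

    n_segments: int | None = None
    total_length: int | None = None
    family_mix: tuple[float, ...] = (0.1345, 0.3336, 0.2955, 0.1963, 0.0401)
    gc_targets: tuple[float, ...] = (35.80, 38.98, 43.23, 48.94, 56.24)
    size_means_mb: tuple[float, ...] = (1.31, 0.89, 0.86, 0.79, 0.68)
    size_sigma: float = 0.45
    gc_jitter_sd: float = 1.0
    gc_drift: float = 0.0
    gc_range: tuple[float, float] | None = None
    min_adjacent_delta_gc: float | None = None
    gap_count: int = 0
    gap_length: int = 50_000
    gene_rate_base: float = 1.0
    gene_rate_k: float = 0.12
    gene_bump_bins: tuple[tuple[float, float], ...] = ()
    gene_bump_rate: float = 8.0
    cds_codons: int = 300
    gc3_slope: float = 2.66
    gc3_intercept: float = -60.8
    gc3_noise_sd: float = 21.8
    line_rate_intercept: float = 150.0
    line_rate_slope: float = -2.2
    sine_rate: float = 10.0
    chrom_id: str = "chrSim"

    def __post_init__(self) -> None:
        if (self.n_segments is None) == (self.total_length is None):
            raise ValueError("set exactly one of n_segments / total_length")
        if abs(sum(self.family_mix) - 1.0) > 1e-9:
            raise ValueError("family_mix must sum to 1")
        if any(r < 0 for r in (self.gene_rate_base, self.sine_rate)):
            raise ValueError("rates must be non-negative")
        for target, lo, hi in zip(
            self.gc_targets, (0,) + FAMILY_BOUNDARIES, FAMILY_BOUNDARIES + (100,)
        ):
            if not lo <= target < hi:
                raise ValueError(
                    f"GC target {target} outside its family bin [{lo}, {hi})"
                )


@dataclass
class MosaicTruth:
    """Ground truth of a generated mosaic chromosome."""

    chrom_id: str
    length: int
    segments: pd.DataFrame  # start, end (0-based half-open), gc (%), family
    gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def breakpoints(self) -> list[int]:
        """Internal segment boundaries (0-based)."""
        return self.segments["end"].tolist()[:-1]

    def segments_1based(self) -> pd.DataFrame:
        """Truth segments in the 1-based inclusive table dialect."""
        df = self.segments.copy()
        df.insert(0, "chrom", self.chrom_id)
        df["start"] = df["start"] + 1
        df = df.rename(columns={"end": "stop"})
        return df


def _draw_segments(spec: MosaicSpec, rng: np.random.Generator) -> pd.DataFrame:
    fams: list[int] = []
    gcs: list[float] = []
    lengths: list[int] = []
    bounds_lo = (0.0,) + FAMILY_BOUNDARIES
    bounds_hi = FAMILY_BOUNDARIES + (100.0,)

    def draw_one() -> None:
        for _attempt in range(1000):
            if spec.gc_range is not None:
                gc = float(rng.uniform(*spec.gc_range))
                fam = int(np.searchsorted(FAMILY_BOUNDARIES, gc, side="right"))
            else:
                fam = int(rng.choice(5, p=spec.family_mix))
                gc = spec.gc_targets[fam] + rng.normal(0.0, spec.gc_jitter_sd)
                gc = float(
                    np.clip(gc, bounds_lo[fam] + 0.2, bounds_hi[fam] - 0.2)
                )
            if (
                spec.min_adjacent_delta_gc is None
                or not gcs
                or abs(gc - gcs[-1]) >= spec.min_adjacent_delta_gc
            ):
                break
        else:
            raise ValueError(
                "could not satisfy min_adjacent_delta_gc with the given "
                "family mix and GC targets"
            )
        mean_bp = spec.size_means_mb[fam] * 1e6
        mu = np.log(mean_bp) - spec.size_sigma**2 / 2
        length = max(int(rng.lognormal(mu, spec.size_sigma)), 1000)
        fams.append(fam)
        gcs.append(gc)
        lengths.append(length)

    if spec.n_segments is not None:
        for _ in range(spec.n_segments):
            draw_one()
    else:
        while sum(lengths) < spec.total_length:
            draw_one()
        excess = sum(lengths) - spec.total_length
        if excess >= lengths[-1] - 1000:
            lengths[-1] = 1000
        else:
            lengths[-1] -= excess
    ends = np.cumsum(lengths)
    return pd.DataFrame(
        {
            "start": ends - np.asarray(lengths),
            "end": ends,
            "gc": gcs,
            "family": [FAMILY_LABELS[f] for f in fams],
        }
    )


def _realize_sequence(
    segments: pd.DataFrame, spec: MosaicSpec, rng: np.random.Generator
) -> np.ndarray:
    total = int(segments["end"].iloc[-1])
    arr = np.empty(total, dtype=np.uint8)
    for row in segments.itertuples(index=False):
        m = row.end - row.start
        gc = np.full(m, row.gc / 100.0)
        if spec.gc_drift:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            gc += sign * (spec.gc_drift / 100.0) * (
                np.linspace(0, 1, m) - 0.5
            )
            np.clip(gc, 0.01, 0.99, out=gc)
        u = rng.random(m)
        # A, C, G, T with the AT and GC masses split evenly within pairs
        is_gc = u < gc
        strong = rng.random(m) < 0.5  # G vs C, A vs T
        block = np.where(
            is_gc,
            np.where(strong, ord("G"), ord("C")),
            np.where(strong, ord("A"), ord("T")),
        ).astype(np.uint8)
        arr[row.start : row.end] = block
    return arr


def _place_gaps(
    spec: MosaicSpec, length: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    gaps: list[tuple[int, int]] = []
    for _ in range(spec.gap_count):
        glen = int(rng.integers(spec.gap_length // 2, spec.gap_length * 3 // 2 + 1))
        if glen >= length:
            raise ValueError("gap longer than chromosome")
        for _attempt in range(100):
            s = int(rng.integers(0, length - glen))
            if all(e2 <= s or s + glen <= s2 for s2, e2 in gaps):
                gaps.append((s, s + glen))
                break
    return sorted(gaps)


def generate_mosaic(
    spec: MosaicSpec, seed: int, with_sequence: bool = True
) -> tuple[GenomeSequence | None, MosaicTruth]:
    """Generate a mosaic chromosome and its ground truth.

    Deterministic given ``(spec, seed)``.  ``with_sequence=False`` skips
    base-level realization and returns only the truth — segment
    structure, gaps — for annotation-level simulations where the
    sequence itself is not needed.
    """
    rng = np.random.default_rng(seed)
    segments = _draw_segments(spec, rng)
    length = int(segments["end"].iloc[-1])
    gaps = _place_gaps(spec, length, rng)
    truth = MosaicTruth(
        chrom_id=spec.chrom_id, length=length, segments=segments, gaps=gaps
    )
    if not with_sequence:
        return None, truth
    arr = _realize_sequence(segments, spec, rng)
    for s, e in gaps:
        arr[s:e] = ord("N")
    seq = GenomeSequence(
        chrom_id=spec.chrom_id, residues=arr.tobytes().decode("ascii")
    )
    return seq, truth


def _gene_rate(spec: MosaicSpec, gc: float) -> float:
    rate = spec.gene_rate_base * np.exp(spec.gene_rate_k * (gc - 42.0))
    for lo, hi in spec.gene_bump_bins:
        if lo <= gc < hi:
            rate += spec.gene_bump_rate
    return rate


def _gc3_percent(host_gc: float, spec: MosaicSpec, rng: np.random.Generator) -> float:
    mu = spec.gc3_slope * host_gc + spec.gc3_intercept
    return float(np.clip(mu + rng.normal(0.0, spec.gc3_noise_sd), 1.0, 99.0))


def _make_cds(
    host_gc: float, spec: MosaicSpec, rng: np.random.Generator
) -> tuple[str, float]:
    """CDS whose GC3 follows the host-GC coupling model (exact GC3 count)."""
    n = spec.cds_codons
    p3 = _gc3_percent(host_gc, spec, rng) / 100
    k = int(round(p3 * n))
    third = np.where(
        np.isin(np.arange(n), rng.choice(n, size=k, replace=False)),
        rng.choice(_BASES[[1, 2]], size=n),  # C or G
        rng.choice(_BASES[[0, 3]], size=n),  # A or T
    ).astype(np.uint8)
    first_second = _BASES[rng.integers(0, 4, size=2 * n)]
    codons = np.empty(3 * n, dtype=np.uint8)
    codons[0::3] = first_second[0::2]
    codons[1::3] = first_second[1::2]
    codons[2::3] = third
    return codons.tobytes().decode("ascii"), 100.0 * k / n


def generate_annotations(
    truth: MosaicTruth,
    spec: MosaicSpec,
    seed: int,
    with_repeats: bool = True,
    with_cds: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate gene and repeat annotations on a mosaic truth.

    Gene counts per segment are Poisson with a rate (genes/Mb) that
    rises exponentially with segment GC plus any configured bump; each
    gene's CDS third-position GC equals host GC plus Gaussian coupling
    noise.  LINE counts are Poisson with a linearly decreasing rate in
    GC, and constant-rate SINE records are mixed in.  Returns
    ``(genes, repeats)`` in the exact dialects :mod:`lhgr.io` writes and
    parses (1-based inclusive coordinates).

    ``with_repeats=False`` skips the repeat draw (empty repeat table);
    ``with_cds=False`` records each gene's GC3 without realizing a CDS
    string — sufficient for density simulations and much faster.
    """
    rng = np.random.default_rng(seed)
    gene_rows = []
    repeat_rows = []
    gene_i = 0
    rep_i = 0
    for row in truth.segments.itertuples(index=False):
        seg_len = row.end - row.start
        mb = seg_len / 1e6
        span = min(5000, seg_len)
        n_genes = rng.poisson(_gene_rate(spec, row.gc) * mb)
        for _ in range(n_genes):
            pos = int(rng.integers(row.start, row.end - span + 1))
            if with_cds:
                cds, g3 = _make_cds(row.gc, spec, rng)
            else:
                cds = ""
                p3 = _gc3_percent(row.gc, spec, rng)
                g3 = round(p3 / 100 * spec.cds_codons) / spec.cds_codons * 100.0
            gene_i += 1
            gene_rows.append(
                {
                    "gene_id": f"G{gene_i:05d}",
                    "chrom": truth.chrom_id,
                    "start": pos + 1,
                    "end": pos + span,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "cds": cds,
                    "gc3": g3,
                }
            )
        if not with_repeats:
            continue
        line_rate = max(0.0, spec.line_rate_intercept + spec.line_rate_slope * row.gc)
        for rate, name, klass in (
            (line_rate, "L1_SS", "LINE/L1"),
            (spec.sine_rate, "PRE1_SS", "SINE/tRNA"),
        ):
            for _ in range(rng.poisson(rate * mb)):
                rlen = int(rng.integers(500, 6001))
                rlen = min(rlen, seg_len)
                pos = int(rng.integers(row.start, row.end - rlen + 1))
                rep_i += 1
                repeat_rows.append(
                    {
                        "chrom": truth.chrom_id,
                        "start": pos + 1,
                        "end": pos + rlen,
                        "repeat_name": name,
                        "repeat_class": klass,
                    }
                )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "cds", "gc3"],
    )
    repeats = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "repeat_name", "repeat_class"]
    )
    return genes, repeats
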