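# Methods

## Model and procedure

The package treats a chromosome as a mosaic of long homogeneous genome
regions (LHGRs): maximal stretches of near-constant GC content
separated by compositional breakpoints. Everything is computed from
cumulative base counts — no sliding windows — so results carry no
window-size or step-size artefacts.

### Composition curves and the z′ curve

`CompositionCurve` stores cumulative A/C/G/T/N counts at every
position. N residues (ambiguity codes and assembly gaps) are counted
separately and excluded from every base-frequency denominator, while
their coordinates are preserved, so all reported intervals are
chromosomal.

The raw disparity series over an interval is
`z_i = (#A + #T) − (#C + #G)` over its first `i` bases. Two distinct
detrending conventions are used, deliberately:

- **z′ visualization** removes the straight line through the interval
  *endpoints*. Segment interiors then appear as near-straight runs
  and breakpoints as slope kinks; the series is exactly zero at both
  ends.
- **Homogeneity index** uses a *least-squares* line (see below), the
  natural choice where residual variance is the quantity of interest.

### Recursive segmentation

For base frequencies `(a, c, g, t)` the genome order index is
`S = a² + c² + g² + t²` (0.25 for uniform composition, 1 for a
single-letter sequence). Splitting interval `[s, e)` at `i` yields

    δ(i) = w · [ (n_l/n)·S_left + (n_r/n)·S_right − S_whole ],

with `n_l`, `n_r`, `n` non-N base counts; δ ≥ 0 by convexity, and
equals `w · (n_l n_r / n²) Σ_b (f_b,left − f_b,right)²`, so it is a
pure between-half composition contrast. The split at the argmax of δ
(ties broken leftmost) is accepted when the **halting statistic**
`n·δ` reaches `t0` and both children are at least `l_min` long;
otherwise the interval is emitted as one segment. Candidate positions
respect `l_min` on both sides, which is what makes regions shorter
than `2·l_min` indivisible.

The `n·δ` scaling is this package's definition of the halting
statistic: under within-region homogeneity δ fluctuates as `O(1/n)`,
so `n·δ` is approximately scale-free and a single threshold is
meaningful from 10-kb toys to 300-Mb chromosomes. Exact numeric parity
with other segmentation programs built on the same divergence is not
claimed; the accuracy claims here are parameter-recovery results on
synthetic truth (below). Defaults `t0 = 100`, `l_min = 300,000`,
`w = 1` are the settings selected for mammalian chromosomes by the
per-family SD sweep (`parameter_sweep` reproduces that selection logic
by minimising the unweighted mean of per-family GC standard
deviations; the full grid is returned so a user can instead read the
dip off the curves).

**Scaling rule.** When segment sizes are scaled down by a factor `k`
(desk-scale studies), the halting statistic at a true boundary scales
with `n`, so the comparable setting is `t0·k` with `l_min·k`. The
package's own scaled studies use sizes ×1/3 with `t0 = 33`,
`l_min = 100,000`.

### Gaps and contigs

Any maximal N-run is a gap. Gaps of at least `gap_fraction` (default
1%) of the chromosome split it into contigs that are segmented
independently; shorter gaps stay inside contigs and are simply
invisible to the frequency math. Neighbour statistics (ΔGC) are never
computed across a splitting gap. Segment lengths are coordinate-true:
retained short gaps count toward length.

### Classification

- **Family** from GC percent, lower-inclusive bins: L1 < 37,
  L2 [37, 41), H1 [41, 46), H2 [46, 53), H3 ≥ 53. All printed GC
  values of the bundled reference table sit strictly inside bins, so
  bin-edge inclusivity is a convention, not a testable fact.
- **AT/GC type** relative to the chromosome mean GC; ties go to AT.
- **Homogeneity index** `h = s²(segment) / s²(chromosome)`, where `s²`
  is the mean squared residual of the raw z series about its
  least-squares line. `h = 1` for the chromosome itself by
  construction; `h > 1` is possible and means the segment is locally
  the most heterogeneous stretch of its host. Isochore iff
  `h < h_cut` (default 0.2, the empirical bound separating isochores
  from isochore-like regions); the rule is strict at the cutoff.

### Density profiling

Windows are full 1-Mb non-overlapping tiles per chromosome (a trailing
partial window is dropped so per-window counts are comparable). All
features and windows attach to segments by midpoint. Gene density is
genes per Mb window, binned by host-segment GC (1% bins — the width of
the reported density peaks) or by gene GC3 under the classical
criteria (37.5/50/65/80). Peak significance uses a one-sided Welch
t-test of per-window counts, focal GC range against all other windows
— one-sided because the claim under test is an excess, Welch because
bin variances differ. GC3-vs-host-GC coupling is the squared Pearson
correlation. LINE density per family is regressed (OLS) on family mean
GC. Excluded features (midpoint in a splitting gap, beyond the last
full window, unknown chromosome) are tallied with reasons.

## The synthetic generator

`MosaicSpec`/`generate_mosaic` emulate the study conditions: segments
drawn from the five families with the published pig mixture
(13.45/33.36/29.55/19.63/4.01% of segments), GC targets
(35.80/38.98/43.23/48.94/56.24%), and mean sizes
(1.31/0.89/0.86/0.79/0.68 Mb) under a right-skewed lognormal
(shape 0.45); per-segment GC jitter sd 1.0 point, clamped inside the
family bin. Bases are i.i.d. within a segment, AT and GC mass split
evenly within pairs. Annotation rates were chosen to match
genome-scale averages: genes at `1.0·exp(0.12·(GC−42))` per Mb
(≈1.2/Mb genome-wide, matching ≈2,800 genes on a 2.3-Gb genome), an
optional density bump of +8 genes/Mb in configurable GC bins
(several-fold, like the reported 50–51% and 54–55% peaks), LINEs at
`max(0, 150 − 2.2·GC)` per Mb (≈53/Mb genome-wide, strongly
decreasing), plus constant-rate SINEs so repeat parsers see mixed
classes. Gene GC3 is drawn around the classical amplification line
`GC3 = 2.66·hostGC − 60.8` (which aligns host families with the GC3
criteria bins) with Gaussian coupling noise, sd 21.8 GC3 points —
calibrated so the GC3-vs-host-GC r² lands near the observed ≈0.35.
Third-position GC counts are realized exactly (rounding only), so zero
coupling noise gives r² = 1.

What the generator does **not** emulate: base-order autocorrelation,
CpG suppression, repeat sequence content (only placements), realistic
codon usage beyond third-position GC, and within-segment
heterogeneity unless `gc_drift` is set. Consequences: i.i.d. segments
are *more* homogeneous than real isochores (h values near zero, so
default simulations classify everything as isochores — use `gc_drift`
to produce isochore-like regions), and breakpoint recovery on these
mosaics is an upper bound on real-data sharpness. Passing recovery
tests therefore validates the machinery and its calibration, not
performance on any particular genome.

## Numerical choices and degenerate inputs

- Split ties broken leftmost; candidate evaluation is vectorised in
  blocks (2²¹ positions) to bound memory on chromosome-scale contigs.
- δ is clipped at 0 (float round-off on homogeneous input).
- A split side with zero non-N bases is invalid (NaN in the profile);
  an all-N interval raises a degenerate-interval error, as does GC
  content of an all-N range or h on a zero-variance host.
- `gc3` requires an in-frame CDS (length divisible by 3) and at least
  one non-N third position.
- All-N chromosomes yield an empty contig list; contigs shorter than
  `l_min` are emitted whole and flagged.
- Family relative amounts are by segment count by default (`weight="bp"`
  switches to base-pair weighting); histograms are left-inclusive,
  0.5% GC bins and 0.2 Mb size bins.

## Problem sizes used in the test suite

Desk-scale studies keep the suite fast while preserving the full-scale
behaviour via the t0 scaling rule above: breakpoint recovery uses 20
mosaics of nine ≈0.55-Mb segments with guaranteed ≥5-point adjacent
contrast at full `t0 = 100` / `l_min = 300 kb`; family-pattern
recovery uses 20 mosaics of 24 segments at ×1/3 scale
(`t0 = 33`, `l_min = 100 kb`); density power/type-I studies use
annotation-level simulations (no base-level realization) on ≈400-Mb
truths, 20 simulations for power at α = 10⁻⁶ and 300 for the null
rejection rate at α = 0.05.

## Known limitations

- The halting statistic is scale-consistent but its absolute value is
  not comparable across divergence weights `w ≠ 1`.
- Greedy recursive splitting is not globally optimal for
  multi-breakpoint regions; on well-contrasted mosaics this is
  immaterial (the recovery suite), but closely spaced weak boundaries
  can shadow each other.
- `h` compares a segment against its whole host chromosome, so the
  same segment embedded in a calmer chromosome gets a larger h; h
  values are comparable within a chromosome, not across chromosomes.
- The density peak test treats windows as exchangeable; spatial
  autocorrelation of gene placement in real genomes would inflate its
  significance somewhat.
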