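"""GC3, gene/LINE density profiles, peak tests and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lhgr.errors import DataError
from lhgr.feature_density import (
    DensityResult,
    assign_gene_to_segment,
    assign_gc3_family,
    assign_points_to_segments,
    correlation_gc3_host,
    filter_lines,
    gc3,
    gene_density_profile,
    line_density_profile,
    peak_test,
)
from lhgr.simulate import MosaicSpec, generate_annotations, generate_mosaic


def segments_table(rows, chrom="c"):
    """rows: (start_1based, stop, gc)"""
    df = pd.DataFrame(rows, columns=["start", "stop", "gc"])
    df.insert(0, "chrom", chrom)
    from lhgr.classification import assign_family

    df["family"] = df["gc"].map(assign_family)
    return df


class TestGC3:
    @pytest.mark.parametrize(
        "cds, expected",
        [("ATGGCC", 100.0), ("ATGAAA", 50.0), ("ATA", 0.0), ("ATGGCN", 100.0)],
    )
    def test_examples(self, cds, expected):
        assert gc3(cds) == pytest.approx(expected)

    def test_frame_error(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            gc3("ATGG")

    def test_all_n_third_positions_undefined(self):
        with pytest.raises(DataError):
            gc3("AANCCN")

    @pytest.mark.parametrize("gc3_pct, family", [
        (30.0, "L1"), (37.5, "L2"), (50.0, "H1"), (65.0, "H2"), (80.0, "H3"), (95.0, "H3"),
    ])
    def test_gc3_family_criteria(self, gc3_pct, family):
        assert assign_gc3_family(gc3_pct) == family


class TestSegmentAssignment:
    def test_midpoint_rule(self):
        segs = segments_table([(1, 500, 40.0), (501, 1000, 50.0)])
        gene = pd.Series({"start": 100, "end": 200})
        assert assign_gene_to_segment(gene, segs) == 0
        straddler = pd.Series({"start": 450, "end": 650})  # midpoint 550
        assert assign_gene_to_segment(straddler, segs) == 1

    def test_midpoint_in_gap_returns_none(self):
        segs = segments_table([(1, 500, 40.0), (2001, 3000, 50.0)])
        gene = pd.Series({"start": 900, "end": 1500})  # midpoint ~1200, in gap
        assert assign_gene_to_segment(gene, segs) is None

    def test_vectorized_assignment_matches_interval_scan(self, rng):
        segs = segments_table([(1, 300, 40.0), (301, 700, 45.0), (901, 1200, 50.0)])
        pos = rng.integers(0, 1250, size=200)
        got = assign_points_to_segments(pos, segs)
        starts = segs["start"].to_numpy() - 1
        stops = segs["stop"].to_numpy()
        for p, idx in zip(pos, got):
            hits = [i for i in range(3) if starts[i] <= p < stops[i]]
            assert (idx == -1 and not hits) or (hits == [idx])


class TestGeneDensityProfile:
    def test_single_bin_uniform_density(self):
        # 10 full windows inside one 45%-GC segment, 20 genes
        segs = segments_table([(1, 10_000_000, 45.0)])
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                "chrom": "c",
                "start": np.arange(20) * 500_000 + 1000,
                "end": np.arange(20) * 500_000 + 4000,
                "strand": "+",
                "cds": "ATG",
            }
        )
        res = gene_density_profile(genes, segs, {"c": 10_000_000}, mode="host_gc")
        assert len(res.table) == 1
        assert res.table.iloc[0]["window_count"] == 10
        assert res.table.iloc[0]["density"] == pytest.approx(2.0)

    def test_gc3_mode_bins_genes_by_their_own_gc3(self):
        segs = segments_table([(1, 2_000_000, 39.0)])
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "chrom": "c",
                "start": [1000, 500_000, 900_000],
                "end": [4000, 504_000, 904_000],
                "strand": "+",
                "cds": ["ATA", "ATGGCC", "ATG"],  # GC3 0, 100, 100
            }
        )
        res = gene_density_profile(genes, segs, {"c": 2_000_000}, mode="gc3")
        t = res.table.set_index("bin")
        assert t.loc["L1", "feature_count"] == 1
        assert t.loc["H3", "feature_count"] == 2
        assert t.loc["L2", "window_count"] == 2  # host windows are L2

    def test_monotone_gene_rate_gives_monotone_density(self):
        # pool several seeds and bin windows by host family: density
        # rises from GC-poor to GC-rich families (H3 ignored: its few
        # windows make it noisy)
        from lhgr.classification import assign_family

        spec = MosaicSpec(n_segments=250, size_means_mb=(1.0,) * 5, size_sigma=0.2)
        windows = pd.Series(0.0, index=["L1", "L2", "H1", "H2"])
        features = pd.Series(0.0, index=["L1", "L2", "H1", "H2"])
        for seed in range(3):
            _, truth = generate_mosaic(spec, seed=500 + seed, with_sequence=False)
            genes, _ = generate_annotations(
                truth, spec, seed=600 + seed, with_repeats=False, with_cds=False
            )
            segs = truth.segments_1based()
            res = gene_density_profile(
                genes, segs, {truth.chrom_id: truth.length}, mode="host_gc"
            )
            fam = res.windows["host_gc"].map(assign_family)
            windows = windows.add(fam.value_counts(), fill_value=0)[windows.index]
            features = features.add(
                res.windows.groupby(fam)["count"].sum(), fill_value=0
            )[features.index]
        pooled = (features / windows).to_numpy()
        assert (np.diff(pooled) > 0).all()

    def test_unknown_mode_rejected(self):
        segs = segments_table([(1, 2_000_000, 45.0)])
        genes = pd.DataFrame(
            {"gene_id": ["a"], "chrom": "c", "start": [10], "end": [20], "strand": "+", "cds": ["ATG"]}
        )
        with pytest.raises(ValueError):
            gene_density_profile(genes, segs, {"c": 2_000_000}, mode="bogus")


class TestPeakTest:
    def windows(self, focal_counts, other_counts):
        return pd.DataFrame(
            {
                "host_gc": [50.5] * len(focal_counts) + [45.5] * len(other_counts),
                "count": list(focal_counts) + list(other_counts),
            }
        )

    def test_null_case_centred(self, rng):
        w = self.windows(rng.poisson(2, 50), rng.poisson(2, 50))
        t, p = peak_test(w, (50, 51))
        assert abs(t) < 3
        assert 0.001 < p < 0.999

    def test_strong_peak_is_significant_closed_form(self, rng):
        focal = rng.normal(5, 1, 50).round(2)
        rest = rng.normal(1, 1, 50).round(2)
        t, p = peak_test(self.windows(focal, rest), (50, 51))
        # cross-check against an independent Welch computation
        t2, p2 = stats.ttest_ind(focal, rest, equal_var=False, alternative="greater")
        assert t == pytest.approx(float(t2))
        assert p == pytest.approx(float(p2))
        assert p < 1e-6

    def test_empty_focal_bin_is_an_error(self, rng):
        w = self.windows([], rng.poisson(2, 20))
        with pytest.raises(DataError):
            peak_test(w, (50, 51))


class TestCorrelationGC3Host:
    def base(self, gc3_noise_sd):
        spec = MosaicSpec(
            n_segments=150,
            size_means_mb=(0.5,) * 5,
            gc3_noise_sd=gc3_noise_sd,
            gene_rate_base=3.0,
        )
        _, truth = generate_mosaic(spec, seed=21, with_sequence=False)
        genes, _ = generate_annotations(truth, spec, seed=22, with_repeats=False, with_cds=False)
        segs = truth.segments_1based().rename(columns={"end": "stop"})
        return genes, segs

    def test_deterministic_coupling_gives_r2_of_one(self):
        genes, segs = self.base(gc3_noise_sd=0.0)
        r2, p = correlation_gc3_host(genes, segs)
        assert r2 == pytest.approx(1.0, abs=0.01)
        assert p < 1e-6

    def test_decoupled_gc3_gives_r2_near_zero(self):
        genes, segs = self.base(gc3_noise_sd=0.0)
        rng = np.random.default_rng(33)
        genes = genes.assign(gc3=rng.permutation(genes["gc3"].to_numpy()))
        r2, _ = correlation_gc3_host(genes, segs)
        assert r2 < 0.05

    def test_default_coupling_noise_lands_near_a_third(self):
        # the default coupling noise is calibrated to the observed
        # GC3-vs-host-GC coupling strength (r^2 ~= 0.35)
        r2s = []
        for seed in range(5):
            spec = MosaicSpec(n_segments=150, size_means_mb=(0.5,) * 5, gene_rate_base=3.0)
            _, truth = generate_mosaic(spec, seed=100 + seed, with_sequence=False)
            genes, _ = generate_annotations(
                truth, spec, seed=200 + seed, with_repeats=False, with_cds=False
            )
            segs = truth.segments_1based().rename(columns={"end": "stop"})
            r2s.append(correlation_gc3_host(genes, segs)[0])
        assert abs(np.mean(r2s) - 0.35) < 0.1

    def test_constant_vectors_rejected(self):
        segs = segments_table([(1, 1000, 45.0)])
        genes = pd.DataFrame(
            {
                "gene_id": list("abc"),
                "chrom": "c",
                "start": [1, 101, 201],
                "end": [50, 150, 250],
                "strand": "+",
                "gc3": [50.0, 50.0, 50.0],
            }
        )
        with pytest.raises(DataError):
            correlation_gc3_host(genes, segs)


class TestLineDensity:
    def repeats(self, positions, chrom="c", klass="LINE/L1"):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": positions,
                "end": [p + 400 for p in positions],
                "repeat_name": "L1_SS",
                "repeat_class": klass,
            }
        )

    def test_equal_counts_in_all_bins_give_zero_slope(self):
        segs = segments_table(
            [(1, 2_000_000, 35.0), (2_000_001, 4_000_000, 44.0), (4_000_001, 6_000_000, 55.0)]
        )
        pos = [w * 1_000_000 + off for w in range(6) for off in (100, 300_000, 600_000)]
        res, reg = line_density_profile(
            self.repeats(pos), segs, {"c": 6_000_000}
        )
        assert reg is not None
        assert reg.slope == pytest.approx(0.0, abs=1e-9)

    def test_single_bin_regression_flagged_undefined(self):
        segs = segments_table([(1, 3_000_000, 45.0)])
        res, reg = line_density_profile(
            self.repeats([100, 1_200_000, 2_500_000]), segs, {"c": 3_000_000}
        )
        assert reg is None
        assert len(res.table) == 1

    def test_no_line_records_is_an_error(self):
        segs = segments_table([(1, 2_000_000, 45.0)])
        with pytest.raises(DataError):
            line_density_profile(self.repeats([]), segs, {"c": 2_000_000})

    def test_decreasing_generator_rate_recovered(self):
        slopes, r2s = [], []
        for seed in range(5):
            spec = MosaicSpec(n_segments=80, size_means_mb=(1.0,) * 5, size_sigma=0.2)
            _, truth = generate_mosaic(spec, seed=300 + seed, with_sequence=False)
            _, repeats = generate_annotations(truth, spec, seed=400 + seed, with_cds=False)
            lines = filter_lines(repeats)
            segs = truth.segments_1based().rename(columns={"end": "stop"})
            res, reg = line_density_profile(lines, segs, {truth.chrom_id: truth.length})
            slopes.append(reg.slope)
            r2s.append(reg.r_squared)
        assert all(s < 0 for s in slopes)
        assert np.median(r2s) >= 0.9

    def test_constant_rate_gives_equal_family_densities(self):
        spec = MosaicSpec(
            n_segments=80,
            size_means_mb=(1.0,) * 5,
            size_sigma=0.2,
            line_rate_intercept=50.0,
            line_rate_slope=0.0,
        )
        _, truth = generate_mosaic(spec, seed=17, with_sequence=False)
        _, repeats = generate_annotations(truth, spec, seed=18, with_cds=False)
        lines = filter_lines(repeats)
        segs = truth.segments_1based().rename(columns={"end": "stop"})
        res, _ = line_density_profile(lines, segs, {truth.chrom_id: truth.length})
        dens = res.table["density"].to_numpy()
        # all family densities near the common 50/Mb rate
        assert np.all(np.abs(dens - 50) < 10)
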