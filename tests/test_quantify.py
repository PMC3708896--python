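"""Tests for RPKM, Venn partitioning, binning and saturation analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import triadexpr as tx
from conftest import flat_count_matrix, uniform_catalog


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [(10, 1000, 1_000_000, 10.0), (0, 1000, 1_000_000, 0.0), (5, 500, 10_000_000, 1.0)],
    )
    def test_formula(self, count, length, total, expected):
        cm = flat_count_matrix(
            {"A": [count], "B": [count], "C": [count]},
            totals={"A": total, "B": total, "C": total},
        )
        catalog = uniform_catalog(cm.gene_ids, length_bp=length)
        rpkm = tx.compute_rpkm(cm, catalog)
        assert rpkm["A"].iloc[0] == pytest.approx(expected)

    def test_zero_iff_zero_count(self, small_dataset):
        rpkm = small_dataset["rpkm"]
        counts = small_dataset["counts"].counts
        assert ((rpkm == 0) == (counts == 0)).all().all()
        assert np.isfinite(rpkm.to_numpy()).all()

    def test_missing_gene_raises_keyed_error(self):
        cm = flat_count_matrix({"A": [1, 2], "B": [1, 2], "C": [1, 2]})
        catalog = uniform_catalog(cm.gene_ids[:1])
        with pytest.raises(tx.ComputeError, match="g0001"):
            tx.compute_rpkm(cm, catalog)

    @given(scale=st.integers(min_value=1, max_value=50))
    def test_invariant_under_joint_scaling(self, scale):
        base = np.array([3, 0, 17, 250])
        cm1 = flat_count_matrix(
            {"A": base, "B": base, "C": base}, totals=dict.fromkeys("ABC", 1000)
        )
        cm2 = flat_count_matrix(
            {"A": base * scale, "B": base * scale, "C": base * scale},
            totals=dict.fromkeys("ABC", 1000 * scale),
        )
        catalog = uniform_catalog(cm1.gene_ids, 500)
        pd.testing.assert_frame_equal(
            tx.compute_rpkm(cm1, catalog), tx.compute_rpkm(cm2, catalog)
        )


class TestExpressedAndVenn:
    def test_min_count_threshold(self):
        cm = flat_count_matrix({"A": [0, 1, 29, 30], "B": [1] * 4, "C": [1] * 4})
        flags1 = tx.call_expressed(cm, min_count=1)
        assert flags1["A"].tolist() == [False, True, True, True]
        flags30 = tx.call_expressed(cm, min_count=30)
        assert flags30["A"].tolist() == [False, False, False, True]
        with pytest.raises(tx.ConfigError):
            tx.call_expressed(cm, min_count=0)

    def test_partition_from_flag_matrix(self):
        # one gene per region plus one silent gene
        rows = {
            "A": [1, 1, 1, 0, 1, 0, 0, 0],
            "B": [1, 1, 0, 1, 0, 1, 0, 0],
            "C": [1, 0, 1, 1, 0, 0, 1, 0],
        }
        flags = pd.DataFrame({k: np.array(v, dtype=bool) for k, v in rows.items()})
        venn = tx.venn_partition(flags)
        assert (venn.abc, venn.ab, venn.ac, venn.bc, venn.a, venn.b, venn.c) == (
            1, 1, 1, 1, 1, 1, 1,
        )
        assert venn.grand_total == 7
        assert venn.library_totals == {"A": 4, "B": 4, "C": 4}

    def test_all_expressed_everywhere(self):
        flags = pd.DataFrame(
            {lib: np.ones(50, dtype=bool) for lib in tx.LIBRARIES}
        )
        venn = tx.venn_partition(flags)
        assert venn.abc == 50
        assert venn.grand_total == 50

    def test_empty_input_gives_zero_partition(self):
        flags = pd.DataFrame({lib: np.zeros(0, dtype=bool) for lib in tx.LIBRARIES})
        assert tx.venn_partition(flags).grand_total == 0

    @given(
        data=st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()),
            min_size=0,
            max_size=200,
        )
    )
    def test_totals_conservation_property(self, data):
        flags = pd.DataFrame(data or np.empty((0, 3), dtype=bool), columns=list(tx.LIBRARIES)).astype(bool)
        venn = tx.venn_partition(flags)
        for lib in tx.LIBRARIES:
            assert venn.library_total(lib) == int(flags[lib].sum())
        assert venn.grand_total == int(flags.any(axis=1).sum())


class TestLengthAndCoverageBins:
    def test_percentages_round_half_up_to_2_decimals(self):
        pct = tx.bin_percentages([5048, 10024, 8293, 4446, 4831])
        assert pct.tolist() == [15.46, 30.71, 25.41, 13.62, 14.80]

    def test_single_gene_single_bin(self):
        summary = tx.length_bin_summary([120])
        assert summary["count"].tolist() == [1, 0, 0, 0, 0]
        assert summary["percentage"].tolist()[0] == 100.0

    def test_boundary_length_falls_in_upper_bin(self):
        summary = tx.length_bin_summary([500])
        assert summary["count"].tolist() == [0, 1, 0, 0, 0]

    def test_coverage_full_and_high(self):
        cov = pd.Series([1.0, 1.0, 0.95, 0.0])
        bins = tx.coverage_bins(cov)
        assert bins.iloc[9, 0] == 3  # the three matched genes, >90% bin
        assert bins.iloc[:, 0].sum() == 3  # zero-coverage gene excluded

    def test_coverage_out_of_range_rejected(self):
        with pytest.raises(tx.ConfigError):
            tx.coverage_bins(pd.Series([0.5, 1.2]))


class TestSaturation:
    def test_full_depth_recovers_exact_detection(self):
        counts = np.array([0, 1, 5, 100])
        curve = tx.saturation_curve(counts, [0, 50, 106], n_reps=2, seed=0)
        assert curve.detected_mean[0] == 0
        assert curve.detected_mean[-1] == 3  # genes with >= 1 read

    def test_replicate_curves_are_monotone(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, 500)
        depths = np.linspace(0, counts.sum(), 8, dtype=int)
        curve = tx.saturation_curve(counts, depths, n_reps=4, seed=2)
        assert (np.diff(curve.detected, axis=1) >= 0).all()

    def test_rare_gene_detection_probability(self):
        # counts (1, 999,999), depth 10: P(seeing the singleton) = 1e-5,
        # so the mean detected is 1 + 1e-5 in expectation
        counts = np.array([1, 999_999])
        reps = 200
        curve = tx.saturation_curve(counts, [0, 10, 1_000_000], n_reps=reps, seed=3)
        mean10 = curve.detected_mean[1]
        se = np.sqrt(1e-5 * (1 - 1e-5) / reps)
        assert abs(mean10 - (1 + 1e-5)) <= 5 * se + 1e-9

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(tx.ConfigError):
            tx.saturation_curve(np.array([5, 5]), [0, 11, 20])

    def test_flat_curve_saturates_at_first_depth(self):
        curve = tx.SaturationCurve(
            depths=[0, 1_000_000, 2_000_000], detected=[[500, 500, 500]], min_count=1
        )
        assert tx.saturation_point(curve) == 0

    def test_strictly_linear_curve_never_saturates(self):
        depths = np.array([0, 1_000_000, 2_000_000, 3_000_000])
        curve = tx.SaturationCurve(
            depths=depths, detected=[depths / 1000.0], min_count=1
        )
        assert tx.saturation_point(curve) is None

    def test_plateau_detected_at_knee(self):
        curve = tx.SaturationCurve(
            depths=[0, 1_000_000, 2_000_000, 3_000_000],
            detected=[[0, 900, 1000, 1004]],
            min_count=1,
        )
        # gain beyond 2M is 4 genes/M < 0.5% of 1004
        assert tx.saturation_point(curve) == 2_000_000
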