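"""Tests for the ground-truth simulator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triadexpr as tx
from conftest import make_dataset


class TestCatalog:
    def test_degenerate_weights_confine_lengths_to_first_bin(self):
        cfg = tx.SimulationConfig(n_genes=100, length_bin_weights=(1, 0, 0, 0, 0))
        catalog = tx.generate_catalog(cfg)
        assert ((catalog["length_bp"] >= 100) & (catalog["length_bp"] < 500)).all()

    def test_bin_shares_track_configured_weights(self):
        # full-scale catalog: realized bin shares within 1 percentage point
        cfg = tx.SimulationConfig(n_genes=32642, seed=3)
        catalog = tx.generate_catalog(cfg)
        counts = tx.quantify.length_bin_counts(catalog["length_bp"])
        shares = counts / counts.sum()
        for share, weight in zip(shares, cfg.length_bin_weights):
            assert abs(share - weight) < 0.01

    def test_same_seed_reproduces_catalog(self):
        cfg = tx.SimulationConfig(n_genes=500, seed=9)
        a = tx.generate_catalog(cfg)
        b = tx.generate_catalog(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_ids_unique_and_lengths_at_least_100(self):
        cfg = tx.SimulationConfig(n_genes=2000, seed=1)
        catalog = tx.generate_catalog(cfg)
        assert catalog["gene_id"].is_unique
        assert (catalog["length_bp"] >= 100).all()


class TestTruth:
    def test_no_nonadditivity_means_hybrid_is_exact_midparent(self):
        _, catalog, truth, _ = make_dataset(
            n_genes=1000, frac_nonadditive=0.0, frac_specific=0.0, seed=5
        )
        mpv = (truth["mean_rpkm_A"] + truth["mean_rpkm_B"]) / 2
        np.testing.assert_array_equal(truth["mean_rpkm_C"].to_numpy(), mpv.to_numpy())
        assert not truth["nonadditive"].any()

    def test_unbiased_deviations_balance_between_parents(self):
        # paternal_bias=0: deviations away from A vs away from B should be
        # a fair coin among divergent nonadditive genes
        _, _, truth, _ = make_dataset(
            n_genes=20000,
            frac_de_parents=0.5,
            frac_nonadditive=0.5,
            paternal_bias=0.0,
            frac_specific=0.0,
            seed=17,
        )
        away_a = int((truth["deviates_from"] == "A").sum())
        away_b = int((truth["deviates_from"] == "B").sum())
        assert away_a + away_b > 2000
        assert stats.binomtest(away_a, away_a + away_b, 0.5).pvalue > 1e-4

    def test_positive_bias_skews_deviations_away_from_paternal(self):
        _, _, truth, _ = make_dataset(
            n_genes=10000,
            frac_de_parents=0.5,
            frac_nonadditive=0.5,
            paternal_bias=0.8,
            frac_specific=0.0,
            seed=18,
        )
        away_a = int((truth["deviates_from"] == "A").sum())
        away_b = int((truth["deviates_from"] == "B").sum())
        assert away_a > 2 * away_b

    def test_no_specific_genes_means_no_partial_zeros(self):
        _, _, truth, _ = make_dataset(n_genes=1000, frac_specific=0.0, seed=6)
        means = truth[["mean_rpkm_A", "mean_rpkm_B", "mean_rpkm_C"]].to_numpy()
        n_zero = (means == 0).sum(axis=1)
        assert (n_zero == 0).all()

    def test_specific_genes_are_zero_exactly_elsewhere(self):
        _, _, truth, _ = make_dataset(
            n_genes=5000, frac_specific=(0.1, 0.1, 0.1), seed=7
        )
        spec_a = truth[truth["specific_to"] == "A"]
        assert len(spec_a) > 0
        assert (spec_a["mean_rpkm_B"] == 0).all()
        assert (spec_a["mean_rpkm_C"] == 0).all()
        assert (spec_a["mean_rpkm_A"] > 0).all()

    def test_pattern_group_matches_true_effect_signs(self):
        _, _, truth, _ = make_dataset(n_genes=3000, seed=8)
        grouped = truth[truth["pattern_group"] > 0]
        assert len(grouped) > 0
        up_a = grouped["true_log2_CA"] > 0
        up_b = grouped["true_log2_CB"] > 0
        expected = np.where(up_a, np.where(up_b, 4, 3), np.where(up_b, 2, 1))
        np.testing.assert_array_equal(grouped["pattern_group"].to_numpy(), expected)

    def test_nonadditive_flag_consistent_with_midparent(self):
        _, _, truth, _ = make_dataset(n_genes=3000, seed=12)
        mpv = (truth["mean_rpkm_A"] + truth["mean_rpkm_B"]) / 2
        np.testing.assert_array_equal(
            truth["nonadditive"].to_numpy(), (truth["mean_rpkm_C"] != mpv).to_numpy()
        )


class TestCounts:
    def test_zero_rate_yields_zero_counts(self):
        _, catalog, truth, counts = make_dataset(
            n_genes=3000, frac_specific=(0.2, 0.2, 0.2), seed=10
        )
        truth = truth.set_index("gene_id")
        zero_a = truth.index[truth["mean_rpkm_A"] == 0]
        assert len(zero_a) > 0
        assert (counts.counts.loc[zero_a, "A"] == 0).all()

    def test_poisson_limit_moments(self):
        # dispersion=0 with expected count 100 over 10,000 genes: the
        # sample mean must sit within 3 standard errors of 100
        ids = [f"g{i}" for i in range(10000)]
        catalog = pd.DataFrame({"gene_id": ids, "length_bp": 1000})
        truth = pd.DataFrame(
            {
                "gene_id": ids,
                "mean_rpkm_A": 50.0,
                "mean_rpkm_B": 50.0,
                "mean_rpkm_C": 50.0,
            }
        )
        cfg = tx.SimulationConfig(
            n_genes=10000, library_sizes=(2_000_000,) * 3, dispersion=0.0, seed=11
        )
        counts = tx.sample_counts(truth, catalog, cfg)
        mean = counts.counts["A"].mean()
        se = np.sqrt(100 / 10000)
        assert abs(mean - 100) < 3 * se

    def test_overdispersion_inflates_variance(self):
        ids = [f"g{i}" for i in range(20000)]
        catalog = pd.DataFrame({"gene_id": ids, "length_bp": 1000})
        truth = pd.DataFrame(
            {"gene_id": ids, "mean_rpkm_A": 50.0, "mean_rpkm_B": 50.0, "mean_rpkm_C": 50.0}
        )
        base = dict(n_genes=20000, library_sizes=(2_000_000,) * 3, seed=11)
        poisson = tx.sample_counts(
            truth, catalog, tx.SimulationConfig(dispersion=0.0, **base)
        )
        nb = tx.sample_counts(
            truth, catalog, tx.SimulationConfig(dispersion=0.2, **base)
        )
        # NB variance m + alpha m^2 = 100 + 2000 vs Poisson 100
        assert nb.counts["A"].var() > 5 * poisson.counts["A"].var()

    def test_same_seed_reproduces_counts(self):
        _, _, _, counts_a = make_dataset(n_genes=400, seed=13)
        _, _, _, counts_b = make_dataset(n_genes=400, seed=13)
        pd.testing.assert_frame_equal(counts_a.counts, counts_b.counts)

    def test_library_totals_are_realized_column_sums(self, small_dataset):
        counts = small_dataset["counts"]
        assert (counts.totals == counts.counts.sum(axis=0)).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"length_bin_weights": (0.5, 0.5, 0.5, 0, 0)},
        {"length_bin_weights": (1, 0, 0, 0)},
        {"library_sizes": (0, 10, 10)},
        {"frac_de_parents": 1.5},
        {"frac_nonadditive": -0.1},
        {"paternal_bias": 2.0},
        {"dispersion": -1.0},
        {"frac_specific": (0.5, 0.4, 0.3)},
        {"n_genes": 0},
    ],
)
def test_invalid_configuration_rejected(kwargs):
    with pytest.raises(tx.ConfigError):
        tx.SimulationConfig(**kwargs)
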