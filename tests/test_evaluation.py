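"""MCC genotype concordance and haplogroup concordance evaluation."""

import numpy as np
import pytest

from mitopanel.chip_sim import ChipDefinition, mask_to_chip
from mitopanel.evaluation import (
    baseline_mean_mcc,
    evaluate_run,
    haplogroup_concordance,
    mcc_from_counts,
    mean_mcc_ci,
    parameter_sweep,
    per_site_mcc,
)
from mitopanel.haplogroup import HaplogroupCall
from mitopanel.imputation import HaplotypeImputer


class TestMccFromCounts:
    def test_perfect_calls(self):
        assert mcc_from_counts(5, 0, 7, 0) == 1.0

    def test_balanced_noise_is_zero(self):
        assert mcc_from_counts(1, 1, 1, 1) == 0.0

    def test_hand_computed_example(self):
        # TP=3, TN=4, FP=1, FN=2 -> 10 / sqrt(600)
        assert round(mcc_from_counts(3, 1, 4, 2), 5) == 0.40825

    def test_zero_denominator_convention(self):
        assert mcc_from_counts(0, 0, 5, 0) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_sklearn_on_random_tables(self, seed):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(seed)
        for _ in range(50):
            truth = rng.integers(0, 2, size=30)
            calls = rng.integers(0, 2, size=30)
            tp = int(np.sum((truth == 1) & (calls == 1)))
            fp = int(np.sum((truth == 0) & (calls == 1)))
            tn = int(np.sum((truth == 0) & (calls == 0)))
            fn = int(np.sum((truth == 1) & (calls == 0)))
            assert mcc_from_counts(tp, fp, tn, fn) == pytest.approx(
                matthews_corrcoef(truth, calls), abs=1e-12
            )


class TestMeanMccCi:
    def test_single_site_degenerate_interval(self):
        assert mean_mcc_ci([0.5]) == (0.5, 0.5, 0.5)

    def test_two_site_mean(self):
        mu, lo, hi = mean_mcc_ci([0.4, 0.6])
        assert mu == pytest.approx(0.5)
        assert lo < mu < hi

    def test_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.2, 0.9, size=200)
        mu, lo, hi = mean_mcc_ci(values)
        boots = np.array([
            rng.choice(values, size=values.size, replace=True).mean()
            for _ in range(10000)
        ])
        b_lo, b_hi = np.quantile(boots, [0.025, 0.975])
        assert lo == pytest.approx(b_lo, abs=0.01)
        assert hi == pytest.approx(b_hi, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_mcc_ci([])


class TestHaplogroupConcordance:
    def test_identical_vectors(self):
        calls = {f"s{i}": "H1" for i in range(4)}
        assert haplogroup_concordance(calls, dict(calls), "full") == 1.0

    def test_three_of_four(self):
        truth = {"a": "H", "b": "H", "c": "J", "d": "K"}
        test = {"a": "H", "b": "H", "c": "J", "d": "U"}
        assert haplogroup_concordance(truth, test, "full") == 0.75

    def test_macro_level_collapses_before_comparing(self):
        truth = {"a": "H1a", "b": "HV4"}
        test = {"a": "H3", "b": "HV9"}
        assert haplogroup_concordance(truth, test, "macro") == 1.0
        assert haplogroup_concordance(truth, test, "full") == 0.0

    def test_unassigned_counts_discordant(self):
        truth = {"a": "H"}
        test = {"a": HaplogroupCall("a", None, 0.0, 0)}
        assert haplogroup_concordance(truth, test, "full") == 0.0

    def test_disjoint_samples_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            haplogroup_concordance({"a": "H"}, {"b": "H"}, "full")


class TestPerSiteMcc:
    def test_clade_tagging_chip_imputes_near_perfectly(
        self, truth_panel, reference_panel, population, target_ids
    ):
        """A chip carrying one defining variant per clade node resolves
        every lineage, so imputed clade variants score MCC ~ 1."""
        tag_positions = sorted(
            muts[0][0] for muts in population.clade_defining.values() if muts
        )
        chip = ChipDefinition("tags", np.array(tag_positions))
        typed = mask_to_chip(truth_panel, chip, list(target_ids))
        result = HaplotypeImputer(k_hap=100).fit(reference_panel).predict(typed)
        table = per_site_mcc(truth_panel, result)
        assert len(table) > 10
        assert (table["mcc"] > 0.9).mean() > 0.9

    def test_order_invariance(self, truth_panel, reference_panel, target_ids):
        chip = ChipDefinition("c", truth_panel.positions[::5].copy())
        typed = mask_to_chip(truth_panel, chip, list(target_ids))
        result = HaplotypeImputer(k_hap=100).fit(reference_panel).predict(typed)
        table = per_site_mcc(truth_panel, result)
        mu1, *_ = mean_mcc_ci(table["mcc"].to_numpy())
        mu2, *_ = mean_mcc_ci(table["mcc"].to_numpy()[::-1])
        assert mu1 == pytest.approx(mu2, abs=1e-15)

    def test_unknown_samples_rejected(self, truth_panel, reference_panel, target_ids):
        chip = ChipDefinition("c", truth_panel.positions[:5].copy())
        typed = mask_to_chip(truth_panel, chip, list(target_ids[:2]))
        result = HaplotypeImputer(k_hap=10).fit(reference_panel).predict(typed)
        tiny_truth = truth_panel.subset_samples(truth_panel.sample_ids[:1])
        with pytest.raises(ValueError, match="absent"):
            per_site_mcc(tiny_truth, result)


class TestEvaluateRun:
    def test_improvement_reported(self, truth_panel, reference_panel,
                                  population, target_ids):
        chip = ChipDefinition("c", truth_panel.positions[::13].copy())
        typed = mask_to_chip(truth_panel, chip, list(target_ids))
        result = HaplotypeImputer(k_hap=100).fit(reference_panel).predict(typed)
        truth_labels = {s: population.truth_labels[s] for s in target_ids}
        report = evaluate_run(
            truth_panel, truth_labels, typed, result, population.haplogroup_table()
        )
        for key in ("masked_macro", "masked_full", "imputed_macro", "imputed_full"):
            assert 0.0 <= report.concordance[key] <= 1.0
        assert report.improvement_full == pytest.approx(
            report.concordance["imputed_full"] - report.concordance["masked_full"]
        )
        assert report.concordance["imputed_full"] >= report.concordance["masked_full"]

    def test_copying_model_beats_frequency_baseline(
        self, truth_panel, reference_panel, population, target_ids
    ):
        chip = ChipDefinition("c", truth_panel.positions[::13].copy())
        typed = mask_to_chip(truth_panel, chip, list(target_ids))
        result = HaplotypeImputer(k_hap=100).fit(reference_panel).predict(typed)
        table = per_site_mcc(truth_panel, result)
        base = baseline_mean_mcc(
            truth_panel, reference_panel, typed,
            positions=table["position"].to_numpy(),
        )
        assert table["mcc"].mean() > base + 0.2


class TestParameterSweep:
    def test_grid_shape_and_determinism(self, truth_panel, population, target_ids):
        chips = [
            ChipDefinition("c1", truth_panel.positions[::11].copy()),
            ChipDefinition("c2", truth_panel.positions[::17].copy()),
        ]
        table = population.haplogroup_table()
        truth_labels = {s: population.truth_labels[s] for s in target_ids}
        kwargs = dict(
            truth=truth_panel, truth_labels=truth_labels, chips=chips,
            target_ids=list(target_ids), table=table,
            k_hap_grid=(50, 100), maf_grid=(0.01, 0.001),
        )
        df1 = parameter_sweep(**kwargs)
        df2 = parameter_sweep(**kwargs)
        assert len(df1) == 2 * 2 * 2
        assert df1.equals(df2)

    def test_k_hap_equal_to_panel_matches_no_selection_oracle(
        self, truth_panel, reference_panel, population, target_ids
    ):
        """k_hap = K reproduces imputation without conditioning-set
        pre-selection exactly."""
        chip = ChipDefinition("c", truth_panel.positions[::11].copy())
        typed = mask_to_chip(truth_panel, chip, list(target_ids[:10]))
        K = reference_panel.n_samples
        lam = 0.01
        res_k = HaplotypeImputer(k_hap=K, copying_error=lam).fit(
            reference_panel
        ).predict(typed)
        res_big = HaplotypeImputer(k_hap=10 * K, copying_error=lam).fit(
            reference_panel
        ).predict(typed)
        assert np.allclose(res_k.p_alt, res_big.p_alt, atol=1e-12)
        mu_k, *_ = mean_mcc_ci(per_site_mcc(truth_panel, res_k)["mcc"].to_numpy())
        mu_big, *_ = mean_mcc_ci(per_site_mcc(truth_panel, res_big)["mcc"].to_numpy())
        assert mu_k == mu_big

    def test_empty_grid_rejected(self, truth_panel, population, target_ids):
        with pytest.raises(ValueError):
            parameter_sweep(
                truth=truth_panel, truth_labels={}, chips=[],
                target_ids=list(target_ids), table=population.haplogroup_table(),
            )
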