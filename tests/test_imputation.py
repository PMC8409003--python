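"""Haploid copying-model imputation engine.

The independent oracle re-implements the collapsed copying model as a
literal product over typed sites for every reference haplotype, with no
conditioning-set selection, no log-space tricks and no vectorisation.
"""

import numpy as np
import pytest
from sklearn.base import clone

from mitopanel.chip_sim import TypedGenotypes
from mitopanel.imputation import (
    HaplotypeImputer,
    ImputationConfig,
    MajorAlleleImputer,
    apply_info_filter,
    copying_weights,
    default_copying_error,
    hard_call,
    impute_sample,
    info_score,
    select_conditioning_haplotypes,
)
from mitopanel.panel import MISSING, VariantPanel


def panel_from_matrix(H: np.ndarray) -> VariantPanel:
    n_sites, n_samples = H.shape
    return VariantPanel(
        positions=np.arange(1, n_sites + 1, dtype=np.int64),
        ref_alleles=["A"] * n_sites,
        alt_alleles=[("G",)] * n_sites,
        haplotypes=H.astype(np.int8),
        sample_ids=[f"h{j}" for j in range(n_samples)],
    )


def naive_posteriors(target: np.ndarray, H: np.ndarray, lam: float) -> np.ndarray:
    """Direct enumeration over all reference haplotypes."""
    n_sites, K = H.shape
    weights = []
    for h in range(K):
        w = 1.0
        for s in range(n_sites):
            if target[s] == MISSING or H[s, h] == MISSING:
                continue
            w *= (1.0 - lam) if H[s, h] == target[s] else lam
        weights.append(w)
    weights = np.array(weights) / np.sum(weights)
    p = np.empty(n_sites)
    for s in range(n_sites):
        if target[s] != MISSING:
            p[s] = float(target[s] == 1)
            continue
        carriers = [h for h in range(K) if H[s, h] != MISSING]
        wsum = sum(weights[h] for h in carriers)
        if wsum == 0.0:
            obs = H[s][H[s] != MISSING]
            p[s] = obs.mean() if obs.size else 0.5
            continue
        p[s] = sum(
            (weights[h] / wsum) * ((1.0 - lam) if H[s, h] == 1 else lam)
            for h in carriers
        )
    return p


class TestDefaultCopyingError:
    def test_strictly_decreasing_in_k(self):
        lams = [default_copying_error(k) for k in (2, 5, 10, 100, 1000)]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_valid_range(self):
        for k in (1, 2, 10, 30000):
            assert 0 < default_copying_error(k) < 0.5


class TestConditioningSelection:
    def test_k_at_least_panel_returns_all(self):
        panel = panel_from_matrix(np.zeros((4, 6)))
        assert list(select_conditioning_haplotypes(np.zeros(4), panel, 10)) == list(range(6))

    def test_exact_match_selected_first(self):
        H = np.array([[0, 1, 1], [0, 1, 1], [0, 0, 1]])
        target = np.array([1, 1, 1], dtype=np.int8)
        chosen = select_conditioning_haplotypes(target, panel_from_matrix(H), 1)
        assert list(chosen) == [2]

    def test_tie_broken_by_lower_index(self):
        H = np.array([[1, 1], [0, 0]])
        target = np.array([1, MISSING], dtype=np.int8)
        chosen = select_conditioning_haplotypes(target, panel_from_matrix(H), 1)
        assert list(chosen) == [0]


class TestCopyingWeights:
    def test_worked_example(self):
        # lambda=0.1; h1 matches 3/3 typed sites, h2 matches 1/3:
        # raw (0.729, 0.009) -> normalised (0.98780, 0.01220)
        H = np.array([[1, 1], [1, 0], [1, 0]])
        target = np.array([1, 1, 1], dtype=np.int8)
        w = copying_weights(target, H, 0.1)
        assert w == pytest.approx([0.729 / 0.738, 0.009 / 0.738], abs=1e-12)
        assert tuple(np.round(w, 5)) == (0.98780, 0.01220)

    def test_small_lambda_concentrates_on_exact_match(self):
        H = np.array([[1, 0], [1, 0], [1, 0]])
        target = np.array([1, 1, 1], dtype=np.int8)
        w = copying_weights(target, H, 1e-9)
        assert w[0] == pytest.approx(1.0, abs=1e-6)

    def test_no_typed_overlap_gives_uniform(self):
        H = np.array([[0, 1, 1]])
        target = np.array([MISSING], dtype=np.int8)
        assert copying_weights(target, H, 0.1) == pytest.approx([1 / 3] * 3)

    def test_invalid_lambda_rejected(self):
        H = np.array([[0, 1]])
        with pytest.raises(ValueError):
            copying_weights(np.array([1], dtype=np.int8), H, 0.7)


class TestImputeSample:
    def test_worked_example_posterior(self):
        # weights (0.98780, 0.01220), h1 ref / h2 alt at the untyped site,
        # lambda = 0.1 -> P(alt) = 0.10976
        H = np.array([[1, 1], [1, 0], [1, 0], [0, 1]])
        target = np.array([1, 1, 1, MISSING], dtype=np.int8)
        config = ImputationConfig(k_hap=2, copying_error=0.1)
        p, fallback = impute_sample(target, panel_from_matrix(H), config)
        assert round(p[3], 5) == 0.10976
        assert not fallback.any()

    def test_unanimous_alt_small_lambda_limit(self):
        H = np.ones((3, 4))
        target = np.array([1, 1, MISSING], dtype=np.int8)
        config = ImputationConfig(k_hap=4, copying_error=1e-9)
        p, _ = impute_sample(target, panel_from_matrix(H), config)
        assert p[2] == pytest.approx(1.0, abs=1e-6)

    def test_typed_sites_degenerate(self):
        H = np.array([[0, 1], [1, 0]])
        target = np.array([1, 0], dtype=np.int8)
        config = ImputationConfig(k_hap=2, copying_error=0.1)
        p, _ = impute_sample(target, panel_from_matrix(H), config)
        assert list(p) == [1.0, 0.0]

    def test_all_missing_site_falls_back_to_frequency(self):
        H = np.array([[0, 1], [MISSING, MISSING]])
        target = np.array([0, MISSING], dtype=np.int8)
        config = ImputationConfig(k_hap=2, copying_error=0.1)
        p, fallback = impute_sample(target, panel_from_matrix(H), config)
        assert fallback[1]
        assert p[1] == pytest.approx(0.5)  # overall panel alt frequency

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence(self, seed):
        """Matches naive direct enumeration to 1e-9 with k_hap = K."""
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(2, 51))
        K = int(rng.integers(1, 21))
        H = rng.integers(0, 2, size=(n_sites, K)).astype(np.int8)
        H[rng.random(H.shape) < 0.1] = MISSING
        target = rng.integers(0, 2, size=n_sites).astype(np.int8)
        target[rng.random(n_sites) < 0.5] = MISSING
        lam = float(rng.uniform(0.001, 0.4))
        config = ImputationConfig(k_hap=K, copying_error=lam)
        p, _ = impute_sample(target, panel_from_matrix(H), config)
        expected = naive_posteriors(target, H, lam)
        assert p == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_smaller_lambda_favours_nearest_haplotype(self, seed):
        """Decreasing lambda increases the posterior probability of the
        nearest haplotype's allele at every untyped site."""
        rng = np.random.default_rng(seed)
        n_sites, K = 20, 8
        H = rng.integers(0, 2, size=(n_sites, K)).astype(np.int8)
        target = H[:, 0].copy()
        flip = rng.choice(n_sites, size=2, replace=False)
        target[flip] = 1 - target[flip]
        untyped = rng.choice(n_sites, size=5, replace=False)
        target[untyped] = MISSING
        panel = panel_from_matrix(H)
        # identify the nearest haplotype at lambda-independent Hamming distance
        typed = target != MISSING
        dist = ((H[typed] != target[typed][:, None])).sum(axis=0)
        nearest = int(np.argmin(dist))
        p_hi, _ = impute_sample(target, panel, ImputationConfig(k_hap=K, copying_error=0.2))
        p_lo, _ = impute_sample(target, panel, ImputationConfig(k_hap=K, copying_error=0.02))
        for s in untyped:
            want_alt = H[s, nearest] == 1
            if want_alt:
                assert p_lo[s] >= p_hi[s] - 1e-12
            else:
                assert p_lo[s] <= p_hi[s] + 1e-12

    def test_unique_match_recovered_at_small_lambda(self):
        rng = np.random.default_rng(42)
        H = rng.integers(0, 2, size=(30, 10)).astype(np.int8)
        target = H[:, 3].copy()
        untyped = rng.choice(30, size=10, replace=False)
        target[untyped] = MISSING
        config = ImputationConfig(k_hap=10, copying_error=0.01)
        p, _ = impute_sample(target, panel_from_matrix(H), config)
        calls = np.array([hard_call(x) for x in p])
        assert np.array_equal(calls[untyped], H[untyped, 3])


class TestInfoScore:
    def test_certain_posteriors_score_one(self):
        assert info_score(np.array([1.0, 0.0, 1.0, 1.0])) == 1.0

    def test_constant_posteriors_score_zero(self):
        assert info_score(np.full(7, 0.42)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # p = (1, 0.5): 1 - 0.25 / (2 * 0.75 * 0.25) = 1/3
        assert info_score(np.array([1.0, 0.5])) == pytest.approx(1 / 3, rel=1e-12)

    def test_monomorphic_site_scores_one(self):
        assert info_score(np.zeros(5)) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            info_score(np.array([]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            info_score(np.array([0.5, 1.2]))


class TestInfoFilterAndHardCalls:
    def _result(self, info, typed):
        from mitopanel.imputation import ImputationResult

        n = len(info)
        return ImputationResult(
            positions=np.arange(1, n + 1),
            ref_alleles=["A"] * n, alt_alleles=["G"] * n, sample_ids=["t"],
            p_alt=np.full((n, 1), 0.5),
            typed_sites=np.array(typed),
            observed_mask=np.array(typed)[:, None],
            info=np.array(info, dtype=float),
            filtered=np.zeros(n, dtype=bool),
            hard_calls=np.zeros((n, 1), dtype=np.int8),
        )

    def test_boundary_inclusive_exclusion(self):
        res = apply_info_filter(self._result([0.3, 0.31, 1.0], [False] * 3), 0.3)
        assert list(res.filtered) == [True, False, False]

    def test_typed_sites_never_filtered(self):
        res = apply_info_filter(self._result([0.0, 0.2], [True, True]), 0.3)
        assert not res.filtered.any()

    def test_hard_call_tie_goes_to_ref(self):
        assert hard_call(0.5) == 0
        assert hard_call(0.6) == 1
        assert hard_call(0.4) == 0


class TestEstimators:
    def test_sklearn_params_round_trip(self):
        imp = HaplotypeImputer(k_hap=100, copying_error=0.05)
        params = imp.get_params()
        assert params["k_hap"] == 100
        cloned = clone(imp)
        assert cloned.get_params() == params
        cloned.set_params(k_hap=250)
        assert cloned.k_hap == 250

    def test_unfitted_predict_rejected(self):
        typed = TypedGenotypes(sample_ids=["t"], positions=np.array([1]),
                               alleles=np.array([["A"]]))
        with pytest.raises(ValueError, match="not fitted"):
            HaplotypeImputer().predict(typed)

    def test_self_imputation_returns_input(self, truth_panel, target_ids):
        """Typing every site reproduces the observed alleles."""
        from mitopanel.chip_sim import ChipDefinition, mask_to_chip

        chip = ChipDefinition("all", truth_panel.positions.copy())
        typed = mask_to_chip(truth_panel, chip, list(target_ids[:5]))
        ref_ids = [s for s in truth_panel.sample_ids if s not in set(target_ids)]
        imp = HaplotypeImputer(k_hap=50).fit(truth_panel.subset_samples(ref_ids))
        result = imp.predict(typed)
        bi = truth_panel.subset_samples(list(target_ids[:5])).to_biallelic()
        observed = bi.haplotypes != MISSING
        assert np.array_equal(
            result.hard_calls[observed], bi.haplotypes[observed]
        )

    def test_fitted_attributes(self, reference_panel):
        imp = HaplotypeImputer(k_hap=100).fit(reference_panel)
        assert imp.n_haplotypes_ == reference_panel.n_samples
        assert imp.copying_error_ == pytest.approx(default_copying_error(100))

    def test_baseline_predicts_panel_frequency(self, reference_panel, truth_panel, target_ids):
        from mitopanel.chip_sim import ChipDefinition, mask_to_chip

        chip = ChipDefinition("half", truth_panel.positions[::2].copy())
        typed = mask_to_chip(truth_panel, chip, list(target_ids[:4]))
        base = MajorAlleleImputer().fit(reference_panel).predict(typed)
        untyped = ~base.typed_sites
        expected = base.p_alt[untyped, 0]
        for j in range(1, 4):
            assert np.array_equal(base.p_alt[untyped, j], expected)
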