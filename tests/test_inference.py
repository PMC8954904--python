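import numpy as np
import pytest

from sfsdemog.demography import build_null_model
from sfsdemog.engine import ExpectedSFS, draw_sfs, expected_sfs
from sfsdemog.inference import (
    FitResult,
    aic,
    compare_models,
    composite_log_likelihood,
    fit_model,
    fit_models,
    max_observed_likelihood,
)
from sfsdemog.sfs import SpectrumData


def make_expected(probs, n_chrom, folded=True):
    return ExpectedSFS(
        probs=np.asarray(probs, dtype=float),
        n_chromosomes=n_chrom,
        mu=2.5e-8,
        folded=folded,
        n_sims=10_000,
    )


class TestCompositeLikelihood:
    def test_hand_computed_example(self):
        obs = SpectrumData([90.0, 6.0, 4.0], folded=True, n_chromosomes=4)
        exp = make_expected([0.9, 0.06, 0.04], 4)
        ll10 = composite_log_likelihood(obs, exp)
        assert ll10 * np.log(10) == pytest.approx(-39.238, abs=1e-3)
        assert ll10 == pytest.approx(-17.042, abs=1e-3)

    def test_saturated_model_attains_observed_maximum(self):
        obs = SpectrumData([80.0, 15.0, 5.0], folded=True, n_chromosomes=4)
        exp = make_expected([0.80, 0.15, 0.05], 4)
        assert composite_log_likelihood(obs, exp) == pytest.approx(
            max_observed_likelihood(obs), rel=1e-12
        )

    def test_masked_class_does_not_contribute(self):
        mask = [False, True, False]
        a = SpectrumData([90.0, 6.0, 4.0], folded=True, n_chromosomes=4, mask=mask)
        b = SpectrumData([90.0, 600.0, 4.0], folded=True, n_chromosomes=4, mask=mask)
        exp = make_expected([0.9, 0.06, 0.04], 4)
        assert composite_log_likelihood(a, exp) == pytest.approx(
            composite_log_likelihood(b, exp), rel=1e-12
        )

    def test_entropy_bound(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=5).astype(float)
            if counts.sum() == 0:
                continue
            obs = SpectrumData(counts, folded=True, n_chromosomes=8)
            probs = rng.random(5) + 1e-3
            exp = make_expected(probs / probs.sum(), 8)
            assert composite_log_likelihood(obs, exp) <= max_observed_likelihood(obs) + 1e-9

    def test_shape_mismatch(self):
        obs = SpectrumData([1.0, 2.0, 3.0], folded=True, n_chromosomes=4)
        with pytest.raises(ValueError):
            composite_log_likelihood(obs, make_expected([0.5, 0.3, 0.1, 0.05, 0.05], 8))


class TestMaxObservedLikelihood:
    def test_single_class_saturated(self):
        obs = SpectrumData([100.0, 0.0, 0.0], folded=True, n_chromosomes=4)
        assert max_observed_likelihood(obs) == pytest.approx(0.0)

    def test_even_split(self):
        obs = SpectrumData([50.0, 50.0, 0.0], folded=True, n_chromosomes=4)
        assert max_observed_likelihood(obs) == pytest.approx(-30.103, abs=1e-3)


class TestAIC:
    def test_full_scale_worked_examples(self):
        # log10 likelihoods and AICs from the full-scale model comparison
        assert aic(-882_361.6, 3) == pytest.approx(4_063_431, abs=2)
        assert aic(-882_378.8, 1) == pytest.approx(4_063_506, abs=2)

    def test_degenerate(self):
        assert aic(0.0, 0) == 0.0

    def test_parameter_penalty(self):
        assert aic(-10.0, 3) - aic(-10.0, 1) == pytest.approx(4.0)


def _fit_result(name, aic_value, k_params, fingerprint="fp"):
    return FitResult(
        model_name=name,
        estimates={f"p{i}": 1.0 for i in range(k_params)},
        log10_cl=-1.0,
        delta_lhood=0.0,
        aic=aic_value,
        n_replicates=1,
        n_loops=1,
        n_sims=1,
        seed=1,
        best_replicate_index=0,
        obs_fingerprint=fingerprint,
    )


class TestCompareModels:
    def test_prefers_lower_aic(self):
        comp = compare_models(
            [_fit_result("bottleneck", 4_063_431, 3), _fit_result("null", 4_063_506, 1)]
        )
        assert comp.preferred == "bottleneck"
        assert comp.delta_aic()["null"] == pytest.approx(75.0)

    def test_tie_broken_toward_fewer_parameters(self):
        comp = compare_models(
            [_fit_result("bottleneck", 100.0, 3), _fit_result("null", 100.0, 1)]
        )
        assert comp.preferred == "null"

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError):
            compare_models([_fit_result("null", 1.0, 1)])

    def test_different_observed_data_rejected(self):
        with pytest.raises(ValueError):
            compare_models(
                [_fit_result("a", 1.0, 1, "fp1"), _fit_result("b", 2.0, 1, "fp2")]
            )


class TestFitModel:
    def test_null_parameter_recovery(self, rng):
        # observed spectrum placed exactly at the expected SFS of N = 20000
        truth = build_null_model(20_000.0)
        exp = expected_sfs(truth, 20, 2.5e-8, 100_000, rng)
        obs = SpectrumData(exp.probs * 1e7, folded=True, n_chromosomes=20)
        fit = fit_model(obs, "null", n_replicates=10, n_loops=30, n_sims=20_000, rng=rng)
        assert fit.estimates["Ne_post"] == pytest.approx(20_000.0, rel=0.05)
        assert fit.delta_lhood >= -1e-6

    def test_reproducible_under_master_seed(self, rng):
        truth = build_null_model(8_000.0)
        exp = expected_sfs(truth, 12, 2.5e-8, 20_000, rng)
        obs = draw_sfs(exp, 500_000, rng)
        fits = [
            fit_model(obs, "null", n_replicates=2, n_loops=8, n_sims=3_000,
                      rng=np.random.default_rng(99))
            for _ in range(2)
        ]
        assert fits[0] == fits[1]

    def test_nested_families_on_small_data(self, rng):
        # a richer family can always match the null's composite likelihood
        from sfsdemog.demography import build_bottleneck_model

        truth = build_bottleneck_model(8_000.0, 300.0, 16_000.0)
        exp = expected_sfs(truth, 20, 2.5e-8, 50_000, rng)
        obs = draw_sfs(exp, 2_000_000, rng)
        comp = fit_models(obs, n_replicates=3, n_loops=15, n_sims=5_000, rng=rng)
        assert comp["bottleneck"].log10_cl >= comp["null"].log10_cl - 0.5
        for fit in comp.fits:
            assert all(v >= 2.0 for v in fit.estimates.values())

    def test_unknown_family_rejected(self, rng):
        obs = SpectrumData(np.ones(11), folded=True, n_chromosomes=20)
        with pytest.raises(ValueError):
            fit_model(obs, "three-epoch-island", rng=rng)

    def test_unfolded_observed_rejected(self, rng):
        obs = SpectrumData(np.ones(21), folded=False, n_chromosomes=20)
        with pytest.raises(ValueError):
            fit_model(obs, "null", rng=rng)
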