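"""Pareto+Beta VAF mixture: EM behaviour, ICL and model selection."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import tinc
from tinc.mobster_fit import (
    count_free_params,
    entropy_term,
    icl_score,
    responsibilities_from_params,
)
from tinc.synthetic import _truncated_pareto


def _beta_draws(rng, mean, precision, n):
    return rng.beta(mean * precision, (1 - mean) * precision, size=n)


def reference_icl(fit: tinc.MobsterFit, vafs) -> float:
    """Brute-force ICL recomputation from the stored parameters, using scipy
    distributions directly (independent of the fitter's density code)."""
    x = np.clip(np.asarray(vafs, float), 1e-9, 1 - 1e-9)
    dens = np.zeros((x.size, fit.n_components))
    for j, (m, p) in enumerate(fit.betas):
        dens[:, j] = stats.beta.pdf(x, m * p, (1 - m) * p)
    if fit.tail_present:
        # Pareto Type-I with pdf shape*scale^shape / x^(shape+1) on [scale, inf)
        dens[:, -1] = stats.pareto.pdf(x, fit.tail_shape, scale=fit.tail_scale)
    mix = dens @ fit.pi
    loglik = float(np.sum(np.log(mix)))
    z = dens * fit.pi / mix[:, None]
    ent = -float(np.sum(np.where(z > 0, z * np.log(z), 0.0)))
    n_params = 2 * fit.k + (1 if fit.tail_present else 0) + (fit.n_components - 1)
    return -2 * loglik + n_params * np.log(x.size) + ent


class TestFitRecovery:
    def test_single_beta_cluster(self, rng):
        x = _beta_draws(rng, 0.45, 100, 1000)
        fit = tinc.fit_mobster(x, tail="off", seed=1)
        assert fit.k == 1 and not fit.tail_present
        assert fit.betas[0][0] == pytest.approx(0.45, abs=0.02)

    def test_tail_plus_clonal(self, rng):
        x = np.concatenate([
            _truncated_pareto(rng, 2.0, 0.05, 1.0, 800),
            _beta_draws(rng, 0.45, 100, 1200),
        ])
        fit = tinc.fit_mobster(x, tail="auto", seed=1)
        assert fit.tail_present
        assert fit.betas[0][0] == pytest.approx(0.45, abs=0.02)

    def test_degenerate_identical_vafs(self):
        fit = tinc.fit_mobster(np.full(200, 0.5), seed=0)
        assert fit.k == 1 and not fit.tail_present
        assert fit.betas[0][0] == pytest.approx(0.5, abs=1e-3)

    def test_too_few_observations(self):
        with pytest.raises(tinc.DeconvolutionError):
            tinc.fit_mobster([0.4] * 10, seed=0)

    def test_model_selection_recovery_suite(self):
        """(k, tail) recovered on >=90% of simulated 2000-point datasets."""
        scenarios = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            scenarios.append((rng.beta(45, 55, 2000), 1, False))
            scenarios.append((
                np.concatenate([
                    _truncated_pareto(rng, 2.0, 0.05, 1.0, 800),
                    rng.beta(45, 55, 1200),
                ]), 1, True))
            scenarios.append((
                np.concatenate([rng.beta(45, 55, 1000), rng.beta(20, 80, 1000)]),
                2, False))
        hits = 0
        for x, k_true, tail_true in scenarios:
            fit = tinc.fit_mobster(x, seed=0, restarts=3)
            hits += int(fit.k == k_true and fit.tail_present == tail_true)
        assert hits / len(scenarios) >= 0.9


class TestIcl:
    def test_one_hot_entropy_is_zero(self):
        z = np.eye(4)
        assert entropy_term(z) == 0.0

    def test_two_equal_components_entropy(self):
        # 10 points split 50/50 between two components: entropy = 10 log 2
        z = np.full((10, 2), 0.5)
        assert entropy_term(z) == pytest.approx(10 * np.log(2))
        assert icl_score(-5.0, 3, 10, z) == pytest.approx(
            10.0 + 3 * np.log(10) + 10 * np.log(2))

    def test_icl_matches_bruteforce_recomputation(self, rng):
        x = np.concatenate([
            _truncated_pareto(rng, 2.0, 0.05, 1.0, 400),
            _beta_draws(rng, 0.45, 100, 600),
        ])
        fit = tinc.fit_mobster(x, seed=3)
        assert fit.icl == pytest.approx(reference_icl(fit, x), rel=1e-6)

    def test_param_count(self):
        assert count_free_params(1, False) == 2      # one Beta, pi fixed
        assert count_free_params(2, True) == 2 * 2 + 1 + 2


class TestResponsibilities:
    def test_rows_sum_to_one(self, contaminated_result):
        fit = contaminated_result.mobster
        z = tinc.responsibilities(fit, [s.t_vaf for s in contaminated_result.used_snvs])
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-9)

    def test_support_constraint_below_tail_scale(self):
        z = responsibilities_from_params(
            np.array([0.02, 0.45]),
            betas=[(0.45, 100.0)],
            tail=(2.0, 0.05),
            pi=np.array([0.6, 0.4]),
        )
        assert z[0, 1] == 0.0          # below the Pareto scale: tail density 0
        assert z[1, 0] > 0.99          # inside the clonal bulk

    def test_one_component_all_ones(self):
        z = responsibilities_from_params(
            np.array([0.1, 0.5, 0.9]), betas=[(0.5, 50.0)], tail=None,
            pi=np.array([1.0]))
        np.testing.assert_allclose(z, 1.0)


class TestEMProperties:
    def test_loglik_monotone(self, rng):
        x = np.concatenate([_beta_draws(rng, 0.45, 100, 500),
                            _beta_draws(rng, 0.2, 100, 500)])
        fit = tinc.fit_mobster(x, seed=5)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-7)

    def test_permutation_invariance(self, rng):
        x = np.concatenate([
            _truncated_pareto(rng, 2.0, 0.05, 1.0, 300),
            _beta_draws(rng, 0.45, 100, 700),
        ])
        fit_a = tinc.fit_mobster(x, seed=2)
        perm = rng.permutation(x.size)
        fit_b = tinc.fit_mobster(x[perm], seed=2)
        assert fit_a.k == fit_b.k and fit_a.tail_present == fit_b.tail_present
        np.testing.assert_allclose(
            [m for m, _ in fit_a.betas], [m for m, _ in fit_b.betas], atol=1e-9)
        np.testing.assert_allclose(fit_a.pi, fit_b.pi, atol=1e-9)
        np.testing.assert_allclose(fit_a.z[perm], fit_b.z, atol=1e-9)
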