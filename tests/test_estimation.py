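import numpy as np
import pandas as pd
import pytest

from zganet.estimation import (
    CHI2_95_1DF,
    ObjectiveSpec,
    l2_prior_penalty,
    multistart_fit,
    neg2_loglik,
    profile_likelihood,
)
from zganet.mini_models import MiniModelParams, RegulationScenario, simulate_target
from zganet.objectives import build_mini_objective

LOG2PI = np.log(2 * np.pi)


class TestNeg2LogLik:
    def test_perfect_fit_leaves_only_normalization(self):
        y = np.arange(10.0)
        sigma = 2.0
        assert neg2_loglik(y, y, sigma) == pytest.approx(10 * np.log(2 * np.pi * sigma**2))

    def test_unit_standardized_residual_adds_one(self):
        sigma = 3.0
        base = neg2_loglik([0.0], [0.0], sigma)
        assert neg2_loglik([0.0], [sigma], sigma) - base == pytest.approx(1.0)

    def test_data_term_is_quadratic_in_residuals(self):
        y = np.zeros(5)
        r = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        sigma = 1.5
        norm = 5 * np.log(2 * np.pi * sigma**2)
        small = neg2_loglik(y, r, sigma) - norm
        big = neg2_loglik(y, 2 * r, sigma) - norm
        assert big == pytest.approx(4 * small)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="not aligned"):
            neg2_loglik(np.zeros(3), np.zeros(4), 1.0)

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            neg2_loglik(np.zeros(2), np.zeros(2), 0.0)


class TestPrior:
    def test_center_is_zero(self):
        assert l2_prior_penalty([0.0]) == 0.0

    @pytest.mark.parametrize("decades", [3.0, -3.0])
    def test_three_decades_contribute_one(self, decades):
        assert l2_prior_penalty([decades]) == pytest.approx(1.0)

    def test_objective_decomposes_into_data_term_plus_prior(self):
        fn = lambda th: float(np.sum((th - 1.0) ** 2))
        spec = ObjectiveSpec(fn=fn, param_names=["a", "b"], include_prior=True)
        th = np.array([0.5, -2.0])
        assert spec.value(th) == pytest.approx(fn(th) + l2_prior_penalty(th))
        assert spec.value(th, with_prior=False) == pytest.approx(fn(th))

    def test_duplicate_parameter_names_rejected(self):
        with pytest.raises(ValueError, match="exactly once"):
            ObjectiveSpec(fn=lambda th: 0.0, param_names=["a", "a"])


class TestMultistart:
    def quad(self):
        target = np.array([0.5, -1.0, 2.0])
        return ObjectiveSpec(fn=lambda th: float(np.sum((th - target) ** 2)), param_names=list("xyz"), include_prior=False), target

    def test_converged_runs_reach_analytic_minimum(self):
        obj, target = self.quad()
        coll = multistart_fit(obj, n_starts=12, start_box=(-3, 3), seed=5)
        assert coll.best.objective < 1e-6
        assert coll.best.params_log10 == pytest.approx(target, abs=1e-3)
        for r in coll.results:
            if r.converged:
                assert r.objective < 1e-6

    def test_same_seed_reproduces_starts_and_waterfall(self):
        obj, _ = self.quad()
        a = multistart_fit(obj, n_starts=6, seed=11)
        b = multistart_fit(obj, n_starts=6, seed=11)
        assert np.array_equal(np.vstack([r.start_log10 for r in a.results]), np.vstack([r.start_log10 for r in b.results]))
        assert np.array_equal(a.waterfall, b.waterfall)

    def test_waterfall_sorted_and_best_is_first(self):
        obj, _ = self.quad()
        coll = multistart_fit(obj, n_starts=8, seed=2)
        w = coll.waterfall
        assert np.all(np.diff(w) >= 0)
        assert w[0] == pytest.approx(coll.best.objective)
        assert 1 <= coll.cluster_size <= w.size

    def test_starts_respect_box(self):
        obj, _ = self.quad()
        box = np.array([[-1, 0.0], [0.5, 1.5], [-2, -1]])
        coll = multistart_fit(obj, n_starts=10, start_box=box, seed=3)
        starts = np.vstack([r.start_log10 for r in coll.results])
        assert np.all(starts >= box[:, 0]) and np.all(starts <= box[:, 1])

    def test_invalid_start_count_rejected(self):
        obj, _ = self.quad()
        with pytest.raises(ValueError, match="n_starts"):
            multistart_fit(obj, n_starts=0)


class TestProfileLikelihood:
    def test_quadratic_confidence_interval_matches_closed_form(self):
        s = 0.5
        obj = ObjectiveSpec(fn=lambda th: ((th[0] - 2.0) / s) ** 2, param_names=["theta"], include_prior=False)
        coll = multistart_fit(obj, n_starts=6, start_box=(-3, 3), seed=1)
        pr = profile_likelihood(coll, "theta", grid_spec=(0.0, 4.0, 201))
        half = s * np.sqrt(CHI2_95_1DF)
        assert pr.identifiable
        assert pr.ci_lower == pytest.approx(2.0 - half, rel=0.01)
        assert pr.ci_upper == pytest.approx(2.0 + half, rel=0.01)
        assert pr.ci_lower <= pr.mle_value <= pr.ci_upper

    def test_flat_direction_flagged_non_identifiable(self):
        obj = ObjectiveSpec(fn=lambda th: (th[0] - 1.0) ** 2 + 0.0 * th[1], param_names=["a", "b"], include_prior=False)
        coll = multistart_fit(obj, n_starts=4, seed=0)
        pr = profile_likelihood(coll, "b")
        assert not pr.identifiable
        assert pr.ci_lower == -np.inf and pr.ci_upper == np.inf

    def test_profile_value_at_mle_equals_best_objective(self):
        obj = ObjectiveSpec(fn=lambda th: (th[0] - 1.0) ** 2 + (th[1] + 0.5) ** 2, param_names=["a", "b"], include_prior=False)
        coll = multistart_fit(obj, n_starts=6, seed=4)
        pr = profile_likelihood(coll, "a", grid_spec=(0.0, 2.0, 41))
        assert pr.best_objective == pytest.approx(coll.best.objective, abs=1e-6)
        assert np.nanmin(pr.profile) >= pr.best_objective - 1e-6

    def test_profile_excludes_prior(self):
        # with the prior included in fitting, the profile still reports the
        # pure data term
        obj = ObjectiveSpec(fn=lambda th: (th[0] - 2.0) ** 2, param_names=["a"], include_prior=True)
        coll = multistart_fit(obj, n_starts=4, seed=0)
        pr = profile_likelihood(coll, "a", grid_spec=(1.0, 3.0, 81))
        assert pr.best_objective == pytest.approx(0.0, abs=1e-6)


class TestRecoveryWithNoise:
    def test_estimates_covered_by_own_profile_intervals(self, input_curves):
        """On noisy synthetic targets the true synthesis rate falls inside its
        95% profile CI in >= 85% of 20 seeded replicates."""
        sc = RegulationScenario(+1, 0, 0)
        true = MiniModelParams(v=100.0, d=1.0, K_P=200.0, h=5.0)
        t = np.linspace(2.5, 6, 8)
        curves = {c: simulate_target(sc, true, input_curves, c, t) for c in input_curves.conditions}
        cmax = max(float(c.max()) for c in curves.values())
        inside = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            rows = []
            for c, vals in curves.items():
                for _ in range(3):
                    noisy = np.clip(vals + rng.normal(0, 0.05 * cmax, t.size), 0, None)
                    rows += [{"condition": c, "time": t[k], "value": noisy[k]} for k in range(t.size)]
            obj = build_mini_objective(sc, input_curves, pd.DataFrame(rows))
            coll = multistart_fit(obj, n_starts=4, seed=rep, maxiter=120)
            v_hat = coll.best.params_log10[0]
            pr = profile_likelihood(coll, "v", grid_spec=(v_hat - 0.6, v_hat + 0.6, 25))
            inside += pr.ci_lower <= np.log10(true.v) <= pr.ci_upper
        assert inside >= 17
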