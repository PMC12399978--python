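import numpy as np
import pytest

from synemg.activation import ActivationParams
from synemg.calibration import (CalibrationConfig, calibrate, objective_J,
                                objective_from_moments, pack_parameters,
                                tracking_metrics, validate)
from synemg.optimize import AnnealingSettings, simulated_anneal


class TestObjective:
    def test_zero_for_perfect_tracking(self):
        m = np.random.default_rng(0).random((5, 100, 4))
        assert objective_from_moments(m, m) == 0.0

    def test_constant_offset_closed_form(self):
        exp = np.random.default_rng(1).random((5, 100, 4))
        delta = 0.37
        # 5 cycles x 4 DOFs, each contributing mean(delta^2) = delta^2
        assert objective_from_moments(exp + delta, exp) == pytest.approx(20 * delta**2)

    def test_additive_over_cycles_and_dofs(self):
        rng = np.random.default_rng(2)
        exp = rng.random((4, 50, 3))
        mod = exp + rng.random((4, 50, 3))
        total = objective_from_moments(mod, exp)
        parts = sum(objective_from_moments(mod[c:c + 1, :, i:i + 1],
                                           exp[c:c + 1, :, i:i + 1])
                    for c in range(4) for i in range(3))
        assert total == pytest.approx(parts)

    def test_noise_raises_objective_by_its_variance(self):
        rng = np.random.default_rng(3)
        exp = rng.random((5, 100, 4))
        sigma = 0.2
        js = [objective_from_moments(exp + rng.normal(0, sigma, exp.shape), exp)
              for _ in range(200)]
        assert np.mean(js) == pytest.approx(20 * sigma**2, rel=0.05)

    def test_non_finite_moments_reported(self):
        exp = np.zeros((1, 10, 2))
        mod = exp.copy()
        mod[0, 3, 1] = np.nan
        with pytest.raises(FloatingPointError, match="cycle 0"):
            objective_from_moments(mod, exp)


class TestObjectiveAtTruth:
    def test_noise_free_truth_is_global_minimum(self, noise_free_case):
        subject, ds = noise_free_case
        x = pack_parameters(subject.nominal_table(), subject.activation)
        J = objective_J(x, subject.model(), subject.nominal_table(), ds, range(5))
        assert J <= 1e-12


class TestSimulatedAnnealing:
    def test_deterministic_and_within_bounds(self):
        fun = lambda x: float(np.sum((x - 0.3) ** 2))
        lo, hi = np.zeros(4), np.ones(4)
        s = AnnealingSettings(max_evals=600, n_per_temp=20, cooling=0.8)
        r1 = simulated_anneal(fun, np.full(4, 0.9), lo, hi, seed=5, settings=s)
        r2 = simulated_anneal(fun, np.full(4, 0.9), lo, hi, seed=5, settings=s)
        assert np.array_equal(r1.x, r2.x)
        assert np.all((r1.x >= lo) & (r1.x <= hi))
        assert r1.fun < 0.01

    def test_trace_is_non_increasing(self):
        fun = lambda x: float(np.sum(x**2))
        r = simulated_anneal(fun, np.full(3, 0.8), np.zeros(3), np.ones(3),
                             seed=1, settings=AnnealingSettings(max_evals=300))
        assert np.all(np.diff(r.trace) <= 0)

    def test_extra_candidate_never_lost(self):
        # objective minimized exactly at the injected candidate
        fun = lambda x: float(np.sum(x**2))
        r = simulated_anneal(fun, np.full(2, 0.9), np.zeros(2), np.ones(2),
                             seed=2, settings=AnnealingSettings(max_evals=50),
                             extra_candidates=[np.zeros(2)])
        assert r.fun == 0.0


@pytest.fixture(scope="module")
def short_result(default_case):
    subject, ds = default_case
    nom = subject.nominal_table()
    start = nom.copy()
    start[:3, 0] *= 1.3
    cfg = CalibrationConfig(seed=7, annealing=AnnealingSettings(max_evals=600))
    return subject, ds, calibrate(ds, subject.model(), nom, cfg, start_mt=start)


class TestCalibrate:
    def test_parameters_within_boxes(self, short_result):
        subject, _, res = short_result
        nom = subject.nominal_table()
        mt = np.array([[m.F0m, m.l0m, m.lst] for m in res.model.muscles])
        assert np.all(mt >= nom[:, :3] * 0.5 - 1e-12)
        assert np.all(mt <= nom[:, :3] * 1.5 + 1e-12)
        act = res.model.activation
        assert -3 <= act.A < 0 and abs(act.C1) < 1 and abs(act.C2) < 1
        assert 0.01 <= act.d <= 0.3

    def test_objective_improves_and_trace_monotone(self, short_result):
        _, _, res = short_result
        assert res.J < res.trace[0]
        assert np.all(np.diff(res.trace) <= 0)

    def test_deterministic_for_seed(self, default_case, short_result):
        subject, ds, res = short_result
        nom = subject.nominal_table()
        start = nom.copy()
        start[:3, 0] *= 1.3
        cfg = CalibrationConfig(seed=7, annealing=AnnealingSettings(max_evals=600))
        res2 = calibrate(ds, subject.model(), nom, cfg, start_mt=start)
        assert np.array_equal(res.x, res2.x)
        assert res.J == res2.J

    def test_validation_disjointness_enforced(self, short_result):
        _, ds, res = short_result
        with pytest.raises(ValueError, match="overlap"):
            validate(res, ds, range(4, 9))

    def test_validation_consistency_with_tracking(self, short_result):
        _, ds, res = short_result
        direct = tracking_metrics(res.model, ds, range(5, 10))
        via = validate(res, ds, range(5, 10))
        assert np.allclose(direct["pct_rmse"], via["pct_rmse"])

    def test_metrics_table_layout(self, short_result):
        _, _, res = short_result
        assert list(res.metrics["dof"]) == ["arm_add_abd", "arm_flex_ext",
                                            "arm_int_ext_rot", "elbow_flex_ext"]
        for col in ("pct_rmse", "r", "pct_mae"):
            assert col in res.metrics.columns
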