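"""Subject-specific parameter calibration by joint-moment tracking.

Calibrated parameters (34 in total, shared curve constants fixed):
  * per muscle: maximum isometric force F0m, optimal fiber length l0m,
    tendon slack length lst — each bounded within +/-50% of its nominal
    (generic-model) value;
  * per subject: activation nonlinearity A in [-3, 0), recursion
    coefficients C1, C2 in (-1, 1), electromechanical delay d in
    [0.01, 0.3] s, with initials A=-0.1, C1=0.5, C2=-0.5, d=0.05.

The objective is the sum over calibration cycles and degrees of freedom of
the per-series mean squared moment-tracking error,

    J = sum_c sum_i (1/n) sum_p (M_mod[c,i,p] - M_exp[c,i,p])^2,

minimized by seeded simulated annealing.  Validation re-evaluates the
fitted model on held-out cycles and reports %RMSE, Pearson r and %MAE per
DOF (per cycle, then averaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation import ActivationParams
from .evaluation import pct_mae, pct_rmse, pearson_r
from .model import EmgDrivenModel
from .optimize import AnnealingSettings, AnnealingResult, simulated_anneal
from .synthetic import SyntheticDataset

__all__ = ["CalibrationConfig", "CalibrationResult", "objective_J",
           "objective_from_moments", "calibrate", "validate"]

# activation-parameter boxes; A and the C's are kept strictly inside their
# open intervals so the recursion stays stable and the nonlinearity defined
_ACT_LOWER = np.array([-3.0, -0.999, -0.999, 0.01])
_ACT_UPPER = np.array([-1e-3, 0.999, 0.999, 0.3])
_ACT_INITIALS = np.array([-0.1, 0.5, -0.5, 0.05])


@dataclass(frozen=True)
class CalibrationConfig:
    """Bounds, initials and annealing budget for one calibration run."""

    n_calibration_cycles: int = 5
    mt_bound_frac: float = 0.5            # +/-50% of nominal for F0m, l0m, lst
    act_initials: tuple = tuple(_ACT_INITIALS)
    seed: int = 0
    annealing: AnnealingSettings = field(
        default_factory=lambda: AnnealingSettings(max_evals=5000))

    def __post_init__(self):
        if self.n_calibration_cycles < 1:
            raise ValueError("need at least one calibration cycle")
        a = np.asarray(self.act_initials)
        if np.any(a < _ACT_LOWER) or np.any(a > _ACT_UPPER):
            raise ValueError("activation initials outside their bounds")


@dataclass
class CalibrationResult:
    model: EmgDrivenModel                 # model with fitted parameters
    x: np.ndarray                         # fitted 34-vector
    J: float
    trace: np.ndarray                     # best-so-far objective
    calibration_cycles: list
    metrics: pd.DataFrame                 # per-DOF tracking metrics (calibration)
    config: CalibrationConfig = None
    annealing: AnnealingResult = None


def objective_from_moments(mod: np.ndarray, exp: np.ndarray) -> float:
    """Sum over cycles and DOFs of the mean squared error per series.

    ``mod``, ``exp`` : (n_cycles, n_points, n_dofs).  The objective is a sum
    of per-series MSEs (no square root), so it decomposes additively over
    cycles and DOFs.
    """
    mod = np.asarray(mod, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if mod.shape != exp.shape:
        raise ValueError("moment arrays must share a shape")
    if not np.all(np.isfinite(mod)):
        c, p, i = np.argwhere(~np.isfinite(mod))[0]
        raise FloatingPointError(
            f"non-finite model moment at cycle {c}, point {p}, DOF {i}")
    return float(np.sum(np.mean((mod - exp) ** 2, axis=1)))


def _unpack(x: np.ndarray, nominal_mt: np.ndarray):
    """34-vector -> ((m, 4) musculotendon table, ActivationParams)."""
    m = nominal_mt.shape[0]
    mt = nominal_mt.copy()
    mt[:, 0] = x[0:m]
    mt[:, 1] = x[m:2 * m]
    mt[:, 2] = x[2 * m:3 * m]
    A, C1, C2, d = x[3 * m:3 * m + 4]
    return mt, ActivationParams(A=A, C1=C1, C2=C2, d=d)


def _bounds(nominal_mt: np.ndarray, frac: float):
    m = nominal_mt.shape[0]
    nom = np.concatenate([nominal_mt[:, 0], nominal_mt[:, 1], nominal_mt[:, 2]])
    lower = np.concatenate([nom * (1 - frac), _ACT_LOWER])
    upper = np.concatenate([nom * (1 + frac), _ACT_UPPER])
    return lower, upper


def objective_J(x: np.ndarray, model: EmgDrivenModel, nominal_mt: np.ndarray,
                dataset: SyntheticDataset, cycles) -> float:
    """Eq-4 style tracking objective for a packed parameter vector."""
    idx = list(cycles)
    mt, act = _unpack(np.asarray(x, dtype=float), nominal_mt)
    trial = model.with_parameters(mt=mt, activation=act)
    mod = trial.moments(dataset.envelopes[idx], dataset.lmt[idx],
                        dataset.moment_arms[idx])
    return objective_from_moments(mod, dataset.ref_moments[idx])


def pack_parameters(mt: np.ndarray, act: ActivationParams) -> np.ndarray:
    return np.concatenate([mt[:, 0], mt[:, 1], mt[:, 2],
                           [act.A, act.C1, act.C2, act.d]])


def calibrate(dataset: SyntheticDataset, model: EmgDrivenModel,
              nominal_mt: np.ndarray, config: CalibrationConfig = None,
              cycles=None, start_mt: np.ndarray = None) -> CalibrationResult:
    """Fit subject parameters on the calibration cycles by annealing.

    ``nominal_mt`` is the (m, 4) table of generic-model nominals that
    anchors the +/-50% boxes; ``start_mt`` (default: the nominals) is the
    starting point.  Activation parameters always start at the standard
    initials.  Deterministic for a fixed seed and config.
    """
    config = config or CalibrationConfig()
    if cycles is None:
        cycles = list(range(config.n_calibration_cycles))
    cycles = list(cycles)
    if len(cycles) != config.n_calibration_cycles:
        raise ValueError("cycle list does not match the configured count")

    nominal_mt = np.asarray(nominal_mt, dtype=float)
    start = pack_parameters(start_mt if start_mt is not None else nominal_mt,
                            ActivationParams(*config.act_initials))
    lower, upper = _bounds(nominal_mt, config.mt_bound_frac)
    start = np.clip(start, lower, upper)

    res = simulated_anneal(
        lambda x: objective_J(x, model, nominal_mt, dataset, cycles),
        start, lower, upper, seed=config.seed, settings=config.annealing)

    mt_fit, act_fit = _unpack(res.x, nominal_mt)
    fitted = model.with_parameters(mt=mt_fit, activation=act_fit)
    metrics = tracking_metrics(fitted, dataset, cycles)
    return CalibrationResult(fitted, res.x, res.fun, res.trace, cycles,
                             metrics, config, res)


def tracking_metrics(model: EmgDrivenModel, dataset: SyntheticDataset,
                     cycles) -> pd.DataFrame:
    """Per-DOF moment-tracking metrics (%RMSE, r, %MAE), mean over cycles."""
    idx = list(cycles)
    mod = model.moments(dataset.envelopes[idx], dataset.lmt[idx],
                        dataset.moment_arms[idx])
    exp = dataset.ref_moments[idx]
    rows = []
    for i, dof in enumerate(dataset.dof_labels):
        per_cycle = [(pct_rmse(exp[c, :, i], mod[c, :, i]),
                      pearson_r(exp[c, :, i], mod[c, :, i]),
                      pct_mae(exp[c, :, i], mod[c, :, i]))
                     for c in range(len(idx))]
        arr = np.asarray(per_cycle)
        rows.append({"dof": dof,
                     "pct_rmse": arr[:, 0].mean(), "pct_rmse_sd": arr[:, 0].std(),
                     "r": arr[:, 1].mean(), "r_sd": arr[:, 1].std(),
                     "pct_mae": arr[:, 2].mean(), "pct_mae_sd": arr[:, 2].std()})
    return pd.DataFrame(rows)


def validate(result: CalibrationResult, dataset: SyntheticDataset,
             cycles) -> pd.DataFrame:
    """Evaluate a calibrated model on held-out cycles.

    The held-out set must be disjoint from the calibration cycles.
    """
    cycles = list(cycles)
    overlap = set(cycles) & set(result.calibration_cycles)
    if overlap:
        raise ValueError(f"validation cycles overlap calibration cycles: {sorted(overlap)}")
    return tracking_metrics(result.model, dataset, cycles)
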