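"""Hill-type musculotendon mechanics with an elastic tendon.

The musculotendon unit is a muscle fiber (active contractile element in
parallel with a passive elastic element) in series with a nonlinear elastic
tendon, at pennation angle ``alpha`` to the tendon line of action.  At every
time frame the fiber length is the root of the force balance

    F_T(l_t) = (F_CE + F_PE) * cos(alpha),

all forces normalized by the maximum isometric force ``F0m``.  The curve
shapes are shared across muscles (dimensionless constants); only ``F0m``,
the optimal fiber length ``l0m``, the tendon slack length ``lst`` and the
pennation at optimum ``alpha0`` are muscle-specific (and calibrated).

Scalar/array curve evaluations live here in plain numpy; the per-frame
equilibrium loop is delegated to the compiled kernels in :mod:`synemg._engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _engine

__all__ = [
    "CurveConstants",
    "MusculotendonParams",
    "MuscleState",
    "active_force_length",
    "passive_force_length",
    "contractile_force",
    "fiber_velocity",
    "tendon_force",
    "tendon_strain",
    "pennation_cos",
    "solve_equilibrium",
]

# Maximum pennation angle admitted by the constant-thickness model (rad).
_PEN_MAX = np.deg2rad(84.3)


@dataclass(frozen=True)
class CurveConstants:
    """Dimensionless Hill-curve constants shared by all muscles.

    Defaults are the standard values for this model family:
    ``Vmax`` maximum contraction velocity (optimal fiber lengths per second),
    ``FlenM`` maximum normalized lengthening force, ``Af`` force-velocity
    shape, ``gamma`` active force-length width, ``KPE``/``eps0M`` passive
    exponential shape and strain at F0m, and the tendon toe/linear constants
    ``Ftoe``, ``eps0T``, ``epstoe``, ``ktoe``, ``klin``.
    """

    Vmax: float = 10.0
    FlenM: float = 1.8
    Af: float = 0.3
    gamma: float = 0.6
    KPE: float = 5.0
    eps0M: float = 0.6
    Ftoe: float = 0.33
    eps0T: float = 0.04
    ktoe: float = 3.0
    # Derived defaults (0.609*eps0T and 1.712/eps0T); recomputed in __post_init__
    # when eps0T is overridden.
    epstoe: float = field(default=0.609 * 0.04)
    klin: float = field(default=1.712 / 0.04)

    def __post_init__(self):
        if self.eps0T != 0.04:
            object.__setattr__(self, "epstoe", 0.609 * self.eps0T)
            object.__setattr__(self, "klin", 1.712 / self.eps0T)
        for name in ("Vmax", "FlenM", "Af", "gamma", "KPE", "eps0M", "Ftoe",
                     "eps0T", "ktoe", "epstoe", "klin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"curve constant {name} must be positive")

    def as_array(self) -> np.ndarray:
        """Pack into the flat float64 layout the compiled kernels expect."""
        return np.array(
            [self.Vmax, self.FlenM, self.Af, self.gamma, self.KPE, self.eps0M,
             self.Ftoe, self.eps0T, self.epstoe, self.ktoe, self.klin],
            dtype=np.float64,
        )


DEFAULT_CONSTANTS = CurveConstants()


@dataclass(frozen=True)
class MusculotendonParams:
    """Muscle-specific Hill parameters plus the shared curve constants."""

    F0m: float
    l0m: float
    lst: float
    alpha0: float = 0.0
    label: str = ""
    constants: CurveConstants = DEFAULT_CONSTANTS

    def __post_init__(self):
        if self.F0m <= 0 or self.l0m <= 0 or self.lst <= 0:
            raise ValueError("F0m, l0m and lst must be positive")
        if not 0.0 <= self.alpha0 < np.pi / 2:
            raise ValueError("alpha0 must lie in [0, pi/2)")

    def with_values(self, **kwargs) -> "MusculotendonParams":
        return replace(self, **kwargs)


@dataclass
class MuscleState:
    """Per-frame solution trajectory of the tendon-fiber equilibrium.

    Arrays are aligned with the input time grid.  ``flagged`` marks frames
    where no bracketing sign change existed and the rigid-tendon fallback
    was used.
    """

    lm: np.ndarray          # fiber length (m)
    lm_bar: np.ndarray      # fiber length / l0m
    lt: np.ndarray          # tendon length (m)
    lt_bar: np.ndarray      # tendon length / lst
    eps_t: np.ndarray       # tendon strain
    vm: np.ndarray          # fiber velocity (l0m/s)
    fl: np.ndarray          # active force-length value
    fce_bar: np.ndarray     # normalized contractile force
    fpe_bar: np.ndarray     # normalized passive force
    ft_bar: np.ndarray      # normalized tendon force
    cos_pen: np.ndarray     # cosine of pennation
    fmt: np.ndarray         # musculotendon force (N)
    flagged: np.ndarray     # bool, rigid-tendon fallback frames


# ---------------------------------------------------------------------------
# Curve evaluations (numpy; mirrored by scalar kernels in _engine)
# ---------------------------------------------------------------------------

def active_force_length(lm_bar, gamma: float = DEFAULT_CONSTANTS.gamma):
    """Gaussian active force-length curve, peak 1 at the optimal length."""
    lm_bar = np.asarray(lm_bar, dtype=float)
    if np.any(lm_bar <= 0):
        raise ValueError("normalized fiber length must be positive")
    return np.exp(-((lm_bar - 1.0) ** 2) / gamma)


def passive_force_length(lm_bar, KPE: float = DEFAULT_CONSTANTS.KPE,
                         eps0M: float = DEFAULT_CONSTANTS.eps0M):
    """Exponential passive force-length curve, clamped at zero below optimum.

    Equals 1 exactly at ``lm_bar = 1 + eps0M`` (fiber strain at which the
    passive element carries F0m).
    """
    lm_bar = np.asarray(lm_bar, dtype=float)
    if np.any(lm_bar <= 0):
        raise ValueError("normalized fiber length must be positive")
    fpe = (np.exp(KPE * (lm_bar - 1.0) / eps0M) - 1.0) / (np.exp(KPE) - 1.0)
    return np.maximum(fpe, 0.0)


def contractile_force(a, fl, vm, constants: CurveConstants = DEFAULT_CONSTANTS):
    """Normalized contractile force from activation, fl and fiber velocity.

    ``vm`` is in optimal fiber lengths per second (negative = shortening).
    Closed-form solution of the two force-velocity branches for the force:
    shortening branch denominator ``b = a*fl + F/Af``, lengthening branch
    ``b = (2 + 2/Af) * (a*fl*FlenM - F) / (FlenM - 1)``, with the effective
    maximum velocity scaled by ``(0.25 + 0.75 a) * Vmax``.
    """
    a = np.asarray(a, dtype=float)
    fl = np.asarray(fl, dtype=float)
    vm = np.asarray(vm, dtype=float)
    c = constants
    k = (0.25 + 0.75 * a) * c.Vmax
    afl = a * fl
    # shortening (vm <= 0)
    f_short = afl * (k + vm) / (k - vm / c.Af)
    f_short = np.maximum(f_short, 0.0)  # |vm| beyond max shortening velocity
    # lengthening (vm > 0)
    cc = (2.0 + 2.0 / c.Af) / (c.FlenM - 1.0)
    f_len = afl * (k + cc * c.FlenM * vm) / (k + cc * vm)
    return np.where(vm <= 0, f_short, f_len)


def fiber_velocity(a, fl, fce_bar, constants: CurveConstants = DEFAULT_CONSTANTS):
    """Inverse force-velocity relation: fiber velocity (l0m/s) from force.

    Raises for forces at/above the lengthening asymptote ``a*fl*FlenM``.
    """
    a = np.asarray(a, dtype=float)
    fl = np.asarray(fl, dtype=float)
    fce_bar = np.asarray(fce_bar, dtype=float)
    c = constants
    afl = a * fl
    if np.any(fce_bar < 0):
        raise ValueError("normalized contractile force must be nonnegative")
    if np.any(fce_bar >= afl * c.FlenM):
        raise ValueError("force at or above the lengthening asymptote a*fl*FlenM")
    b_short = afl + fce_bar / c.Af
    b_len = (2.0 + 2.0 / c.Af) * (afl * c.FlenM - fce_bar) / (c.FlenM - 1.0)
    b = np.where(fce_bar <= afl, b_short, b_len)
    return (0.25 + 0.75 * a) * c.Vmax * (fce_bar - afl) / b


def tendon_force(lt_bar, constants: CurveConstants = DEFAULT_CONSTANTS):
    """Normalized tendon force from normalized tendon length.

    Zero below slack length, exponential toe region up to the transition
    force ``Ftoe``, linear above; the branches meet continuously.
    """
    lt_bar = np.asarray(lt_bar, dtype=float)
    if np.any(lt_bar < 0):
        raise ValueError("normalized tendon length must be nonnegative")
    c = constants
    eps = lt_bar - 1.0
    f_toe = c.Ftoe * (np.exp(c.ktoe * eps / c.epstoe) - 1.0) / (np.exp(c.ktoe) - 1.0)
    f_lin = c.Ftoe + c.klin * (eps - c.epstoe)
    out = np.where(eps <= c.epstoe, f_toe, f_lin)
    return np.maximum(out, 0.0)


def tendon_strain(ft_bar, constants: CurveConstants = DEFAULT_CONSTANTS):
    """Tendon strain from normalized tendon force (inverse of tendon_force)."""
    ft_bar = np.asarray(ft_bar, dtype=float)
    if np.any(ft_bar < 0):
        raise ValueError("tendon force must be nonnegative")
    c = constants
    eps_toe_branch = (c.epstoe / c.ktoe) * np.log1p(
        ft_bar * (np.exp(c.ktoe) - 1.0) / c.Ftoe)
    eps_lin_branch = c.epstoe + (ft_bar - c.Ftoe) / c.klin
    return np.where(ft_bar <= c.Ftoe, eps_toe_branch, eps_lin_branch)


def pennation_cos(lm, params: MusculotendonParams):
    """Cosine of the pennation angle under the constant-thickness model.

    ``sin(pen) * lm = sin(alpha0) * l0m``, with the angle clamped below
    84.3 degrees so the cosine never vanishes.
    """
    lm = np.asarray(lm, dtype=float)
    if np.any(lm <= 0):
        raise ValueError("fiber length must be positive")
    sin_pen = np.sin(params.alpha0) * params.l0m / lm
    sin_pen = np.clip(sin_pen, 0.0, np.sin(_PEN_MAX))
    return np.sqrt(1.0 - sin_pen**2)


# ---------------------------------------------------------------------------
# Per-frame equilibrium
# ---------------------------------------------------------------------------

def solve_equilibrium(a: np.ndarray, lmt: np.ndarray,
                      params: MusculotendonParams, dt: float,
                      force_tol: float = 1e-6) -> MuscleState:
    """Solve the tendon-fiber force balance along a trajectory.

    Parameters
    ----------
    a : activation in [0, 1], one value per frame.
    lmt : musculotendon length (m), same length as ``a``.
    dt : time step of the (pre-normalization) grid, seconds.

    Per frame, the normalized fiber length is the bisection root of
    ``F_T(l_t(lm)) - (F_CE + F_PE) cos(pen)`` on [0.05, 1.8]; fiber velocity
    is the backward difference of the solved fiber length (zero at the first
    frame).  Frames with no bracketing sign change fall back to a
    rigid-tendon estimate and are flagged.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    lmt = np.ascontiguousarray(lmt, dtype=np.float64)
    if a.ndim != 1 or a.shape != lmt.shape:
        raise ValueError("a and lmt must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(lmt)) and np.all(lmt > 0)):
        raise ValueError("musculotendon lengths must be finite and positive")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")

    n = a.shape[0]
    mt = np.array([[params.F0m, params.l0m, params.lst, params.alpha0]])
    out = _engine.solve_cycle(a[:, None], lmt[:, None], dt, mt,
                              params.constants.as_array(), force_tol)
    lm, vm, fce, fpe, ft, cospen, flagged = (x[:, 0] for x in out)
    lt = lmt - lm * cospen
    return MuscleState(
        lm=lm, lm_bar=lm / params.l0m, lt=lt, lt_bar=lt / params.lst,
        eps_t=lt / params.lst - 1.0, vm=vm,
        fl=active_force_length(lm / params.l0m, params.constants.gamma),
        fce_bar=fce, fpe_bar=fpe, ft_bar=ft, cos_pen=cospen,
        fmt=ft * params.F0m, flagged=flagged.astype(bool),
    )


def params_table(muscles: Sequence[MusculotendonParams]) -> np.ndarray:
    """Stack per-muscle (F0m, l0m, lst, alpha0) rows for the compiled kernels."""
    return np.array([[m.F0m, m.l0m, m.lst, m.alpha0] for m in muscles],
                    dtype=np.float64)
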