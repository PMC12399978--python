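"""EMG-to-activation dynamics.

A delayed EMG envelope e(t - d) drives a critically-dampable second-order
recursive filter giving neural excitation

    u(t) = alpha * e(t - d) - (C1 + C2) * u(t-1) - C1*C2 * u(t-2),

followed by the nonlinear shaping a = (exp(A*u) - 1) / (exp(A) - 1) mapping
[0, 1] onto [0, 1].  The filter poles are -C1 and -C2, so stability requires
|C1| < 1 and |C2| < 1.  The gain is pinned to unit steady state,
alpha = 1 + (C1 + C2) + C1*C2, so that a constant envelope c yields u = c;
without this constraint the filter gain would be indistinguishable from the
muscles' maximum isometric forces during calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine

__all__ = ["ActivationParams", "excitation_to_neural", "neural_to_activation",
           "apply_delay", "activations_from_envelopes"]


@dataclass(frozen=True)
class ActivationParams:
    """Recursive-filter and nonlinearity coefficients.

    A : nonlinearity shape, in [-3, 0) (more negative = more concave).
    C1, C2 : recursion coefficients, each in (-1, 1).
    d : electromechanical delay in seconds, in [0.01, 0.3].
    """

    A: float = -0.1
    C1: float = 0.5
    C2: float = -0.5
    d: float = 0.05

    def __post_init__(self):
        if abs(self.C1) >= 1 or abs(self.C2) >= 1:
            raise ValueError("unstable recursion: |C1| and |C2| must be < 1")
        if self.A >= 0:
            raise ValueError("A must be negative")
        if self.d < 0:
            raise ValueError("delay must be nonnegative")

    @property
    def alpha(self) -> float:
        """Gain enforcing unit steady state: 1 + (C1 + C2) + C1*C2."""
        return 1.0 + (self.C1 + self.C2) + self.C1 * self.C2


def apply_delay(e: np.ndarray, d: float, dt: float) -> np.ndarray:
    """Shift a time series right by the delay d, rounded to whole samples.

    Applied in the original time domain (seconds), never on the normalized
    cycle grid.  The left edge is padded with the first sample.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = int(round(d / dt))
    if k == 0:
        return np.array(e, dtype=float, copy=True)
    e = np.asarray(e, dtype=float)
    out = np.empty_like(e)
    out[:k] = e[0]
    out[k:] = e[:-k] if k < e.shape[0] else e[0]
    return out


def excitation_to_neural(e: np.ndarray, params: ActivationParams,
                         dt: float) -> np.ndarray:
    """Delayed envelope -> neural excitation via the second-order recursion.

    ``e`` may be (n,) or (n, n_muscles); zero initial conditions.
    """
    e = np.asarray(e, dtype=float)
    squeeze = e.ndim == 1
    if squeeze:
        e = e[:, None]
    ed = np.empty_like(e)
    for j in range(e.shape[1]):
        ed[:, j] = apply_delay(e[:, j], params.d, dt)
    u = _engine.excitation_recursion(np.ascontiguousarray(ed),
                                     params.alpha, params.C1, params.C2)
    return u[:, 0] if squeeze else u


def neural_to_activation(u: np.ndarray, A: float) -> np.ndarray:
    """Nonlinear excitation-to-activation shaping, a in [0, 1].

    u is clipped to [0, 1] first: the exponential map is a bijection of
    [0, 1] only on that domain, and transient overshoot of the recursion
    must not produce activations above 1.
    """
    if A == 0:
        raise ValueError("A must be nonzero (negative); the A->0 limit a = u "
                         "is not enabled implicitly")
    if A > 0:
        raise ValueError("A must be negative")
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return np.expm1(A * u) / np.expm1(A)


def activations_from_envelopes(env: np.ndarray, params: ActivationParams,
                               dt: float, warmup: bool = True) -> np.ndarray:
    """Full activation dynamics over contiguous cycles.

    env : (n_cycles, n_points, n_muscles) envelope array on the original
    uniform time grid.  A copy of the first cycle is prepended as warm-up to
    wash out the zero initial conditions, then discarded.
    """
    env = np.asarray(env, dtype=float)
    if env.ndim != 3:
        raise ValueError("env must be (n_cycles, n_points, n_muscles)")
    ncyc, npts, m = env.shape
    flat = env.reshape(ncyc * npts, m)
    if warmup:
        flat = np.vstack([env[0], flat])
    u = excitation_to_neural(flat, params, dt)
    a = neural_to_activation(u, params.A)
    if warmup:
        a = a[npts:]
    return a.reshape(ncyc, npts, m)


def invert_activation(a: np.ndarray, A: float) -> np.ndarray:
    """Inverse of the nonlinear shaping: excitation u from activation a."""
    a = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    return np.log1p(a * np.expm1(A)) / A
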