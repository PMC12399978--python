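"""End-to-end EMG-driven forward model: envelopes -> activations -> forces -> moments.

Binds the activation dynamics, the per-frame tendon-fiber equilibrium and
the moment-arm projection into one subject-specific model object, operating
on cycle-stacked arrays:

    envelopes, lmt : (n_cycles, n_points, n_muscles)
    moment arms    : (n_cycles, n_points, n_dofs, n_muscles)
    moments        : (n_cycles, n_points, n_dofs)

Cycles are contiguous in time; activation dynamics run on the concatenated
series (with a warm-up copy of the first cycle), while the equilibrium is
solved per cycle with the fiber velocity reset at each cycle's first frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _engine
from .activation import ActivationParams, activations_from_envelopes
from .musculotendon import MusculotendonParams, params_table

__all__ = ["EmgDrivenModel"]


@dataclass
class EmgDrivenModel:
    """A calibrated (or nominal) subject model.

    dt is the time step of the pre-normalization grid in seconds; with
    equal-duration poling and recovery phases the 100-point normalized grid
    is uniform, dt = cycle_duration / 100.
    """

    muscles: Sequence[MusculotendonParams]
    activation: ActivationParams
    dt: float
    force_tol: float = 1e-6

    def __post_init__(self):
        self._mt = params_table(self.muscles)
        self._consts = self.muscles[0].constants.as_array()

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def f0m(self) -> np.ndarray:
        return self._mt[:, 0].copy()

    def with_parameters(self, mt: np.ndarray | None = None,
                        activation: ActivationParams | None = None) -> "EmgDrivenModel":
        """Copy with a new (m, 4) musculotendon table and/or activation params."""
        muscles = self.muscles
        if mt is not None:
            muscles = [replace(mu, F0m=row[0], l0m=row[1], lst=row[2], alpha0=row[3])
                       for mu, row in zip(self.muscles, np.asarray(mt, dtype=float))]
        return EmgDrivenModel(muscles, activation or self.activation,
                              self.dt, self.force_tol)

    # -- forward stages -----------------------------------------------------

    def activations(self, envelopes: np.ndarray) -> np.ndarray:
        """(C, n, m) envelopes -> activations via the activation dynamics."""
        return activations_from_envelopes(envelopes, self.activation, self.dt)

    def solve_states(self, activations: np.ndarray, lmt: np.ndarray,
                     muscle_idx: Sequence[int] | None = None):
        """Per-cycle equilibrium solve; returns (fce, fpe, ft, cos_pen, flagged).

        ``muscle_idx`` restricts the solve to a subset of muscles (columns of
        the inputs must already match that subset).
        """
        activations = np.asarray(activations, dtype=np.float64)
        lmt = np.asarray(lmt, dtype=np.float64)
        mt = self._mt if muscle_idx is None else self._mt[list(muscle_idx)]
        C, n, m = activations.shape
        fce = np.empty((C, n, m)); fpe = np.empty((C, n, m))
        ft = np.empty((C, n, m)); cosp = np.empty((C, n, m))
        flagged = np.zeros((C, n, m), dtype=bool)
        for c in range(C):
            _, _, fc, fp, f, cp, fl = _engine.solve_cycle(
                np.ascontiguousarray(activations[c]),
                np.ascontiguousarray(lmt[c]),
                self.dt, mt, self._consts, self.force_tol)
            fce[c], fpe[c], ft[c], cosp[c], flagged[c] = fc, fp, f, cp, fl
        return fce, fpe, ft, cosp, flagged

    def moments_from_activations(self, activations: np.ndarray, lmt: np.ndarray,
                                 arms: np.ndarray,
                                 muscle_idx: Sequence[int] | None = None) -> np.ndarray:
        """(C, n, m) activations + kinematics -> (C, n, n_dofs) joint moments."""
        fce, fpe, _, cosp, _ = self.solve_states(activations, lmt, muscle_idx)
        f0m = self.f0m if muscle_idx is None else self.f0m[list(muscle_idx)]
        C, n, _ = fce.shape
        out = np.empty((C, n, arms.shape[2]))
        for c in range(C):
            out[c] = _engine.joint_moments_kernel(
                fce[c], fpe[c], cosp[c],
                np.ascontiguousarray(arms[c], dtype=np.float64), f0m)
        return out

    def moments(self, envelopes: np.ndarray, lmt: np.ndarray,
                arms: np.ndarray) -> np.ndarray:
        """Full forward pass from EMG envelopes to joint moments."""
        return self.moments_from_activations(self.activations(envelopes), lmt, arms)
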