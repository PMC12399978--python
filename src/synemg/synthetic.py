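"""Synthetic double-poling subject with known ground truth.

No recordings are distributed with the package, so every pipeline stage is
exercised on a fully synthetic subject that emulates the structure of the
experimental data: 10 upper-limb muscles, 4 shoulder/elbow degrees of
freedom, double-poling cycles of equal poling and recovery duration on the
100-point normalized grid, moment arms with the anatomical sign structure,
and muscle activations built from a small set of nonnegative time-varying
synergy primitives.

Ground truth the generator exposes (and tests rely on):
  * activations are exactly ``W_true @ H_true`` (rank ``n_synergies`` when
    noise-free), with Gaussian-bump primitives mimicking poling-phase bursts;
  * EMG envelopes are the exact inverse of the activation dynamics under the
    subject's true parameters (multiplicative noise added on top), so the
    forward pipeline under true parameters reproduces the activations;
  * musculotendon lengths are the exact path integrals of the moment arms,
    dLMT_j/dt = -sum_i r_ij(q_i) dq_i/dt;
  * reference joint moments are the package's own forward model evaluated
    under the true parameters (additive noise on top), closing the loop:
    with zero noise the calibration objective at the true parameters is zero
    up to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import ActivationParams, invert_activation
from .model import EmgDrivenModel
from .moments import DOFS, MUSCLES, sign_matrix
from .musculotendon import MusculotendonParams
from .signal_processing import N_GRID

__all__ = ["SubjectConfig", "SyntheticSubject", "SyntheticDataset",
           "generate_subject", "synthesize_dataset", "make_dataset"]

# nominal musculotendon parameters per muscle: F0m (N), l0m (m), lst (m)
_NOMINALS = {
    "BB":  (625.0, 0.116, 0.215),
    "TB":  (1000.0, 0.134, 0.185),
    "AD":  (1150.0, 0.098, 0.120),
    "MD":  (1030.0, 0.108, 0.135),
    "PD":  (680.0, 0.137, 0.130),
    "IF":  (1200.0, 0.076, 0.105),
    "TMj": (425.0, 0.162, 0.140),
    "LD":  (1000.0, 0.150, 0.210),
    "PM":  (1175.0, 0.142, 0.170),
    "BRD": (260.0, 0.172, 0.155),
}


@dataclass(frozen=True)
class SubjectConfig:
    """Study conditions for the synthetic subject."""

    n_cycles: int = 14
    cycle_duration: float = 1.2           # s; equal poling/recovery halves
    n_synergies: int = 5
    bump_centers: tuple = (0.10, 0.25, 0.40, 0.60, 0.85)  # cycle fractions
    bump_width: float = 0.08              # sd, fraction of cycle
    envelope_noise_sd: float = 0.03       # multiplicative
    moment_noise_frac: float = 0.02       # additive, fraction of per-DOF range
    activation_peak_range: tuple = (0.60, 0.90)
    arm_magnitude_range: tuple = (0.015, 0.040)  # m
    angle_amplitude_range: tuple = (0.20, 0.35)  # rad per harmonic

    def __post_init__(self):
        if self.n_synergies > 7:
            raise ValueError("n_synergies must not exceed 7 (75% of 10 muscles)")
        if len(self.bump_centers) != self.n_synergies:
            raise ValueError("bump_centers must have one entry per synergy")
        if self.envelope_noise_sd < 0 or self.moment_noise_frac < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")


@dataclass
class SyntheticSubject:
    """Ground-truth description of one synthetic subject."""

    config: SubjectConfig
    seed: int
    muscles: list            # MusculotendonParams, nominal == true
    activation: ActivationParams
    W_true: np.ndarray       # (10, l) nonnegative synergy weights
    H_true: np.ndarray       # (l, 100) primitives on the cycle grid
    angle_coeffs: np.ndarray  # (4, 4): A1, phi1, A2, phi2 per DOF
    arm_coeffs: np.ndarray   # (4, 10, 3): signed polynomial coefficients
    lmt0: np.ndarray         # (10,) reference musculotendon lengths at q=0

    @property
    def dt(self) -> float:
        return self.config.cycle_duration / N_GRID

    def model(self) -> EmgDrivenModel:
        """Forward model under the subject's true parameters."""
        return EmgDrivenModel(self.muscles, self.activation, self.dt)

    def nominal_table(self) -> np.ndarray:
        return np.array([[m.F0m, m.l0m, m.lst, m.alpha0] for m in self.muscles])


@dataclass
class SyntheticDataset:
    """Cycle-stacked arrays consumed by the pipeline (all on the 100-pt grid)."""

    envelopes: np.ndarray         # (C, 100, 10), noisy
    lmt: np.ndarray               # (C, 100, 10), meters
    moment_arms: np.ndarray       # (C, 100, 4, 10), meters
    ref_moments: np.ndarray       # (C, 100, 4), N*m, noisy
    activations_true: np.ndarray  # (C, 100, 10), noise-free ground truth
    envelopes_clean: np.ndarray   # (C, 100, 10), noise-free
    ref_moments_clean: np.ndarray  # (C, 100, 4)
    dt: float
    muscle_labels: list = field(default_factory=lambda: list(MUSCLES))
    dof_labels: list = field(default_factory=lambda: list(DOFS))

    @property
    def n_cycles(self) -> int:
        return self.envelopes.shape[0]

    def subset(self, cycles) -> "SyntheticDataset":
        idx = list(cycles)
        return SyntheticDataset(
            self.envelopes[idx], self.lmt[idx], self.moment_arms[idx],
            self.ref_moments[idx], self.activations_true[idx],
            self.envelopes_clean[idx], self.ref_moments_clean[idx],
            self.dt, list(self.muscle_labels), list(self.dof_labels))


def _periodic_bumps(centers, width, n=N_GRID) -> np.ndarray:
    """Wrapped Gaussian bumps on the cycle grid, peak height 1."""
    phase = np.arange(n) / n
    H = np.empty((len(centers), n))
    for k, c in enumerate(centers):
        d = phase - c
        d = (d + 0.5) % 1.0 - 0.5  # wrap to [-0.5, 0.5)
        H[k] = np.exp(-0.5 * (d / width) ** 2)
    return H


def generate_subject(config: SubjectConfig | None = None,
                     seed: int = 0) -> SyntheticSubject:
    """Draw a synthetic subject deterministically from a seed."""
    config = config or SubjectConfig()
    rng = np.random.default_rng(seed)
    m = len(MUSCLES)
    l = config.n_synergies

    muscles = [MusculotendonParams(*_NOMINALS[name], alpha0=0.0, label=name)
               for name in MUSCLES]

    # true activation-dynamics parameters: mild offsets from the standard
    # calibration initials; d = 0.06 s is an exact number of grid samples.
    act = ActivationParams(A=-0.15, C1=0.45, C2=-0.40, d=0.06)

    H = _periodic_bumps(config.bump_centers, config.bump_width)

    # each muscle dominantly loads one synergy (so every primitive is
    # expressed) plus weaker contributions elsewhere
    W = rng.uniform(0.0, 0.25, size=(m, l))
    for j in range(m):
        W[j, j % l] = rng.uniform(0.6, 0.95)
    peaks = rng.uniform(*config.activation_peak_range, size=m)
    a_raw = W @ H
    W *= (peaks / a_raw.max(axis=1))[:, None]

    # joint angles: two harmonics of the cycle per DOF
    A1 = rng.uniform(*config.angle_amplitude_range, size=4)
    phi1 = rng.uniform(0, 2 * np.pi, size=4)
    A2 = rng.uniform(0.3, 0.6, size=4) * A1
    phi2 = rng.uniform(0, 2 * np.pi, size=4)
    angle_coeffs = np.column_stack([A1, phi1, A2, phi2])

    # moment arms: signed low-order polynomials of the DOF angle, kept
    # single-signed over the angle range by bounding the non-constant part
    signs = sign_matrix()
    b0 = rng.uniform(*config.arm_magnitude_range, size=(4, m))
    b1 = rng.uniform(-0.3, 0.3, size=(4, m)) * b0
    b2 = rng.uniform(-0.3, 0.3, size=(4, m)) * b0
    arm_coeffs = np.stack([signs * b0, signs * b1, signs * b2], axis=-1)

    lmt0 = np.array([mu.lst + 1.01 * mu.l0m for mu in muscles])

    return SyntheticSubject(config, seed, muscles, act, W, H,
                            angle_coeffs, arm_coeffs, lmt0)


def joint_angles(subject: SyntheticSubject) -> np.ndarray:
    """(100, 4) joint angles over one cycle (radians)."""
    t = np.arange(N_GRID) / N_GRID
    q = np.empty((N_GRID, 4))
    for i in range(4):
        A1, phi1, A2, phi2 = subject.angle_coeffs[i]
        q[:, i] = A1 * np.sin(2 * np.pi * t + phi1) + A2 * np.sin(4 * np.pi * t + phi2)
    return q


def moment_arms_from_angles(subject: SyntheticSubject, q: np.ndarray) -> np.ndarray:
    """(n, 4, 10) moment arms r_ij(q_i) from the polynomial coefficients."""
    n = q.shape[0]
    arms = np.empty((n, 4, len(MUSCLES)))
    for i in range(4):
        c0 = subject.arm_coeffs[i, :, 0]
        c1 = subject.arm_coeffs[i, :, 1]
        c2 = subject.arm_coeffs[i, :, 2]
        qi = q[:, i][:, None]
        arms[:, i, :] = c0[None, :] + c1[None, :] * qi + c2[None, :] * qi**2
    return arms


def lmt_from_angles(subject: SyntheticSubject, q: np.ndarray) -> np.ndarray:
    """Musculotendon lengths consistent with the moment arms.

    Moment arms are minus the partial derivative of musculotendon length
    with respect to the joint angle, so with polynomial arms the length is
    the closed-form path integral
    LMT_j(q) = LMT0_j - sum_i [B_ij(q_i) - B_ij(0)], B' = r.
    """
    n = q.shape[0]
    lmt = np.tile(subject.lmt0, (n, 1))
    for i in range(4):
        c0 = subject.arm_coeffs[i, :, 0]
        c1 = subject.arm_coeffs[i, :, 1]
        c2 = subject.arm_coeffs[i, :, 2]
        qi = q[:, i][:, None]
        B = c0[None, :] * qi + c1[None, :] * qi**2 / 2 + c2[None, :] * qi**3 / 3
        lmt -= B
    return lmt


def _inverse_envelopes(subject: SyntheticSubject) -> np.ndarray:
    """Exact periodic inverse of the activation dynamics: (100, 10) envelopes.

    Activations are periodic over the cycle, so the recursion is inverted
    with wrapped indices and the electromechanical delay is undone by a
    circular shift; the forward pass (with warm-up) then reproduces the true
    activations to within the filter's geometric transient decay.
    """
    p = subject.activation
    a = np.clip(subject.W_true @ subject.H_true, 0.0, 1.0)  # (10, 100)
    u = invert_activation(a, p.A)
    b1, b2 = p.C1 + p.C2, p.C1 * p.C2
    e_delayed = (u + b1 * np.roll(u, 1, axis=1) + b2 * np.roll(u, 2, axis=1)) / p.alpha
    k = int(round(p.d / subject.dt))
    e = np.roll(e_delayed, -k, axis=1)
    return np.clip(e.T, 0.0, None)  # (100, 10)


def synthesize_dataset(subject: SyntheticSubject) -> SyntheticDataset:
    """Generate the cycle-stacked dataset for a subject (seeded noise)."""
    cfg = subject.config
    rng = np.random.default_rng(subject.seed + 1)
    C = cfg.n_cycles

    q = joint_angles(subject)
    arms1 = moment_arms_from_angles(subject, q)
    lmt1 = lmt_from_angles(subject, q)
    arms = np.tile(arms1, (C, 1, 1, 1))
    lmt = np.tile(lmt1, (C, 1, 1))

    e1 = _inverse_envelopes(subject)            # (100, 10), one cycle
    env_clean = np.tile(e1, (C, 1, 1))
    noise = rng.normal(0.0, cfg.envelope_noise_sd, size=env_clean.shape)
    env = np.clip(env_clean * (1.0 + noise), 0.0, 1.05)
    if cfg.envelope_noise_sd == 0:
        env = env_clean.copy()

    a_true = np.clip(subject.W_true @ subject.H_true, 0.0, 1.0)  # (10, 100)
    activations_true = np.tile(a_true.T, (C, 1, 1))

    model = subject.model()
    mom_clean = model.moments(env_clean, lmt, arms)
    rng_m = np.random.default_rng(subject.seed + 2)
    dof_range = (mom_clean.max(axis=(0, 1)) - mom_clean.min(axis=(0, 1)))
    mom = mom_clean + rng_m.normal(0.0, 1.0, size=mom_clean.shape) \
        * (cfg.moment_noise_frac * dof_range)[None, None, :]
    if cfg.moment_noise_frac == 0:
        mom = mom_clean.copy()

    return SyntheticDataset(env, lmt, arms, mom, activations_true,
                            env_clean, mom_clean, subject.dt)


def make_dataset(seed: int = 0, config: SubjectConfig | None = None):
    """Convenience: subject + dataset in one call."""
    subject = generate_subject(config, seed)
    return subject, synthesize_dataset(subject)
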