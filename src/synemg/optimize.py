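"""Seeded simulated annealing on a box.

Used for both subject calibration (34 parameters) and missing-muscle
synergy-weight optimization (l parameters).  Proposals perturb one randomly
chosen coordinate at a time with a Gaussian step of 10% of that
coordinate's box width (projected back onto the box); the temperature
follows an exponential schedule T_k = T0 * cooling^k with a fixed number of
proposals per temperature.  T0 is set from warm-up probes so that the
initial uphill acceptance is roughly 0.8.  The best-so-far point is always
tracked and returned, so the reported objective is non-increasing along the
trace regardless of the acceptance sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnnealingSettings", "AnnealingResult", "simulated_anneal"]


@dataclass(frozen=True)
class AnnealingSettings:
    max_evals: int = 5000
    n_per_temp: int = 200
    cooling: float = 0.95
    step_frac: float = 0.10        # proposal sd as fraction of box width
    initial_acceptance: float = 0.8
    n_warmup_probes: int = 30
    t0: float | None = None        # explicit initial temperature (else estimated)


@dataclass
class AnnealingResult:
    x: np.ndarray                  # best point found
    fun: float                     # objective at best point
    n_evals: int
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))  # best-so-far J
    t0: float = 0.0
    accepted: int = 0


def simulated_anneal(fun, x0, lower, upper, seed: int,
                     settings: AnnealingSettings = AnnealingSettings(),
                     extra_candidates=()) -> AnnealingResult:
    """Minimize ``fun`` over the box [lower, upper] starting from ``x0``.

    ``extra_candidates`` are additional points evaluated up front and
    entered into the best-so-far tracking (e.g. the all-zero weight vector
    in missing-muscle optimization, so the optimizer never loses to it).
    """
    rng = np.random.default_rng(seed)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    x = np.clip(np.asarray(x0, dtype=float).copy(), lower, upper)
    width = upper - lower
    if np.any(width <= 0):
        raise ValueError("box must have positive width in every dimension")
    dim = x.size

    n_evals = 0

    def f(z):
        nonlocal n_evals
        n_evals += 1
        v = float(fun(z))
        if not np.isfinite(v):
            raise FloatingPointError("non-finite objective value")
        return v

    j_cur = f(x)
    best_x, best_j = x.copy(), j_cur
    trace = [best_j]
    for cand in extra_candidates:
        jc = f(np.asarray(cand, dtype=float))
        if jc < best_j:
            best_x, best_j = np.clip(np.asarray(cand, dtype=float), lower, upper), jc
        trace.append(best_j)

    def propose(z):
        k = rng.integers(dim)
        znew = z.copy()
        znew[k] += rng.normal(0.0, settings.step_frac * width[k])
        znew[k] = min(max(znew[k], lower[k]), upper[k])
        return znew

    # temperature from uphill warm-up probes
    if settings.t0 is not None:
        temp = settings.t0
    else:
        uphill = []
        for _ in range(min(settings.n_warmup_probes,
                           max(settings.max_evals - n_evals - 1, 0))):
            zp = propose(x)
            dj = f(zp) - j_cur  # probes only estimate the uphill scale
            if dj > 0:
                uphill.append(dj)
        if uphill:
            temp = float(np.median(uphill)) / -np.log(settings.initial_acceptance)
        else:
            temp = max(abs(j_cur), 1.0) * 1e-3

    t0 = temp
    accepted = 0
    since_cool = 0
    while n_evals < settings.max_evals:
        zp = propose(x)
        jp = f(zp)
        dj = jp - j_cur
        if dj <= 0 or rng.random() < np.exp(-dj / temp):
            x, j_cur = zp, jp
            accepted += 1
        if j_cur < best_j:
            best_x, best_j = x.copy(), j_cur
        trace.append(best_j)
        since_cool += 1
        if since_cool >= settings.n_per_temp:
            temp *= settings.cooling
            since_cool = 0

    if accepted == 0 and settings.max_evals > 1:
        raise RuntimeError(
            "annealing budget exhausted without a single accepted move; "
            "check the objective scale and proposal step size")
    return AnnealingResult(best_x, best_j, n_evals, np.asarray(trace), t0, accepted)
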