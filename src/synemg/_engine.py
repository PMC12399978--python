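"""Compiled (numba) kernels for the inner numerical loops.

The simulated-annealing calibration and missing-muscle weight optimization
evaluate the full forward model thousands of times; each evaluation solves
the tendon-fiber equilibrium at every frame of every muscle of every cycle.
These loops are scalar and sequential in time (fiber velocity is a backward
difference of the solved fiber length), so they are implemented as njit
kernels.  The curve formulas are mirrored 1:1 by the numpy functions in
:mod:`synemg.musculotendon`, which the test suite checks for agreement.

Curve-constant layout (float64 vector, see CurveConstants.as_array):
  0 Vmax, 1 FlenM, 2 Af, 3 gamma, 4 KPE, 5 eps0M,
  6 Ftoe, 7 eps0T, 8 epstoe, 9 ktoe, 10 klin
"""

import numpy as np
from numba import njit

LM_BAR_MIN = 0.05
LM_BAR_MAX = 1.8
_SIN_PEN_MAX = np.sin(np.deg2rad(84.3))
_MAX_BISECT = 80


@njit(cache=True)
def _fv_force(a, fl, vm, Vmax, FlenM, Af):
    """Closed-form contractile force from fiber velocity (l0m/s)."""
    k = (0.25 + 0.75 * a) * Vmax
    afl = a * fl
    if vm <= 0.0:
        f = afl * (k + vm) / (k - vm / Af)
        if f < 0.0:
            f = 0.0
        return f
    cc = (2.0 + 2.0 / Af) / (FlenM - 1.0)
    return afl * (k + cc * FlenM * vm) / (k + cc * vm)


@njit(cache=True)
def _fpe(lm_bar, KPE, eps0M):
    f = (np.exp(KPE * (lm_bar - 1.0) / eps0M) - 1.0) / (np.exp(KPE) - 1.0)
    if f < 0.0:
        f = 0.0
    return f


@njit(cache=True)
def _ft(eps, Ftoe, epstoe, ktoe, klin):
    if eps <= 0.0:
        return 0.0
    if eps <= epstoe:
        return Ftoe * (np.exp(ktoe * eps / epstoe) - 1.0) / (np.exp(ktoe) - 1.0)
    return Ftoe + klin * (eps - epstoe)


@njit(cache=True)
def _cos_pen(lm, l0m, alpha0):
    if alpha0 == 0.0:
        return 1.0
    s = np.sin(alpha0) * l0m / lm
    if s > _SIN_PEN_MAX:
        s = _SIN_PEN_MAX
    return np.sqrt(1.0 - s * s)


@njit(cache=True)
def _residual(lm_bar, a, lmt, lm_prev, first, dt, l0m, lst, alpha0, c):
    """Force-balance residual F_T - (F_CE + F_PE) cos(pen) at candidate lm_bar."""
    lm = lm_bar * l0m
    cosp = _cos_pen(lm, l0m, alpha0)
    lt = lmt - lm * cosp
    eps = lt / lst - 1.0
    ft = _ft(eps, c[6], c[8], c[9], c[10])
    if first:
        vm = 0.0
    else:
        vm = (lm - lm_prev) / dt / l0m
    fl = np.exp(-((lm_bar - 1.0) ** 2) / c[3])
    fce = _fv_force(a, fl, vm, c[0], c[1], c[2])
    fpe = _fpe(lm_bar, c[4], c[5])
    return ft - (fce + fpe) * cosp


@njit(cache=True)
def solve_cycle(act, lmt, dt, mt, consts, force_tol):
    """Tendon-fiber equilibrium for one cycle of all muscles.

    act, lmt : (n_frames, n_muscles); mt : (n_muscles, 4) rows of
    (F0m, l0m, lst, alpha0).  Returns lm, vm, fce, fpe, ft, cos_pen
    (all (n, m) float64) and a flag array marking rigid-tendon fallback
    frames.
    """
    n, m = act.shape
    lm_out = np.empty((n, m))
    vm_out = np.empty((n, m))
    fce_out = np.empty((n, m))
    fpe_out = np.empty((n, m))
    ft_out = np.empty((n, m))
    cos_out = np.empty((n, m))
    flag = np.zeros((n, m), dtype=np.bool_)

    for j in range(m):
        l0m = mt[j, 1]
        lst = mt[j, 2]
        alpha0 = mt[j, 3]
        lm_prev = 0.0
        prev_bar = 1.0
        for t in range(n):
            a = act[t, j]
            L = lmt[t, j]
            first = t == 0
            lo = LM_BAR_MIN
            hi = LM_BAR_MAX
            # try a narrow bracket around the previous frame's solution
            if t > 0:
                nlo = prev_bar - 0.12
                nhi = prev_bar + 0.12
                if nlo < LM_BAR_MIN:
                    nlo = LM_BAR_MIN
                if nhi > LM_BAR_MAX:
                    nhi = LM_BAR_MAX
                g_nlo = _residual(nlo, a, L, lm_prev, first, dt, l0m, lst, alpha0, consts)
                g_nhi = _residual(nhi, a, L, lm_prev, first, dt, l0m, lst, alpha0, consts)
                if g_nlo > 0.0 and g_nhi < 0.0:
                    lo = nlo
                    hi = nhi
            g_lo = _residual(lo, a, L, lm_prev, first, dt, l0m, lst, alpha0, consts)
            g_hi = _residual(hi, a, L, lm_prev, first, dt, l0m, lst, alpha0, consts)
            solved = False
            x = prev_bar
            if g_lo == 0.0:
                x = lo
                solved = True
            elif g_hi == 0.0:
                x = hi
                solved = True
            elif g_lo > 0.0 and g_hi < 0.0:
                # residual is decreasing in lm_bar on a valid bracket
                for _ in range(_MAX_BISECT):
                    x = 0.5 * (lo + hi)
                    g = _residual(x, a, L, lm_prev, first, dt, l0m, lst, alpha0, consts)
                    if abs(g) <= force_tol:
                        break
                    if g > 0.0:
                        lo = x
                    else:
                        hi = x
                solved = True
            if not solved:
                # rigid-tendon fallback: tendon at slack length
                cosp0 = _cos_pen(max(L - lst, LM_BAR_MIN * l0m), l0m, alpha0)
                x = (L - lst) / cosp0 / l0m
                if x < LM_BAR_MIN:
                    x = LM_BAR_MIN
                if x > LM_BAR_MAX:
                    x = LM_BAR_MAX
                flag[t, j] = True

            lm = x * l0m
            cosp = _cos_pen(lm, l0m, alpha0)
            if first:
                vm = 0.0
            else:
                vm = (lm - lm_prev) / dt / l0m
            fl = np.exp(-((x - 1.0) ** 2) / consts[3])
            fce = _fv_force(a, fl, vm, consts[0], consts[1], consts[2])
            fpe = _fpe(x, consts[4], consts[5])
            if flag[t, j]:
                ft = (fce + fpe) * cosp
            else:
                eps = (L - lm * cosp) / lst - 1.0
                ft = _ft(eps, consts[6], consts[8], consts[9], consts[10])
            lm_out[t, j] = lm
            vm_out[t, j] = vm
            fce_out[t, j] = fce
            fpe_out[t, j] = fpe
            ft_out[t, j] = ft
            cos_out[t, j] = cosp
            lm_prev = lm
            prev_bar = x
    return lm_out, vm_out, fce_out, fpe_out, ft_out, cos_out, flag


@njit(cache=True)
def excitation_recursion(e, alpha, c1, c2):
    """Second-order recursive filter from delayed envelope to excitation.

    u(t) = alpha*e(t) - (C1+C2)*u(t-1) - C1*C2*u(t-2), zero initial state.
    """
    n, m = e.shape
    u = np.zeros((n, m))
    b1 = c1 + c2
    b2 = c1 * c2
    for t in range(n):
        for j in range(m):
            u1 = u[t - 1, j] if t >= 1 else 0.0
            u2 = u[t - 2, j] if t >= 2 else 0.0
            u[t, j] = alpha * e[t, j] - b1 * u1 - b2 * u2
    return u


@njit(cache=True)
def joint_moments_kernel(fce, fpe, cosp, arms, f0m):
    """M[t, i] = sum_j F0m_j (fce+fpe)[t,j] r[t,i,j] cos_pen[t,j]."""
    n, m = fce.shape
    ndof = arms.shape[1]
    out = np.zeros((n, ndof))
    for t in range(n):
        for i in range(ndof):
            s = 0.0
            for j in range(m):
                s += f0m[j] * (fce[t, j] + fpe[t, j]) * arms[t, i, j] * cosp[t, j]
            out[t, i] = s
    return out
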