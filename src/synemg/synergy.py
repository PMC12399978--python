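"""Muscle-synergy decomposition of activation matrices.

An activation matrix V (m muscles x n time points, values in [0, 1]) is
factorized as V ~ VR = W @ H into time-invariant motor modules W (m x l)
and time-varying motor primitives H (l x n).  The primary method is NMF
(multiplicative updates on the squared Frobenius loss, nonnegative W and
H); PCA, fastICA and maximum-likelihood factor analysis are provided as
comparison methods — for those, time points are treated as samples and
muscles as features, H holds the component score time courses and the
reconstruction restores the removed per-muscle means.

Each factorization is repeated with ``restarts`` random initializations
and the solution with the highest reconstruction R^2 is kept, where

    R^2 = 1 - ||V - VR||_F^2 / ||V - mean(V)||_F^2

with grand-mean (single scalar) centering.  Because extracting as many
synergies as muscles performs no dimensionality reduction, the synergy
number is capped at 75% of the muscle count (l in 2..7 for 10 muscles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF, PCA, FactorAnalysis, FastICA

__all__ = ["SynergyDecomposition", "decompose", "reconstruction_r2",
           "synergy_sweep", "synergy_cap"]

METHODS = ("nmf", "pca", "ica", "fa")


@dataclass
class SynergyDecomposition:
    """One V ~ W @ H factorization (plus per-muscle mean offset where used)."""

    method: str
    l: int
    W: np.ndarray            # (m, l)
    H: np.ndarray            # (l, n)
    mean: np.ndarray | None  # (m,) per-muscle offset (None for NMF)
    VR: np.ndarray           # (m, n) reconstruction
    r2: float
    restarts: int
    seed: int

    def reconstruct(self) -> np.ndarray:
        out = self.W @ self.H
        if self.mean is not None:
            out = out + self.mean[:, None]
        return out


def synergy_cap(n_muscles: int) -> int:
    """Maximum admissible synergy count: 75% of the muscle count."""
    return int(np.floor(0.75 * n_muscles))


def reconstruction_r2(V: np.ndarray, VR: np.ndarray) -> float:
    """Coefficient of determination between a matrix and its reconstruction."""
    V = np.asarray(V, dtype=float)
    VR = np.asarray(VR, dtype=float)
    if V.shape != VR.shape:
        raise ValueError("V and VR must share a shape")
    total = float(np.sum((V - V.mean()) ** 2))
    if total == 0:
        raise ValueError("constant activation matrix: zero total variance")
    return 1.0 - float(np.sum((V - VR) ** 2)) / total


def _check_input(V: np.ndarray, l: int, method: str):
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D (muscles x time)")
    m = V.shape[0]
    if l >= m:
        raise ValueError(f"l = {l} >= {m} muscles performs no dimensionality reduction")
    if l < 1:
        raise ValueError("need at least one synergy")
    if method == "nmf" and np.any(V < 0):
        raise ValueError("NMF requires a nonnegative activation matrix")
    return V


def _fit_once(V: np.ndarray, l: int, method: str, rs: int):
    """One factorization; returns (W, H, mean, VR)."""
    X = V.T  # time points as samples, muscles as features
    if method == "nmf":
        nmf = NMF(n_components=l, init="random", solver="mu",
                  beta_loss="frobenius", max_iter=1000, tol=1e-6,
                  random_state=rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter reached on hard restarts
            W = nmf.fit_transform(V)
        return W, nmf.components_, None, W @ nmf.components_
    if method == "pca":
        pca = PCA(n_components=l, random_state=rs)
        scores = pca.fit_transform(X)
        W = pca.components_.T
        H = scores.T
        VR = (scores @ pca.components_ + pca.mean_).T
        return W, H, pca.mean_.copy(), VR
    if method == "ica":
        ica = FastICA(n_components=l, random_state=rs, whiten="unit-variance",
                      max_iter=2000, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = ica.fit_transform(X)
        W = ica.mixing_
        H = S.T
        VR = (S @ ica.mixing_.T + ica.mean_).T
        return W, H, ica.mean_.copy(), VR
    if method == "fa":
        fa = FactorAnalysis(n_components=l, random_state=rs, max_iter=1000)
        F = fa.fit_transform(X)
        W = fa.components_.T
        H = F.T
        VR = (F @ fa.components_ + fa.mean_).T
        return W, H, fa.mean_.copy(), VR
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def decompose(V: np.ndarray, l: int, method: str = "nmf",
              restarts: int = 10, seed: int = 0) -> SynergyDecomposition:
    """Best-of-``restarts`` synergy factorization at a fixed synergy count.

    Deterministic for fixed inputs and seed: restart k uses random state
    ``seed + k`` and the restart with the highest reconstruction R^2 wins.
    """
    method = method.lower()
    V = _check_input(V, l, method)
    best = None
    for k in range(restarts):
        W, H, mean, VR = _fit_once(V, l, method, rs=seed + k)
        r2 = reconstruction_r2(V, VR)
        if best is None or r2 > best.r2:
            best = SynergyDecomposition(method, l, W, H, mean, VR, r2,
                                        restarts, seed)
    return best


def synergy_sweep(V: np.ndarray, method: str = "nmf", l_values=range(2, 8),
                  restarts: int = 10, seed: int = 0) -> list[SynergyDecomposition]:
    """Factorize at each synergy count in ``l_values`` (bounded by the cap)."""
    V = np.asarray(V, dtype=float)
    cap = synergy_cap(V.shape[0])
    l_values = list(l_values)
    over = [l for l in l_values if l > cap]
    if over:
        raise ValueError(f"synergy counts {over} exceed the cap of {cap} "
                         f"(75% of {V.shape[0]} muscles)")
    return [decompose(V, l, method, restarts, seed) for l in l_values]
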