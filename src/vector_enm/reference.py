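"""Independent reference implementations used to validate the main paths.

These deliberately avoid the algorithms used by the package proper: the
distance oracle is an all-pairs brute force, the AUC oracle enumerates
every presence/background pair, and the penalised maximum-entropy oracle
is a FISTA proximal-gradient solver (the production fit uses L-BFGS-B on
a split-variable formulation). They are slow and only meant for small
instances in tests and validation scripts.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "brute_force_distance_to",
    "pairwise_auc",
    "fista_maxent_objective",
]


def brute_force_distance_to(values: np.ndarray, nodata_mask: np.ndarray,
                            category: int, cell_size: float) -> np.ndarray:
    """Minimum centre-to-centre distance to a category cell, by full scan."""
    target = (values == category) & ~nodata_mask
    if not target.any():
        raise ValueError(f"category {category} absent")
    tr, tc = np.nonzero(target)
    nr, nc = values.shape
    out = np.zeros((nr, nc))
    for i in range(nr):
        for j in range(nc):
            d2 = (tr - i) ** 2 + (tc - j) ** 2
            out[i, j] = np.sqrt(float(d2.min())) * cell_size
    out[nodata_mask] = 0.0
    return out


def pairwise_auc(presence_scores, background_scores) -> float:
    """AUC by exhaustive enumeration of ordered pairs; ties count 1/2."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    wins = 0.0
    ties = 0.0
    for ps in p:
        wins += np.sum(ps > b)
        ties += np.sum(ps == b)
    return float((wins + 0.5 * ties) / (p.size * b.size))


def fista_maxent_objective(
    presence: np.ndarray,
    background: np.ndarray,
    lambdas: np.ndarray,
    max_iter: int = 50000,
    tol: float = 1e-14,
) -> tuple[float, np.ndarray]:
    """Minimise the penalised maxent objective by FISTA proximal gradient.

    Returns (objective value, weights). Convex, run to tight tolerance; the
    step size is 1/L with L an upper bound on the smooth part's curvature
    (the largest squared background row norm).
    """
    presence = np.asarray(presence, float)
    background = np.asarray(background, float)
    lambdas = np.asarray(lambdas, float)
    n, J = background.shape
    p_mean = presence.mean(axis=0)

    def smooth(w):
        return float(-p_mean @ w + logsumexp(background @ w) - np.log(n))

    def grad(w):
        eta = background @ w
        prob = np.exp(eta - logsumexp(eta))
        return background.T @ prob - p_mean

    def objective(w):
        return smooth(w) + float(lambdas @ np.abs(w))

    L = float(np.max(np.sum(background ** 2, axis=1)))
    if L == 0:
        return objective(np.zeros(J)), np.zeros(J)
    step = 1.0 / L
    w = np.zeros(J)
    z = w.copy()
    t = 1.0
    prev = objective(w)
    for it in range(max_iter):
        g = grad(z)
        w_new = z - step * g
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lambdas, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = w_new + ((t - 1.0) / t_new) * (w_new - w)
        w, t = w_new, t_new
        if it % 50 == 49:
            cur = objective(w)
            if abs(prev - cur) < tol * max(1.0, abs(cur)):
                break
            prev = cur
    return objective(w), w
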