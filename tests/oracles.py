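"""Independent reference implementations used only as test oracles."""

import numpy as np
from scipy.optimize import lsq_linear


def exact_tv_l2(b: np.ndarray, mu: float) -> np.ndarray:
    """Exact minimiser of ||Du||_1 + (mu/2)||u - b||^2 via the dual problem.

    Writing u = b - Dtil^T p with Dtil the (F-1) x F difference matrix,
    the dual is the box-constrained least-squares problem
    min ||Dtil^T p - b||^2 s.t. |p_i| <= 1/mu, solved here with the exact
    BVLS active-set method.  Completely independent of the ADMM path.
    """
    b = np.asarray(b, dtype=float)
    F = b.size
    lam = 1.0 / mu
    DtT = np.zeros((F, F - 1))
    for j in range(F - 1):
        DtT[j, j] = -1.0
        DtT[j + 1, j] = 1.0
    res = lsq_linear(DtT, b, bounds=(-lam, lam), method="bvls", tol=1e-14)
    return b - DtT @ res.x


def dense_forward_diff_matrix(F: int) -> np.ndarray:
    """F x F forward-difference matrix with an all-zero last row."""
    D = np.zeros((F, F))
    for v in range(F - 1):
        D[v, v] = -1.0
        D[v, v + 1] = 1.0
    return D


def brute_force_tv(x: np.ndarray) -> float:
    return float(sum(abs(x[v + 1] - x[v]) for v in range(len(x) - 1)))


def brute_force_circular_corr(xn: np.ndarray, yn: np.ndarray) -> np.ndarray:
    """O(F^2) circular cross-correlation: c[k] = sum_t x[t] * y[(t+k) % F]."""
    F = len(xn)
    return np.array(
        [sum(xn[t] * yn[(t + k) % F] for t in range(F)) for k in range(F)]
    )


def ranksum_exact_permutation(a: np.ndarray, b: np.ndarray, tail: str) -> float:
    """Exhaustive permutation p-value of the rank-sum statistic (tiny n)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    # midranks for ties
    order = np.sort(pooled)
    ranks = np.empty(len(pooled))
    for i, v in enumerate(pooled):
        ranks[i] = np.mean(np.flatnonzero(order == v)) + 1.0
    n_a = len(a)
    obs = ranks[:n_a].sum()
    idx = range(len(pooled))
    stats = [ranks[list(c)].sum() for c in combinations(idx, n_a)]
    stats = np.asarray(stats)
    if tail == "greater":
        return float(np.mean(stats >= obs))
    if tail == "less":
        return float(np.mean(stats <= obs))
    hi = np.mean(stats >= obs)
    lo = np.mean(stats <= obs)
    return float(min(1.0, 2.0 * min(hi, lo)))
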