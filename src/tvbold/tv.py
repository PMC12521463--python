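"""1D total-variation (TV-l2) denoising of BOLD time series.

The physiological BOLD signal varies smoothly, while the measured series is
contaminated by broadband noise and isolated spikes.  Frequency-domain or
component-removal filters cannot remove an isolated spike, whose spectrum
spans all frequencies; penalising the total variation of the restored
series removes it by construction.  The restored series ``u`` minimises

    G(u) = ||D u||_1 + (mu / 2) * ||u - b||_2^2

where ``b`` is the measured series, ``D`` the forward-difference operator
and ``mu`` the data-fidelity weight: the first term enforces temporal
smoothness, the second keeps ``u`` close to the measured local means.
This is the 1D analogue of the Rudin-Osher-Fatemi image model.

The minimiser is computed with a partially inexact alternating direction
method of multipliers (ADMM).  The ``u``-subproblem is solved inexactly by
steepest-descent steps with an exact line search; the auxiliary difference
variable ``w`` has a closed-form soft-threshold update; the multipliers
``lam`` ascend on the constraint ``D u = w``.  By default the inner loop is
stopped after a fixed number of gradient steps; a relative-error stopping
criterion (driven by the auxiliary iterate ``r``) is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import InvalidInputError, MultiEchoSeries, as_series

__all__ = [
    "DenoiseParams",
    "ADMMState",
    "forward_diff",
    "forward_diff_adjoint",
    "total_variation",
    "soft_threshold_update",
    "tv_l2_objective",
    "admm_denoise_1d",
    "denoise_batch",
    "denoise_multi_echo",
]


@dataclass(frozen=True)
class DenoiseParams:
    """Parameters of the TV-l2 denoiser.

    Attributes
    ----------
    mu : float
        Data-fidelity weight (> 0).  The default 2**-10 targets
        raw-magnitude BOLD values (order 1e4); decreasing ``mu`` removes
        structures of larger size and contrast.
    beta : float
        ADMM penalty weight (> 0), default 2**-4.
    outer_iters : int
        Number of outer ADMM iterations, default 400.  Each outer pass can
        shrink a forward difference by at most ~2/beta signal units, so the
        count must be large enough for the spike amplitudes present in the
        data; the default brings the objective within 1% (typically ~0.1%)
        of the exact TV-l2 minimum on raw-magnitude BOLD series.
    inner_iters : int
        Gradient steps per u-subproblem when the fixed-step rule is used,
        default 5.
    sigma : float
        Relative-error tolerance in (0, 1]; only consulted when
        ``use_relative_error_stop`` is set.
    use_relative_error_stop : bool
        If True, the inner loop runs until
        ``(2/beta)*|<r - u, g>| + ||g||^2 <= sigma * ||D u - w||^2``
        instead of a fixed number of steps.
    """

    mu: float = 2.0**-10
    beta: float = 2.0**-4
    outer_iters: int = 400
    inner_iters: int = 5
    sigma: float = 0.5
    use_relative_error_stop: bool = False

    def __post_init__(self):
        if self.mu <= 0:
            raise InvalidInputError("mu must be > 0")
        if self.beta <= 0:
            raise InvalidInputError("beta must be > 0")
        if self.outer_iters < 1 or self.inner_iters < 1:
            raise InvalidInputError("iteration counts must be >= 1")
        if not (0 < self.sigma <= 1):
            raise InvalidInputError("sigma must lie in (0, 1]")


@dataclass
class ADMMState:
    """Iterates of the partially inexact ADMM (all vectors of length F)."""

    u: np.ndarray
    w: np.ndarray
    lam: np.ndarray
    r: np.ndarray
    g: np.ndarray
    alpha: float = 0.0


def forward_diff(x) -> np.ndarray:
    """Forward differences of a time series.

    ``D`` is the F x F matrix whose v-th row produces ``x[v+1] - x[v]``;
    only F-1 forward differences exist, so the last row of ``D`` is zero
    (Neumann boundary — the endpoints of a non-periodic physiological
    signal are not wrapped).

    Returns a length-F vector with ``out[v] = x[v+1] - x[v]`` for
    ``v < F-1`` and ``out[F-1] = 0``.
    """
    x = as_series(x, "x")
    return _diff(x)


def _diff(x: np.ndarray) -> np.ndarray:
    # operates along the last axis; supports batches
    out = np.zeros_like(x)
    out[..., :-1] = x[..., 1:] - x[..., :-1]
    return out


def _diff_adjoint(y: np.ndarray) -> np.ndarray:
    # adjoint of _diff: (D^T y)_0 = -y_0, (D^T y)_j = y_{j-1} - y_j for
    # 1 <= j <= F-2, (D^T y)_{F-1} = y_{F-2}; y_{F-1} multiplies the zero row
    out = np.empty_like(y)
    out[..., 0] = -y[..., 0]
    out[..., 1:-1] = y[..., :-2] - y[..., 1:-1]
    out[..., -1] = y[..., -2]
    return out


def forward_diff_adjoint(y) -> np.ndarray:
    """Adjoint ``D^T y`` of the forward-difference operator."""
    y = as_series(y, "y")
    return _diff_adjoint(y)


def total_variation(x) -> float:
    """Total variation: the sum of absolute forward differences.

    Zero iff the series is constant; for a monotone series it equals the
    absolute difference between the first and last sample.
    """
    x = as_series(x, "x")
    return float(np.abs(_diff(x)).sum())


def soft_threshold_update(d, lam_i, beta: float):
    """Closed-form w-update: ``max(|d - lam_i/beta| - 1/beta, 0) * sgn(.)``.

    Scalars or arrays are accepted elementwise.
    """
    if beta <= 0:
        raise InvalidInputError("beta must be > 0")
    v = np.asarray(d, dtype=float) - np.asarray(lam_i, dtype=float) / beta
    out = np.maximum(np.abs(v) - 1.0 / beta, 0.0) * np.sign(v)
    if out.ndim == 0:
        return float(out)
    return out


def tv_l2_objective(u, b, mu: float) -> float:
    """Objective ``G(u) = ||D u||_1 + (mu/2) ||u - b||_2^2``."""
    u = np.asarray(u, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.abs(_diff(u)).sum() + 0.5 * mu * np.sum((u - b) ** 2))


def _admm_batch_fixed(B: np.ndarray, p: DenoiseParams) -> np.ndarray:
    """Vectorised ADMM with the fixed inner-step rule.

    ``B`` has shape (n, F); every row is denoised independently.  All
    reductions run along the last axis only, so the result for a row does
    not depend on the other rows (the single-series path is this function
    with n = 1).
    """
    mu, beta = p.mu, p.beta
    U = B.copy()
    W = _diff(B)          # warm start: w acts on measured differences
    L = np.zeros_like(B)  # multipliers lambda
    for _ in range(p.outer_iters):
        for _ in range(p.inner_iters):
            G = beta * _diff_adjoint(_diff(U) - W - L / beta) + mu * (U - B)
            DG = _diff(G)
            gg = np.sum(G * G, axis=-1)
            gAg = beta * np.sum(DG * DG, axis=-1) + mu * gg
            # A = beta*D^T D + mu*I is positive definite, so gAg = 0 only
            # when g = 0; skip the step there
            with np.errstate(invalid="ignore", divide="ignore"):
                alpha = np.where(gg > 0, gg / gAg, 0.0)
            U = U - alpha[..., None] * G
        DU = _diff(U)
        V = DU - L / beta
        W = np.maximum(np.abs(V) - 1.0 / beta, 0.0) * np.sign(V)
        # multiplier step consistent with the (Du - w - lam/beta) convention
        # used in g and the w-update; the opposite sign diverges
        L = L - beta * (DU - W)
    return U


def admm_denoise_1d(b, p: DenoiseParams | None = None) -> np.ndarray:
    """Denoise one time series by partially inexact ADMM.

    Parameters
    ----------
    b : array-like, length F >= 2
        Measured series (finite values).
    p : DenoiseParams, optional
        Algorithm parameters; defaults target raw-magnitude BOLD data
        (mu = 2**-10, beta = 2**-4, 400 outer iterations, 5 inner
        gradient steps).

    Returns
    -------
    ndarray
        The restored series ``u`` with ``G(u) <= G(b)``.

    Notes
    -----
    Initialisation: ``u0 = b``, ``w0 = D b``, ``lam0 = 0``, ``r0 = 0``.
    The inner loop performs steepest-descent steps ``u <- u - alpha*g``
    with gradient ``g = beta*D^T(D u - w - lam/beta) + mu*(u - b)`` and
    exact line-search step ``alpha = g^T g / g^T A g``,
    ``A = beta*D^T D + mu*I``, computed matrix-free.  After the inner loop
    the difference variable is soft-thresholded, the multipliers ascend,
    and the auxiliary iterate is updated as ``r <- r - beta*g``.
    """
    b = as_series(b, "b")
    if p is None:
        p = DenoiseParams()
    if not p.use_relative_error_stop:
        return _admm_batch_fixed(b[None, :], p)[0]
    return _admm_relative(b, p)


_MAX_INNER_RELATIVE = 1000  # safety cap for the relative-error inner loop


def _admm_relative(b: np.ndarray, p: DenoiseParams) -> np.ndarray:
    mu, beta, sigma = p.mu, p.beta, p.sigma
    state = ADMMState(
        u=b.copy(), w=_diff(b), lam=np.zeros_like(b), r=np.zeros_like(b),
        g=np.zeros_like(b),
    )
    for _ in range(p.outer_iters):
        u = state.u
        for _ in range(_MAX_INNER_RELATIVE):
            g = beta * _diff_adjoint(_diff(u) - state.w - state.lam / beta) + mu * (u - b)
            dg = _diff(g)
            gg = float(g @ g)
            if gg > 0:
                alpha = gg / (beta * float(dg @ dg) + mu * gg)
                u = u - alpha * g
                state.alpha = alpha
            state.g = g
            lhs = (2.0 / beta) * abs(float((state.r - u) @ g)) + gg
            rhs = sigma * float(np.sum((_diff(u) - state.w) ** 2))
            if lhs <= rhs or gg == 0.0:
                break
        state.u = u
        du = _diff(u)
        state.w = soft_threshold_update(du, state.lam, beta)
        state.lam = state.lam - beta * (du - state.w)
        state.r = state.r - beta * state.g
    return state.u


def denoise_batch(B: np.ndarray, p: DenoiseParams | None = None) -> np.ndarray:
    """Denoise the rows of an (n, F) array (vectorised fixed-step ADMM)."""
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[1] < 2:
        raise InvalidInputError("expected an (n, F) array with F >= 2")
    if not np.all(np.isfinite(B)):
        raise InvalidInputError("input contains non-finite values")
    if p is None:
        p = DenoiseParams()
    if p.use_relative_error_stop:
        return np.stack([_admm_relative(row, p) for row in B])
    return _admm_batch_fixed(B, p)


def denoise_multi_echo(
    Y: MultiEchoSeries,
    p: DenoiseParams | None = None,
    mask: np.ndarray | None = None,
) -> MultiEchoSeries:
    """Apply the TV-l2 denoiser to every voxel x echo series of a 5D dataset.

    Each echo of each in-mask voxel is restored independently;
    out-of-mask voxels pass through unchanged.  The computation is
    deterministic and identical to looping :func:`admm_denoise_1d` over
    voxels.
    """
    mask = Y.check_mask(mask)
    if p is None:
        p = DenoiseParams()
    R, C, S, E, F = Y.data.shape
    out = Y.data.copy()
    flat = out.reshape(R * C * S, E, F)
    if mask is None:
        sel = np.ones(R * C * S, dtype=bool)
    else:
        sel = mask.ravel()
    series = flat[sel].reshape(-1, F)
    flat[sel] = denoise_batch(series, p).reshape(-1, E, F)
    return replace(Y, data=flat.reshape(R, C, S, E, F))
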