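"""White-matter / CSF nuisance regression.

Non-neural signal fluctuations shared across WM or CSF voxels are
summarised as the first principal component of the detrended in-mask
time series and regressed out of the data with a three-column GLM
(WM, CSF, constant).  The constant's fitted effect is retained so the
mean signal intensity is unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import detrend as _lin_detrend

from .data import InvalidInputError, as_series

__all__ = ["representative_series", "regress_nuisance", "regress_nuisance_4d"]


def representative_series(
    data: np.ndarray, tissue_mask: np.ndarray, detrend_degree: int = 1
) -> np.ndarray:
    """First principal component of the detrended in-mask voxel series.

    Each in-mask series is detrended (linear by default), the [F x n_vox]
    matrix column-centred, and the first left singular vector returned as
    a unit-norm series.  Its sign is fixed so that the correlation with
    the mean in-mask series is non-negative.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise InvalidInputError("data must be 4D [R,C,S,F]")
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != data.shape[:3]:
        raise InvalidInputError("tissue mask shape mismatch")
    if not tissue_mask.any():
        raise InvalidInputError("tissue mask is empty")
    X = data[tissue_mask].T  # (F, n_vox)
    if detrend_degree == 1:
        X = _lin_detrend(X, axis=0)
    else:
        F = X.shape[0]
        t = np.arange(F, dtype=float)
        A = np.vander(t - t.mean(), detrend_degree + 1)
        coef, *_ = np.linalg.lstsq(A, X, rcond=None)
        X = X - A @ coef
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    pc = U[:, 0]
    ref = X.mean(axis=1)
    if pc @ ref < 0:
        pc = -pc
    return pc


def regress_nuisance(x, wm, csf) -> np.ndarray:
    """Remove the fitted WM and CSF effects from one series.

    Least-squares fit of ``x`` on ``[wm, csf, 1]``; the output is
    ``x - beta_wm * wm - beta_csf * csf`` (the constant's effect stays in
    the data).  A rank-deficient design (wm proportional to csf) is
    solved by pseudo-inverse and flagged with a warning.
    """
    x = as_series(x, "x")
    wm = as_series(wm, "wm")
    csf = as_series(csf, "csf")
    if not (x.size == wm.size == csf.size):
        raise InvalidInputError("series lengths must match")
    A = np.stack([wm, csf, np.ones_like(x)], axis=1)
    if np.linalg.matrix_rank(A) < 3:
        warnings.warn("rank-deficient nuisance design (wm ~ csf); using "
                      "pseudo-inverse solution", RuntimeWarning, stacklevel=2)
    beta, *_ = np.linalg.lstsq(A, x, rcond=None)
    return x - beta[0] * wm - beta[1] * csf


def regress_nuisance_4d(data: np.ndarray, wm, csf,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Vectorised nuisance regression over a 4D [R,C,S,F] series."""
    data = np.asarray(data, dtype=float)
    wm = as_series(wm, "wm")
    csf = as_series(csf, "csf")
    F = data.shape[-1]
    if wm.size != F or csf.size != F:
        raise InvalidInputError("regressor length must match frame count")
    A = np.stack([wm, csf, np.ones(F)], axis=1)
    flat = data.reshape(-1, F)
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).ravel()
    else:
        sel = np.ones(flat.shape[0], dtype=bool)
    beta, *_ = np.linalg.lstsq(A, flat[sel].T, rcond=None)
    out = flat.copy()
    out[sel] = (flat[sel].T - A[:, :2] @ beta[:2]).T
    return out.reshape(data.shape)
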