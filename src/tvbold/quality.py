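"""BOLD signal quality metrics: tSNR, CNR, shift-invariant similarity.

tSNR is the temporal mean over the residual standard deviation after
second-order polynomial detrending (computed on resting-state runs).
CNR is the task contrast ``dS / sigma``, where ``dS`` is the ON-OFF mean
difference extracted by a lag-maximised circular cross-correlation with
an averaging boxcar and ``sigma`` is the noise level of a matched
resting-state run.  Similarity between a voxel series and the normalised
hemodynamic response is the maximum magnitude of their normalised
circular cross-correlation, which is invariant to the hemodynamic lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .data import InvalidInputError, as_series
from .stimulus import TaskDesign, boxcar

__all__ = [
    "DegenerateSeriesError",
    "SimilarityResult",
    "normalize_series",
    "circular_similarity",
    "tsnr",
    "averaging_boxcar",
    "cnr",
    "tsnr_map",
    "similarity_map",
    "cnr_map",
    "quality_maps",
    "ranksum_compare",
]


class DegenerateSeriesError(ValueError):
    """A constant series cannot be normalised or correlated."""


@dataclass(frozen=True)
class SimilarityResult:
    best_corr: float  # in [0, 1]
    best_lag: int     # frames, 0 <= lag < F


def normalize_series(x) -> np.ndarray:
    """Zero-mean, unit-energy normalisation (sum of squares = 1)."""
    x = as_series(x, "x")
    c = x - x.mean()
    ss = np.sum(c * c)
    if ss == 0:
        raise DegenerateSeriesError("constant series cannot be normalised")
    return c / np.sqrt(ss)


def _circular_corr(xn: np.ndarray, yn: np.ndarray) -> np.ndarray:
    # c[k] = sum_t xn[t] * yn[(t + k) mod F], all k, via FFT; with
    # y = roll(x, k) the maximum sits at lag k
    F = xn.shape[-1]
    return np.fft.irfft(
        np.conj(np.fft.rfft(xn, axis=-1)) * np.fft.rfft(yn, axis=-1), n=F, axis=-1
    )


def circular_similarity(x, y) -> SimilarityResult:
    """Maximum magnitude of the normalised circular cross-correlation.

    Both series are normalised to zero mean and unit energy; the circular
    cross-correlation is evaluated at all F integer lags and the maximum
    of its magnitude returned together with the attaining lag.  The value
    lies in [0, 1]; 1 means the series are identical up to a circular
    shift and an affine rescaling.
    """
    x = as_series(x, "x")
    y = as_series(y, "y")
    if x.size != y.size:
        raise InvalidInputError("series must have equal length")
    c = _circular_corr(normalize_series(x), normalize_series(y))
    k = int(np.argmax(np.abs(c)))
    return SimilarityResult(best_corr=float(np.abs(c[k])), best_lag=k)


_DETREND_ORDER = 2


def _detrend_residual_sd(X: np.ndarray) -> np.ndarray:
    """Residual SD after least-squares 2nd-order polynomial detrending.

    ``X`` has shape (..., F); the denominator is F - 3 (degrees of
    freedom of the quadratic fit).
    """
    F = X.shape[-1]
    t = np.arange(F, dtype=float)
    t = (t - t.mean()) / max(t.std(), 1.0)  # scaled monomials, F <= 1e4
    A = np.stack([np.ones(F), t, t * t], axis=1)
    coef, *_ = np.linalg.lstsq(A, X.reshape(-1, F).T, rcond=None)
    resid = X.reshape(-1, F).T - A @ coef
    sd = np.sqrt((resid**2).sum(axis=0) / (F - 3))
    return sd.reshape(X.shape[:-1])


def tsnr(x) -> tuple[float, float]:
    """Temporal SNR of one series.

    Returns ``(tsnr, sigma)`` with ``sigma`` the residual standard
    deviation after removing a second-order polynomial trend and
    ``tsnr = mean(x) / sigma``.  A perfectly quadratic series has
    ``sigma = 0`` and reports infinite tSNR rather than raising.
    """
    x = as_series(x, "x")
    if x.size < 4:
        raise InvalidInputError("tsnr needs at least 4 frames")
    sigma = float(_detrend_residual_sd(x[None, :])[0])
    # residuals at rounding level mean the trend explains everything
    if sigma <= 1e-10 * (np.sqrt(np.mean(x * x)) + 1.0):
        return float("inf"), 0.0
    return float(x.mean() / sigma), sigma


def averaging_boxcar(design: TaskDesign, n_frames: int) -> np.ndarray:
    """Zero-sum averaging weights: +1/#ON on ON frames, -1/#OFF on OFF.

    The dot product with a series equals mean(ON frames) - mean(OFF
    frames).
    """
    on = boxcar(design, n_frames) > 0
    n_on = int(on.sum())
    n_off = int(n_frames - n_on)
    if n_on == 0 or n_off == 0:
        raise InvalidInputError("design must yield at least one ON and one OFF frame")
    out = np.where(on, 1.0 / n_on, -1.0 / n_off)
    return out


def cnr(x, avg, sigma: float) -> float:
    """Contrast-to-noise ratio ``dS / sigma``.

    ``dS`` is the maximum over circular lags of the cross-correlation of
    the series with the averaging boxcar — the ON-OFF mean difference at
    the hemodynamic lag.  ``sigma`` is the non-task noise level,
    typically from a matched resting-state run.
    """
    x = as_series(x, "x")
    avg = as_series(avg, "avg")
    if x.size != avg.size:
        raise InvalidInputError("series and averaging boxcar must have equal length")
    if sigma <= 0:
        raise InvalidInputError("sigma must be positive")
    ds = float(_circular_corr(x[None, :], avg[None, :]).max())
    return ds / sigma


def tsnr_map(series: np.ndarray, mask: np.ndarray | None = None):
    """Voxelwise tSNR and sigma over a 4D [R, C, S, F] series."""
    series = np.asarray(series, dtype=float)
    sd = _detrend_residual_sd(series)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = series.mean(axis=-1) / sd
    if mask is not None:
        snr = np.where(mask, snr, np.nan)
        sd = np.where(mask, sd, np.nan)
    return snr, sd


def similarity_map(series: np.ndarray, response: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise best circular correlation with a reference response."""
    series = np.asarray(series, dtype=float)
    F = series.shape[-1]
    flat = series.reshape(-1, F)
    cent = flat - flat.mean(axis=-1, keepdims=True)
    energy = np.sqrt((cent**2).sum(axis=-1, keepdims=True))
    ok = energy[:, 0] > 0
    xn = np.where(energy > 0, cent / np.where(energy > 0, energy, 1.0), 0.0)
    yn = normalize_series(response)
    c = _circular_corr(xn, yn[None, :])
    best = np.abs(c).max(axis=-1)
    best[~ok] = np.nan
    best = best.reshape(series.shape[:-1])
    if mask is not None:
        best = np.where(mask, best, np.nan)
    return best


def cnr_map(series: np.ndarray, design: TaskDesign, sigma_map: np.ndarray,
            mask: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise CNR of a 4D task series given a matched noise map."""
    series = np.asarray(series, dtype=float)
    F = series.shape[-1]
    avg = averaging_boxcar(design, F)
    ds = _circular_corr(series.reshape(-1, F), avg[None, :]).max(axis=-1)
    ds = ds.reshape(series.shape[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ds / sigma_map
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out


def quality_maps(series: np.ndarray, metric: str, *, design: TaskDesign | None = None,
                 response: np.ndarray | None = None,
                 sigma_map: np.ndarray | None = None,
                 mask: np.ndarray | None = None):
    """Dispatch voxelwise metric computation over a 4D series.

    ``metric`` is one of ``'tsnr'`` (returns (tsnr, sigma) maps),
    ``'cnr'`` (needs ``design`` and ``sigma_map``) or ``'similarity'``
    (needs ``response``).
    """
    if metric == "tsnr":
        return tsnr_map(series, mask)
    if metric == "cnr":
        if design is None or sigma_map is None:
            raise InvalidInputError("cnr needs design and sigma_map")
        return cnr_map(series, design, sigma_map, mask)
    if metric == "similarity":
        if response is None:
            raise InvalidInputError("similarity needs a reference response")
        return similarity_map(series, response, mask)
    raise InvalidInputError(f"unknown metric {metric!r}")


def ranksum_compare(a, b, tail: str = "two-sided"):
    """Wilcoxon rank-sum comparison of two metric distributions.

    Exact p-value for small untied samples, normal approximation with tie
    correction otherwise.  ``tail`` is ``'two-sided'``, ``'greater'``
    (median of ``a`` higher) or ``'less'``.  Returns
    ``(p, median_a, iqr_a, median_b, iqr_b)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be nonempty")
    if tail not in ("two-sided", "greater", "less"):
        raise InvalidInputError("tail must be two-sided, greater or less")
    small = a.size <= 20 and b.size <= 20
    method = "exact" if small and np.unique(np.concatenate([a, b])).size == a.size + b.size else "asymptotic"
    res = mannwhitneyu(a, b, alternative=tail, method=method)
    iqr = lambda x: float(np.subtract(*np.percentile(x, [75, 25])))
    return (float(res.pvalue), float(np.median(a)), iqr(a),
            float(np.median(b)), iqr(b))
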