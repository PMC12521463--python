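"""Brain masking, voxel filtering and FDR-based ROI construction.

The subject-specific brain mask is cut from the bimodal intensity
histogram of the whole series (air/background peak vs. tissue peak); the
threshold sits at the emptiest bin between the two peaks.  Voxels whose
time-averaged echo means do not decrease strictly with echo time violate
the decay model and are excluded.  The task ROI collects voxels whose
echo-2 time course correlates with the normalised hemodynamic response,
converting each best circular correlation to a t-statistic and p-value
and controlling the false discovery rate with the Benjamini-Hochberg
step-up rule at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as _t_dist

from .data import InvalidInputError, MultiEchoSeries
from .quality import similarity_map, normalize_series

__all__ = [
    "BrainMask",
    "FDRResult",
    "FDRRoi",
    "brain_mask_from_histogram",
    "monotonic_echo_filter",
    "correlation_to_p",
    "bh_fdr",
    "fdr_roi",
]


@dataclass
class BrainMask:
    mask: np.ndarray          # boolean [R, C, S]
    threshold: float          # signal units
    bimodal: bool = True      # False when the unimodal fallback fired


@dataclass
class FDRResult:
    p: np.ndarray             # per-test p-values
    alpha: float
    significant: np.ndarray   # indices into p of the declared discoveries
    n_tests: int


@dataclass
class FDRRoi:
    """Subject-specific ROI with its per-voxel statistics."""

    roi: np.ndarray                       # boolean [R, C, S]
    indices: np.ndarray                   # (n_sig, 3) voxel coordinates
    table: pd.DataFrame = field(repr=False)  # rho, t, p per tested voxel


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def _otsu_threshold(centers: np.ndarray, counts: np.ndarray) -> float:
    # maximise between-class variance on the histogram
    w = counts.astype(float)
    total = w.sum()
    best, best_t = -1.0, centers[len(centers) // 2]
    csum = np.cumsum(w)
    cmean = np.cumsum(w * centers)
    mean_all = cmean[-1] / total
    for i in range(1, len(centers)):
        w0 = csum[i - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = cmean[i - 1] / w0
        m1 = (cmean[-1] - cmean[i - 1]) / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best:
            best, best_t = v, 0.5 * (centers[i - 1] + centers[i])
    return float(best_t)


def brain_mask_from_histogram(
    Y, n_bins: int = 256, smooth_window: int = 5
) -> BrainMask:
    """Brain mask from the bimodal intensity histogram of a whole series.

    Builds the histogram of all samples of the (4D or 5D) series, smooths
    it lightly with a moving average, finds the two dominant local
    maxima, and places the threshold at the centre of the lowest-count
    bin strictly between them.  The mask keeps voxels whose time-mean
    exceeds the threshold.  A unimodal histogram triggers a fallback to
    Otsu's single threshold with a warning.
    """
    if isinstance(Y, MultiEchoSeries):
        data = Y.data
    else:
        data = np.asarray(Y, dtype=float)
    if data.ndim not in (4, 5):
        raise InvalidInputError("expected a 4D [R,C,S,F] or 5D [R,C,S,E,F] series")
    flat = data.ravel()
    if flat.max() == flat.min():
        raise InvalidInputError("constant data has no histogram structure")
    counts, edges = np.histogram(flat, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = _moving_average(counts.astype(float), smooth_window)

    interior = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] > smooth[2:])
    peaks = np.flatnonzero(interior) + 1
    if smooth[0] > smooth[1]:
        peaks = np.concatenate([[0], peaks])
    if smooth[-1] > smooth[-2]:
        peaks = np.concatenate([peaks, [n_bins - 1]])

    bimodal = peaks.size >= 2
    if bimodal:
        top2 = peaks[np.argsort(smooth[peaks])[-2:]]
        lo, hi = int(top2.min()), int(top2.max())
        if hi - lo < 2:
            bimodal = False
        else:
            # two genuine modes are separated by a deep valley; count
            # ripples on a single mode are not
            valley_height = smooth[lo + 1 : hi].min()
            if valley_height > 0.5 * min(smooth[lo], smooth[hi]):
                bimodal = False
    if bimodal:
        valley = lo + 1 + int(np.argmin(counts[lo + 1 : hi]))
        threshold = float(centers[valley])
    else:
        warnings.warn(
            "intensity histogram is not bimodal; falling back to Otsu's "
            "single-threshold heuristic",
            RuntimeWarning,
            stacklevel=2,
        )
        threshold = _otsu_threshold(centers, counts)

    time_axes = tuple(range(3, data.ndim))
    mean_img = data.mean(axis=time_axes)
    return BrainMask(mask=mean_img > threshold, threshold=threshold, bimodal=bimodal)


def monotonic_echo_filter(Y: MultiEchoSeries) -> np.ndarray:
    """Keep voxels whose time-averaged echo means strictly decrease.

    A voxel passes iff ``mean(echo 1) > mean(echo 2) > ... > mean(echo E)``
    where each mean is taken over frames.
    """
    if Y.n_echoes < 2:
        raise InvalidInputError("need at least two echoes")
    means = Y.data.mean(axis=4)  # (R, C, S, E)
    return np.all(np.diff(means, axis=3) < 0, axis=3)


def correlation_to_p(rho: float, n: int) -> float:
    """p-value of a correlation via the Student-t transform.

    ``t = rho * sqrt(n - 2) / sqrt(1 - rho^2)`` with n - 2 degrees of
    freedom; ``p = 2 * (1 - P(t))``.  ``|rho| >= 1`` maps to p = 0 by
    convention.
    """
    if n < 3:
        raise InvalidInputError("need n >= 3")
    if abs(rho) >= 1:
        return 0.0
    t = rho * np.sqrt(n - 2) / np.sqrt(1.0 - rho * rho)
    return float(2.0 * _t_dist.sf(t, df=n - 2))


def bh_fdr(p, alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up rule.

    Sort the p-values ascending, find the largest k with
    ``p_(k) <= k * alpha / n`` and declare those k tests significant; on
    average a fraction alpha of the discoveries are false positives.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise InvalidInputError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise InvalidInputError("alpha must lie in (0, 1)")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passes = ranked <= (np.arange(1, n + 1) * alpha / n)
    if passes.any():
        k = int(np.flatnonzero(passes)[-1]) + 1
        sig = np.sort(order[:k])
    else:
        sig = np.array([], dtype=int)
    return FDRResult(p=p, alpha=alpha, significant=sig, n_tests=n)


def fdr_roi(
    echo2: np.ndarray,
    response: np.ndarray,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
) -> FDRRoi:
    """Subject-specific ROI from echo-2 / hemodynamic-response correlation.

    Per in-mask voxel: best circular correlation rho of the echo-2 time
    course with the normalised response; Student-t p-value with n = F;
    Benjamini-Hochberg selection at ``alpha``.
    """
    echo2 = np.asarray(echo2, dtype=float)
    if echo2.ndim != 4:
        raise InvalidInputError("echo2 must be a 4D [R,C,S,F] series")
    F = echo2.shape[-1]
    response = normalize_series(response)
    if response.size != F:
        raise InvalidInputError("response length must match frame count")
    if mask is None:
        mask = np.ones(echo2.shape[:3], dtype=bool)
    rho_map = similarity_map(echo2, response, mask)
    coords = np.argwhere(mask & np.isfinite(rho_map))
    rho = rho_map[tuple(coords.T)]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = rho * np.sqrt(F - 2) / np.sqrt(1.0 - rho * rho)
    p = np.where(np.abs(rho) >= 1, 0.0, 2.0 * _t_dist.sf(tval, df=F - 2))
    res = bh_fdr(p, alpha)
    sig_coords = coords[res.significant]
    roi = np.zeros(echo2.shape[:3], dtype=bool)
    roi[tuple(sig_coords.T)] = True
    table = pd.DataFrame(
        {"r": coords[:, 0], "c": coords[:, 1], "s": coords[:, 2],
         "rho": rho, "t": tval, "p": p,
         "significant": np.isin(np.arange(len(p)), res.significant)}
    )
    return FDRRoi(roi=roi, indices=sig_coords, table=table)
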