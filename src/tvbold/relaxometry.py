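"""Monoexponential echo decay and dynamic T2* mapping.

The transverse magnetisation decays as ``e = S0 * exp(-TE / T2*)``:
``S0`` is the initial signal intensity, ``TE`` the echo time and ``T2*``
the effective decay time constant, all times in milliseconds.  With at
least two echoes per frame, ``(S0, T2*)`` are estimated frame by frame by
a weighted least-squares fit of ``ln e`` on the echo times.  Taking the
logarithm makes the noise on late (weak) echoes loom large —
``Var[ln e] ~ sigma^2 / e^2`` — so the fit compensates by weighting each
echo by its squared amplitude (configurable).

Voxels/frames whose echoes are non-positive or do not decay
monotonically carry no physical estimate and are marked invalid (NaN plus
a boolean validity mask); no clamping or upper T2* bound is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EchoTimes, InvalidInputError, MultiEchoSeries

__all__ = [
    "NonMonotonicDecayError",
    "RelaxFit",
    "T2StarMap",
    "mono_exp",
    "t2star_two_echo",
    "t2star_loglin_weighted",
    "dynamic_t2star_map",
]

WEIGHTINGS = ("uniform", "amplitude", "amplitude2")


class NonMonotonicDecayError(ValueError):
    """Echo pair/sequence does not decay with echo time."""


@dataclass(frozen=True)
class RelaxFit:
    """Result of a single monoexponential fit."""

    s0: float
    t2star_ms: float
    valid: bool


@dataclass
class T2StarMap:
    """Dynamic T2* map: arrays of shape [R, C, S, F].

    Invalid fits are NaN in ``t2star``/``s0`` and False in ``valid``.
    """

    t2star: np.ndarray
    s0: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        if not (self.t2star.shape == self.s0.shape == self.valid.shape):
            raise InvalidInputError("t2star, s0 and valid must share a shape")

    def filled(self) -> np.ndarray:
        """T2* series with invalid frames replaced by the voxel's mean.

        Convenient for temporal statistics (tSNR, CNR, similarity) that
        need gap-free series; voxels with no valid frame stay all-NaN.
        """
        x = np.where(self.valid, self.t2star, np.nan)
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(x, axis=-1, keepdims=True)
        return np.where(np.isnan(x), mu, x)


def mono_exp(s0: float, t2star_ms: float, te_ms) -> np.ndarray | float:
    """Monoexponential echo model ``s0 * exp(-te / t2star)``."""
    if s0 <= 0 or t2star_ms <= 0:
        raise InvalidInputError("s0 and t2star_ms must be positive")
    te = np.asarray(te_ms, dtype=float)
    if np.any(te < 0):
        raise InvalidInputError("echo times must be >= 0")
    out = s0 * np.exp(-te / t2star_ms)
    return float(out) if out.ndim == 0 else out


def t2star_two_echo(e1: float, e2: float, t1_ms: float, t2_ms: float) -> float:
    """Two-echo log-linear T2* estimate ``(t2 - t1) / (ln e1 - ln e2)``.

    Requires a decaying pair ``e1 > e2 > 0``; a non-decaying pair has no
    positive T2* and raises :class:`NonMonotonicDecayError`.
    """
    if e1 <= 0 or e2 <= 0:
        raise InvalidInputError("echo intensities must be positive")
    if t2_ms <= t1_ms:
        raise InvalidInputError("t2_ms must exceed t1_ms")
    if e1 <= e2:
        raise NonMonotonicDecayError(
            f"echo pair does not decay (e1={e1} <= e2={e2})"
        )
    return (t2_ms - t1_ms) / (np.log(e1) - np.log(e2))


def _weights(echoes: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "uniform":
        return np.ones_like(echoes)
    if weighting == "amplitude":
        return echoes
    if weighting == "amplitude2":
        return echoes**2
    raise InvalidInputError(f"unknown weighting {weighting!r}; use one of {WEIGHTINGS}")


def t2star_loglin_weighted(
    echoes, te: EchoTimes, weighting: str = "amplitude2"
) -> RelaxFit:
    """Weighted log-linear monoexponential fit of one echo vector.

    Weighted least squares of ``ln e`` on ``(1, -te)``: the slope gives
    ``1 / T2*`` and the intercept ``ln S0``.  Default weights are the
    squared echo amplitudes, the standard variance compensation for
    log-transformed Gaussian-noise data.  Returns ``valid=False`` when
    any echo is non-positive or the sequence does not strictly decrease.
    """
    e = np.asarray(echoes, dtype=float).ravel()
    if not isinstance(te, EchoTimes):
        te = EchoTimes(te)
    if e.size != len(te):
        raise InvalidInputError("echo vector length must match echo times")
    if e.size < 2:
        raise InvalidInputError("need at least two echoes")
    if not np.all(np.isfinite(e)):
        raise InvalidInputError("echoes must be finite")
    if np.any(e <= 0) or np.any(np.diff(e) >= 0):
        return RelaxFit(s0=float("nan"), t2star_ms=float("nan"), valid=False)
    t = te.te_ms
    w = _weights(e, weighting)
    y = np.log(e)
    wsum = w.sum()
    tbar = (w * t).sum() / wsum
    ybar = (w * y).sum() / wsum
    stt = (w * (t - tbar) ** 2).sum()
    sty = (w * (t - tbar) * (y - ybar)).sum()
    slope = sty / stt  # = -1 / T2*
    intercept = ybar - slope * tbar
    t2 = -1.0 / slope
    return RelaxFit(s0=float(np.exp(intercept)), t2star_ms=float(t2), valid=True)


def dynamic_t2star_map(
    Y: MultiEchoSeries,
    mask: np.ndarray | None = None,
    weighting: str = "amplitude2",
) -> T2StarMap:
    """Frame-by-frame weighted log-linear T2* fit of a 5D dataset.

    Applies :func:`t2star_loglin_weighted` to the E echo values of every
    in-mask voxel at every frame (vectorised).  Out-of-mask voxels and
    invalid fits are NaN with ``valid=False``.
    """
    mask = Y.check_mask(mask)
    if Y.n_echoes < 2:
        raise InvalidInputError("dynamic T2* mapping needs at least two echoes")
    data = Y.data  # (R, C, S, E, F)
    t = Y.te.te_ms[:, None]  # (E, 1)
    ok = np.all(data > 0, axis=3) & np.all(np.diff(data, axis=3) < 0, axis=3)
    if mask is not None:
        ok &= mask[..., None]

    with np.errstate(divide="ignore", invalid="ignore"):
        w = _weights(data, weighting)
        y = np.where(data > 0, np.log(np.where(data > 0, data, 1.0)), 0.0)
        wsum = w.sum(axis=3)
        tbar = (w * t).sum(axis=3) / wsum
        ybar = (w * y).sum(axis=3) / wsum
        tc = t - tbar[..., None, :]  # broadcast (R,C,S,E,F)
        stt = (w * tc**2).sum(axis=3)
        sty = (w * tc * (y - ybar[..., None, :])).sum(axis=3)
        slope = sty / stt
        t2 = -1.0 / slope
        s0 = np.exp(ybar - slope * tbar)

    t2 = np.where(ok, t2, np.nan)
    s0 = np.where(ok, s0, np.nan)
    return T2StarMap(t2star=t2, s0=s0, valid=ok)
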