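"""Block-design task timing and the theoretical hemodynamic response.

The visual task alternates a fixation (OFF) epoch of 30.025 s with an
active (ON) epoch of 21.35 s, repeated for seven cycles.  The theoretical
response of an activated voxel is the task ON/OFF boxcar convolved with
the canonical hemodynamic response function (HRF), modelled as a
difference of two Gamma densities (response peak minus a delayed
undershoot).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .data import InvalidInputError

__all__ = ["TaskDesign", "HRFParams", "boxcar", "canonical_hrf", "theoretical_response"]


@dataclass(frozen=True)
class TaskDesign:
    """Block-design timing.  Durations in seconds; frames sampled at TR."""

    off_duration_s: float = 30.025
    on_duration_s: float = 21.35
    cycles: int = 7
    tr_s: float = 1.8
    starts_with: str = "off"

    def __post_init__(self):
        if self.off_duration_s <= 0 or self.on_duration_s <= 0:
            raise InvalidInputError("epoch durations must be positive")
        if self.cycles < 1:
            raise InvalidInputError("cycles must be >= 1")
        if self.tr_s <= 0:
            raise InvalidInputError("tr_s must be positive")
        if self.starts_with not in ("off", "on"):
            raise InvalidInputError("starts_with must be 'off' or 'on'")

    @property
    def period_s(self) -> float:
        return self.off_duration_s + self.on_duration_s

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(
            {"off_s": d["off_duration_s"], "on_s": d["on_duration_s"],
             "cycles": d["cycles"], "tr_s": d["tr_s"],
             "starts_with": d["starts_with"]}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        d = json.loads(text)
        return cls(
            off_duration_s=d.get("off_s", 30.025),
            on_duration_s=d.get("on_s", 21.35),
            cycles=d.get("cycles", 7),
            tr_s=d.get("tr_s", 1.8),
            starts_with=d.get("starts_with", "off"),
        )


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-Gamma HRF parameters (seconds where applicable)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise InvalidInputError(f"{name} must be positive")


def boxcar(design: TaskDesign, n_frames: int) -> np.ndarray:
    """Binary task ON/OFF indicator sampled at frame acquisition times.

    Frame ``v`` (0-based) is ON iff its acquisition time ``v * TR`` falls
    inside an ON interval; ON intervals are half-open
    ``[off, off + on)`` within each cycle (for ``starts_with='off'``).
    Frames beyond the last cycle are OFF.
    """
    if n_frames < 1:
        raise InvalidInputError("n_frames must be >= 1")
    t = np.arange(n_frames) * design.tr_s
    span = design.cycles * design.period_s
    phase = np.mod(t, design.period_s)
    if design.starts_with == "off":
        on = (phase >= design.off_duration_s)
    else:
        on = (phase < design.on_duration_s)
    on &= t < span
    return on.astype(float)


def canonical_hrf(tr_s: float, p: HRFParams | None = None) -> np.ndarray:
    """Canonical HRF sampled at the TR grid, normalised to unit sum.

    The kernel is ``g(t; peak) - g(t; undershoot) / ratio`` where ``g`` is
    the Gamma probability density with shape ``delay / dispersion`` and
    scale ``dispersion``, sampled at t = 0, TR, 2 TR, ... up to the kernel
    length.  The response peaks ~5 s after stimulus onset and has a late
    negative undershoot.
    """
    if tr_s <= 0:
        raise InvalidInputError("tr_s must be positive")
    if p is None:
        p = HRFParams()
    t = np.arange(0.0, p.kernel_length_s + 0.5 * tr_s, tr_s)
    peak = _gamma_dist.pdf(t, a=p.peak_delay_s / p.peak_dispersion,
                           scale=p.peak_dispersion)
    under = _gamma_dist.pdf(t, a=p.undershoot_delay_s / p.undershoot_dispersion,
                            scale=p.undershoot_dispersion)
    h = peak - under / p.peak_undershoot_ratio
    s = h.sum()
    if s == 0:
        raise InvalidInputError("degenerate HRF kernel (zero sum)")
    return h / s


def theoretical_response(
    design: TaskDesign,
    n_frames: int,
    p: HRFParams | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Theoretical hemodynamic response of an activated voxel.

    Linear (non-circular) convolution of the task boxcar with the
    canonical HRF kernel, truncated to ``n_frames``.  With
    ``normalize=True`` the result has zero mean and unit sum of squares
    (the normalised hemodynamic response common to all voxels).
    """
    box = boxcar(design, n_frames)
    h = canonical_hrf(design.tr_s, p)
    resp = np.convolve(box, h)[:n_frames]
    if normalize:
        from .quality import normalize_series

        resp = normalize_series(resp)
    return resp
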