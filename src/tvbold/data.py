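"""Shared in-memory containers for multi-echo fMRI data.

A multi-echo acquisition records, within each repetition time, one magnitude
image per echo time.  The whole run is held as a five-dimensional array

    Y[r, c, s, e, v]

with ``r`` rows, ``c`` columns, ``s`` slices of the 3D image grid, ``e``
indexing the echoes and ``v`` the acquired frames (volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


def as_series(x, name: str = "series") -> np.ndarray:
    """Validate and return a 1D time series as a float array.

    Requires length >= 2 and all-finite values.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise InvalidInputError(f"{name} must have at least 2 frames, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class EchoTimes:
    """Strictly increasing echo times in milliseconds."""

    te_ms: np.ndarray

    def __post_init__(self):
        te = np.asarray(self.te_ms, dtype=float).ravel()
        if te.size < 1:
            raise InvalidInputError("need at least one echo time")
        if np.any(te <= 0):
            raise InvalidInputError("echo times must be positive")
        if te.size > 1 and np.any(np.diff(te) <= 0):
            raise InvalidInputError("echo times must be strictly increasing")
        object.__setattr__(self, "te_ms", te)

    def __len__(self) -> int:
        return int(self.te_ms.size)


@dataclass
class MultiEchoSeries:
    """5D multi-echo dataset of shape [R, C, S, E, F].

    Parameters
    ----------
    data : ndarray, shape (R, C, S, E, F)
        BOLD signal values in arbitrary scanner units.
    te : EchoTimes
        Echo times (ms); ``len(te)`` must equal ``E``.
    tr_s : float
        Repetition time (frame sampling interval) in seconds.
    affine : ndarray, optional
        4x4 voxel-to-world affine carried along for NIfTI round-trips.
    """

    data: np.ndarray
    te: EchoTimes
    tr_s: float
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise InvalidInputError(
                f"expected 5D array [R,C,S,E,F], got shape {self.data.shape}"
            )
        if not isinstance(self.te, EchoTimes):
            self.te = EchoTimes(self.te)
        if self.data.shape[3] != len(self.te):
            raise InvalidInputError(
                f"echo axis has {self.data.shape[3]} entries but {len(self.te)} "
                "echo times were given"
            )
        if any(d < 1 for d in self.data.shape):
            raise InvalidInputError("all dimensions must be >= 1")
        if self.tr_s <= 0:
            raise InvalidInputError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("data contains non-finite values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[4]

    def echo(self, e: int) -> np.ndarray:
        """Return the 4D [R, C, S, F] series of echo index ``e`` (0-based)."""
        return self.data[:, :, :, e, :]

    def check_mask(self, mask: np.ndarray | None) -> np.ndarray | None:
        if mask is None:
            return None
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.spatial_shape:
            raise InvalidInputError(
                f"mask shape {mask.shape} does not match spatial shape "
                f"{self.spatial_shape}"
            )
        return mask
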