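"""NIfTI-1 I/O for per-echo 4D series and result maps.

The on-disk convention is one 4D NIfTI-1 file per echo (the dominant
multi-echo layout); in memory they are assembled into the 5D
[R, C, S, E, F] container.  Result maps are written as float32 with
invalid entries encoded as NaN; masks as uint8.  Every output directory
gets a provenance JSON recording parameters and versions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .data import EchoTimes, InvalidInputError, MultiEchoSeries
from .stimulus import TaskDesign

__all__ = [
    "AcquisitionConfig",
    "load_multi_echo",
    "save_multi_echo",
    "save_map",
    "save_mask",
    "write_provenance",
]


@dataclass
class AcquisitionConfig:
    echo_files: list[str]
    te_ms: EchoTimes
    tr_s: float
    design: TaskDesign | None = None

    def __post_init__(self):
        if not isinstance(self.te_ms, EchoTimes):
            self.te_ms = EchoTimes(np.asarray(self.te_ms))
        if len(self.echo_files) != len(self.te_ms):
            raise InvalidInputError(
                f"{len(self.echo_files)} echo files but {len(self.te_ms)} echo times"
            )

    @classmethod
    def from_json(cls, path) -> "AcquisitionConfig":
        d = json.loads(Path(path).read_text())
        design = None
        if d.get("design") is not None:
            design = TaskDesign.from_json(json.dumps(d["design"]))
        return cls(echo_files=d["echo_files"], te_ms=np.asarray(d["te_ms"]),
                   tr_s=d["tr_s"], design=design)


def load_multi_echo(cfg: AcquisitionConfig) -> MultiEchoSeries:
    """Assemble per-echo 4D NIfTI files into a 5D series.

    All files must share grid shape, frame count and affine; the first
    file's affine is carried along for round-trips.
    """
    arrays, affines = [], []
    for f in cfg.echo_files:
        img = nib.load(str(f))
        arr = np.asarray(img.get_fdata(), dtype=float)
        if arr.ndim == 3:
            arr = arr[..., None]
        if arr.ndim != 4:
            raise InvalidInputError(f"{f}: expected a 4D image, got {arr.ndim}D")
        arrays.append(arr)
        affines.append(img.affine)
    ref_shape, ref_aff = arrays[0].shape, affines[0]
    for f, arr, aff in zip(cfg.echo_files, arrays, affines):
        if arr.shape != ref_shape:
            raise InvalidInputError(
                f"{f}: shape {arr.shape} does not match first echo {ref_shape}"
            )
        if not np.allclose(aff, ref_aff):
            raise InvalidInputError(f"{f}: affine differs from first echo")
    data = np.stack(arrays, axis=3)  # (R, C, S, E, F)
    return MultiEchoSeries(data=data, te=cfg.te_ms, tr_s=cfg.tr_s, affine=ref_aff)


def _affine(series_or_affine):
    if isinstance(series_or_affine, MultiEchoSeries):
        aff = series_or_affine.affine
    else:
        aff = series_or_affine
    return np.eye(4) if aff is None else np.asarray(aff)


def save_multi_echo(series: MultiEchoSeries, out_dir, prefix: str = "echo") -> list[Path]:
    """Write one float32 4D NIfTI per echo; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(series)
    paths = []
    for e in range(series.n_echoes):
        p = out_dir / f"{prefix}{e + 1}.nii.gz"
        img = nib.Nifti1Image(series.echo(e).astype(np.float32), aff)
        nib.save(img, str(p))
        paths.append(p)
    return paths


def save_map(data: np.ndarray, affine, path) -> Path:
    """Write a float32 map; invalid entries should already be NaN."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(affine))
    nib.save(img, str(path))
    return path


def save_mask(mask: np.ndarray, affine, path) -> Path:
    """Write a boolean mask as uint8."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(affine))
    nib.save(img, str(path))
    return path


def write_provenance(out_dir, params: dict, seed: int | None = None) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "tvbold_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "params": params,
    }
    p = out_dir / "provenance.json"
    p.write_text(json.dumps(record, indent=2, default=str))
    return p
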