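"""NIfTI volume I/O and YAML configuration handling.

Complex volumes are stored as two real NIfTI files — magnitude + phase (in
radians) by default, or real + imaginary with ``convention="realimag"`` —
for the widest toolchain compatibility. World coordinates follow the NIfTI
affine; voxel indices are 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import GridGeometry

COMPLEX_CONVENTIONS = ("magphase", "realimag")
COMPLEX_SUFFIXES = {
    "magphase": ("_mag.nii.gz", "_phase.nii.gz"),
    "realimag": ("_real.nii.gz", "_imag.nii.gz"),
}


@dataclass
class VolumeFile:
    """A loaded NIfTI volume with its affine and free-form metadata."""

    data: np.ndarray
    affine: np.ndarray
    path: Path | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or np.linalg.det(self.affine[:3, :3]) == 0:
            raise ValueError("affine must be an invertible 4x4 matrix")


def default_affine(geometry: GridGeometry) -> np.ndarray:
    """Scaling affine mapping voxel index to mm for a given geometry."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = geometry.voxel_size
    return aff


def write_volume(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> VolumeFile:
    path = Path(path)
    img = nib.load(str(path))
    return VolumeFile(
        data=np.asarray(img.dataobj, dtype=np.float32),
        affine=np.asarray(img.affine),
        path=path,
    )


def write_complex_volume(
    data: np.ndarray,
    base_path: str | Path,
    affine: np.ndarray | None = None,
    convention: str = "magphase",
) -> tuple[Path, Path]:
    """Write a complex volume as a documented pair of real NIfTI files."""
    if convention not in COMPLEX_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    base = Path(base_path)
    sfx = COMPLEX_SUFFIXES[convention]
    data = np.asarray(data, dtype=complex)
    if convention == "magphase":
        parts = (np.abs(data), np.angle(data))
    else:
        parts = (data.real, data.imag)
    paths = tuple(base.with_name(base.name + s) for s in sfx)
    for part, p in zip(parts, paths):
        write_volume(part, p, affine)
    return paths


def read_complex_volume(
    path_a: str | Path, path_b: str | Path, convention: str = "magphase"
) -> VolumeFile:
    """Read a complex volume from its file pair; shapes and affines must match."""
    if convention not in COMPLEX_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    va, vb = read_volume(path_a), read_volume(path_b)
    if va.data.shape != vb.data.shape:
        raise ValueError(
            f"shape mismatch between {path_a} {va.data.shape} "
            f"and {path_b} {vb.data.shape}"
        )
    if not np.allclose(va.affine, vb.affine):
        raise ValueError(f"affine mismatch between {path_a} and {path_b}")
    if convention == "magphase":
        data = va.data * np.exp(1j * vb.data.astype(float))
    else:
        data = va.data + 1j * vb.data
    return VolumeFile(data=data, affine=va.affine, path=Path(path_a))


def save_config(obj, path: str | Path) -> Path:
    """Serialize a (dataclass) config to YAML."""
    path = Path(path)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
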