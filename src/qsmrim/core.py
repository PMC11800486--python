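"""Shared containers: grid geometry, susceptibility / field maps, echo series.

Conventions
-----------
* Grids are 3D numpy arrays indexed ``[i, j, k]``; axis 2 is the slab's
  thin (slice) axis unless stated otherwise.
* Susceptibility and field values are in ppm (parts per million of B0).
* ``b0_direction`` is a unit vector in the grid frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Reduced gyromagnetic ratio of the proton, Hz/T.
GAMMA_HZ_PER_T = 42.577e6


def _as_unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid geometry for a rectangular 3D field of view.

    Parameters
    ----------
    shape : tuple of 3 ints
        Grid dimensions in voxels; each component must be >= 16.
    voxel_size : tuple of 3 floats
        Voxel edge lengths in mm.
    b0_direction : tuple of 3 floats
        Unit vector of the main magnetic field in the grid frame.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise ValueError(f"shape components must be >= 16, got {shape}")
        if len(voxel) != 3 or any(v <= 0 for v in voxel):
            raise ValueError(f"voxel_size components must be > 0, got {voxel}")
        b0 = np.asarray(self.b0_direction, dtype=float)
        if abs(np.linalg.norm(b0) - 1.0) > 1e-9:
            b0 = _as_unit(b0)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        object.__setattr__(self, "b0_direction", tuple(float(x) for x in b0))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the grid centre (voxel centres at (i+0.5)*d)."""
        return np.asarray(self.extent_mm) / 2.0

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open-mesh arrays of voxel-centre coordinates in mm, one per axis."""
        axes = [
            (np.arange(n) + 0.5) * d for n, d in zip(self.shape, self.voxel_size)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


@dataclass
class SusceptibilityMap:
    """3D magnetic susceptibility contrast map in ppm."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("susceptibility values must be finite")


@dataclass
class FieldMap:
    """Relative field perturbation ΔB/B0 in ppm on the grid."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )


@dataclass
class EchoSeries:
    """Complex multi-echo gradient-echo image stack.

    ``data`` has shape ``(n_echoes, *grid_shape)``; ``echo_times_ms`` are
    strictly increasing.
    """

    data: np.ndarray
    echo_times_ms: np.ndarray
    geometry: GridGeometry
    b0_field: float = 3.0
    m0: np.ndarray | None = None
    r2star: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if self.echo_times_ms.ndim != 1 or self.echo_times_ms.size < 2:
            raise ValueError("need >= 2 echoes")
        if np.any(np.diff(self.echo_times_ms) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.data.shape != (self.echo_times_ms.size, *self.geometry.shape):
            raise ValueError("data shape must be (n_echoes, *grid shape)")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times_ms.size)
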