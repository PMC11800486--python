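"""High-pass-filtered (HPF) SWI phase reconstruction.

Reproduces the clinical recipe slice by slice: take the complex echo
acquired at the TE closest to 20 ms, multiply its 2D k-space by a
circularly symmetric low-pass Hanning kernel of a given radius (128
k-space voxels by default), and return the phase of the complex division
of the original slice by its low-pass image. The complex-division
formulation removes the smooth background field without any explicit
phase unwrapping; it also nulls the spatially uniform phase inside a
solid lesion, which is what manufactures the spurious rim appearance on
iron-negative lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EchoSeries

DEFAULT_FILTER_RADIUS = 128  # k-space voxels
DEFAULT_TARGET_TE_MS = 20.0
#: Low-pass magnitudes below eps * max are zero-phase and flagged invalid.
DIVISION_GUARD = 1e-12


def select_echo(echo_times_ms, target_ms: float = DEFAULT_TARGET_TE_MS) -> int:
    """Index of the echo with TE closest to ``target_ms``; ties -> earlier."""
    te = np.asarray(echo_times_ms, dtype=float)
    if te.size == 0:
        raise ValueError("empty echo list")
    return int(np.argmin(np.abs(te - target_ms)))


def hanning_lowpass_kernel(
    slice_shape: tuple[int, int], radius_voxels: float = DEFAULT_FILTER_RADIUS
) -> np.ndarray:
    """2D circularly symmetric Hanning low-pass weights in FFT layout.

    weight(k) = 0.5 (1 + cos(pi |k| / R)) for |k| <= R, else 0, where |k| is
    the radial distance from the zero-frequency sample in k-space voxels.
    """
    if radius_voxels <= 0:
        raise ValueError("radius_voxels must be > 0")
    n0, n1 = slice_shape
    k0 = np.fft.fftfreq(n0) * n0  # signed sample offsets from DC
    k1 = np.fft.fftfreq(n1) * n1
    r = np.sqrt(k0[:, None] ** 2 + k1[None, :] ** 2)
    w = 0.5 * (1.0 + np.cos(np.pi * r / radius_voxels))
    w[r > radius_voxels] = 0.0
    return w


@dataclass
class HPFPhaseImage:
    """High-pass-filtered phase in radians, in (-pi, pi]."""

    values: np.ndarray
    valid_mask: np.ndarray
    echo_index: int
    filter_radius: float
    slice_axis: int = 2


def hpf_phase(
    echoes: EchoSeries,
    radius_voxels: float = DEFAULT_FILTER_RADIUS,
    slice_axis: int = 2,
    echo_index: int | None = None,
    target_te_ms: float = DEFAULT_TARGET_TE_MS,
) -> HPFPhaseImage:
    """HPF phase of the echo nearest ``target_te_ms``, filtered per 2D slice.

    Slices are taken perpendicular to ``slice_axis`` (default the slab's thin
    axis, 2). Voxels whose low-pass magnitude falls below the division guard
    get phase 0 and are flagged invalid.
    """
    if echo_index is None:
        echo_index = select_echo(echoes.echo_times_ms, target_te_ms)
    vol = np.moveaxis(echoes.data[echo_index], slice_axis, -1)
    kernel = hanning_lowpass_kernel(vol.shape[:2], radius_voxels)
    kspace = np.fft.fft2(vol, axes=(0, 1))
    lowpass = np.fft.ifft2(kernel[..., None] * kspace, axes=(0, 1))
    lp_mag = np.abs(lowpass)
    eps = DIVISION_GUARD * lp_mag.max() if lp_mag.size else 0.0
    valid = lp_mag > eps
    ratio = np.where(valid, vol / np.where(valid, lowpass, 1.0), 0.0)
    phase = np.angle(ratio)
    phase[~valid] = 0.0
    return HPFPhaseImage(
        values=np.moveaxis(phase, -1, slice_axis),
        valid_mask=np.moveaxis(valid, -1, slice_axis),
        echo_index=echo_index,
        filter_radius=radius_voxels,
        slice_axis=slice_axis,
    )
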