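"""Field estimation and regularized dipole inversion (QSM).

The total field is estimated per voxel by temporally unwrapping the
inter-echo phase increments and fitting phase against TE by magnitude-
weighted least squares with a free intercept. Two dipole inversions are
provided:

* ``tkd_inversion`` — thresholded k-space division, the classic fast
  baseline: divide the field spectrum by the dipole kernel, clamping it
  near its zero cone.
* ``tikhonov_tfi_inversion`` — a linear total-field inversion solving
  min ||W (d * chi - f)||^2 + lambda ||grad chi||^2 by conjugate
  gradients, with an optional diagonal right-preconditioner boosting the
  expected dynamic range outside a tissue mask. This is a deliberately
  simplified stand-in for nonlinear preconditioned total-field inversion
  methods; the claims exercised here depend on dipole deconvolution per
  se, not on the specific regularizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GAMMA_HZ_PER_T, EchoSeries, FieldMap, GridGeometry, SusceptibilityMap
from .dipole import dipole_kernel


@dataclass
class TotalFieldEstimate:
    """Per-voxel field in ppm with reliability weights and validity mask."""

    field: np.ndarray  # ppm
    weights: np.ndarray  # >= 0
    mask: np.ndarray  # bool
    geometry: GridGeometry
    b0_field: float = 3.0

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.all(np.isfinite(self.field[self.mask])):
            raise ValueError("field must be finite inside the mask")


def estimate_field(echoes: EchoSeries, unwrap: bool = True) -> TotalFieldEstimate:
    """Estimate the total field (ppm) from a multi-echo series.

    Temporal unwrapping reconstructs per-voxel phase as the cumulative sum of
    wrapped inter-echo increments (exact while each per-ΔTE increment stays
    below pi in magnitude); ``unwrap=False`` fits the raw wrapped angles,
    provided for comparison. The slope of the magnitude-weighted linear fit
    of phase vs TE (free intercept) is converted to ppm via gamma and B0.
    Zero-signal voxels get weight 0 and are masked out.
    """
    if echoes.n_echoes < 2:
        raise ValueError("need >= 2 echoes")
    data = echoes.data
    te_s = echoes.echo_times_ms[:, None] * 1e-3  # (n_echo, 1), seconds
    mag = np.abs(data).reshape(echoes.n_echoes, -1)
    if unwrap:
        phases = np.empty_like(mag)
        flat = data.reshape(echoes.n_echoes, -1)
        phases[0] = np.angle(flat[0])
        increments = np.angle(flat[1:] * np.conj(flat[:-1]))
        # anchor inter-echo increments on the first-echo slope so that true
        # increments beyond +-pi (which alias) are still resolved, assuming
        # the first echo itself has not wrapped
        slope0 = phases[0] / te_s[0, 0]
        predicted = slope0[None, :] * np.diff(te_s, axis=0)
        increments = increments + 2 * np.pi * np.round(
            (predicted - increments) / (2 * np.pi)
        )
        phases[1:] = phases[0] + np.cumsum(increments, axis=0)
    else:
        phases = np.angle(data).reshape(echoes.n_echoes, -1)

    w = mag
    wsum = w.sum(axis=0)
    ok = wsum > 0
    wsum_safe = np.where(ok, wsum, 1.0)
    t_bar = (w * te_s).sum(axis=0) / wsum_safe
    p_bar = (w * phases).sum(axis=0) / wsum_safe
    dt = te_s - t_bar
    denom = (w * dt * dt).sum(axis=0)
    ok &= denom > 0
    slope = np.where(ok, (w * dt * (phases - p_bar)).sum(axis=0), 0.0)
    slope = slope / np.where(ok, denom, 1.0)  # rad/s
    field_ppm = slope / (2.0 * np.pi * GAMMA_HZ_PER_T * echoes.b0_field * 1e-6)
    shape = echoes.geometry.shape
    weights = np.where(ok, mag.mean(axis=0), 0.0).reshape(shape)
    return TotalFieldEstimate(
        field=field_ppm.reshape(shape),
        weights=weights,
        mask=ok.reshape(shape),
        geometry=echoes.geometry,
        b0_field=echoes.b0_field,
    )


@dataclass
class InversionConfig:
    """Configuration of the dipole inversion step."""

    method: str = "tkd"  # {"tkd", "tikhonov_tfi"}
    tkd_threshold: float = 0.2
    lam: float = 1e-3
    max_iterations: int = 60
    tolerance: float = 1e-6
    preconditioner_weight: float = 1.0  # applied outside the tissue mask

    def __post_init__(self) -> None:
        if not 0 < self.tkd_threshold <= 2.0 / 3.0:
            raise ValueError("tkd_threshold must be in (0, 2/3]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.method not in ("tkd", "tikhonov_tfi"):
            raise ValueError(f"unknown inversion method {self.method!r}")


@dataclass
class ConvergenceRecord:
    iterations: int
    residuals: list[float] = field(default_factory=list)
    converged: bool = False
    diverged: bool = False


def _field_values(field) -> np.ndarray:
    if isinstance(field, TotalFieldEstimate):
        return field.field
    if isinstance(field, FieldMap):
        return field.values
    return np.asarray(field, dtype=float)


def tkd_inversion(
    field, geometry: GridGeometry, threshold: float = 0.2
) -> SusceptibilityMap:
    """Thresholded k-space division: X(k) = F(k)/D(k), with D clamped to
    sign(D)*threshold where |D| < threshold (and 0 at DC)."""
    if not 0 < threshold <= 2.0 / 3.0:
        raise ValueError("threshold must be in (0, 2/3]")
    f = _field_values(field)
    d = dipole_kernel(geometry)
    d_inv = np.zeros_like(d)
    big = np.abs(d) >= threshold
    d_inv[big] = 1.0 / d[big]
    small = ~big & (d != 0)
    d_inv[small] = np.sign(d[small]) / threshold
    chi = np.fft.ifftn(d_inv * np.fft.fftn(f)).real
    return SusceptibilityMap(chi, geometry)


def _laplacian_multiplier(geometry: GridGeometry) -> np.ndarray:
    """k-space multiplier of grad^T grad for periodic forward differences."""
    mult = np.zeros(geometry.shape)
    for ax, n in enumerate(geometry.shape):
        k = np.fft.fftfreq(n)
        term = 2.0 - 2.0 * np.cos(2.0 * np.pi * k)
        mult = mult + term.reshape([-1 if i == ax else 1 for i in range(3)])
    return mult


def tikhonov_tfi_inversion(
    field: TotalFieldEstimate,
    config: InversionConfig | None = None,
    tissue_mask: np.ndarray | None = None,
) -> tuple[SusceptibilityMap, ConvergenceRecord]:
    """Linear Tikhonov-regularized total-field inversion by CG.

    Solves the normal equations of  min ||W (C chi - f)||^2 + lam ||G chi||^2
    where C is the dipole convolution and G the periodic forward-difference
    gradient, via the conjugate-residual method (residual norm monotone
    nonincreasing for this symmetric positive operator), with a diagonal
    right-preconditioner P (1 inside ``tissue_mask``,
    ``preconditioner_weight`` outside). Divergence (residual increasing 10
    consecutive iterations, possible only through numerical breakdown)
    aborts and returns the partial result flagged.
    """
    config = config or InversionConfig(method="tikhonov_tfi")
    geom = field.geometry
    d = dipole_kernel(geom)
    lap = _laplacian_multiplier(geom)
    w2 = (field.weights * field.mask) ** 2
    wmax = np.sqrt(w2).max()
    if wmax > 0:  # scale-free weighting
        w2 = w2 / wmax**2
    f = np.where(field.mask, field.field, 0.0)

    if tissue_mask is None or config.preconditioner_weight == 1.0:
        precond = None
    else:
        precond = np.where(tissue_mask, 1.0, config.preconditioner_weight)

    def conv(x: np.ndarray) -> np.ndarray:
        return np.fft.ifftn(d * np.fft.fftn(x)).real

    def matvec(x: np.ndarray) -> np.ndarray:
        if precond is not None:
            x = precond * x
        ax = conv(w2 * conv(x)) + config.lam * np.fft.ifftn(
            lap * np.fft.fftn(x)
        ).real
        if precond is not None:
            ax = precond * ax
        return ax

    b = conv(w2 * f)
    if precond is not None:
        b = precond * b
    bnorm = np.linalg.norm(b)
    record = ConvergenceRecord(iterations=0)
    if bnorm == 0:
        return SusceptibilityMap(np.zeros(geom.shape), geom), record

    # conjugate residuals (MINRES for SPD operators)
    x = np.zeros(geom.shape)
    r = b.copy()
    p = r.copy()
    ar = matvec(r)
    ap = ar.copy()
    r_ar = float(np.vdot(r, ar).real)
    bad_streak = 0
    prev = np.linalg.norm(r) / bnorm
    record.residuals.append(prev)
    for it in range(1, config.max_iterations + 1):
        ap_norm2 = float(np.vdot(ap, ap).real)
        if ap_norm2 <= 0 or r_ar <= 0:
            break
        alpha = r_ar / ap_norm2
        x = x + alpha * p
        r = r - alpha * ap
        rel = np.linalg.norm(r) / bnorm
        record.residuals.append(rel)
        record.iterations = it
        if rel < config.tolerance:
            record.converged = True
            break
        bad_streak = bad_streak + 1 if rel > prev else 0
        if bad_streak >= 10:
            record.diverged = True
            break
        prev = rel
        ar_new = matvec(r)
        r_ar_new = float(np.vdot(r, ar_new).real)
        beta = r_ar_new / r_ar
        p = r + beta * p
        ap = ar_new + beta * ap
        r_ar = r_ar_new
    if precond is not None:
        x = precond * x
    return SusceptibilityMap(x, geom), record


def invert(
    field: TotalFieldEstimate,
    config: InversionConfig | None = None,
    tissue_mask: np.ndarray | None = None,
) -> SusceptibilityMap:
    """Dispatch to the configured inversion method."""
    config = config or InversionConfig()
    if config.method == "tkd":
        return tkd_inversion(field, field.geometry, config.tkd_threshold)
    chi, _ = tikhonov_tfi_inversion(field, config, tissue_mask)
    return chi
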