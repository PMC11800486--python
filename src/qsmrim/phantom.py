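"""Lesion susceptibility phantoms with known iron-rim ground truth.

This is the synthetic-data generator standing in for the study material:
formalin-fixed brain slabs containing white-matter lesions of four classes —
solid demyelinated core, core with a full iron rim, core with a partial
(spherical-cap) iron rim, and a solid lesion traversed by a central vein.
It also fabricates multi-rater binary rim-call matrices for the agreement
statistics.

Susceptibility contrasts default to literature-typical orders of magnitude
(demyelinated core +0.02 ppm, iron rim +0.10 ppm, venous blood +0.30 ppm
against a 0 ppm reference); they set SNR only, since every downstream check
is analytic or threshold-relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GridGeometry, SusceptibilityMap, _as_unit

#: Lesion classes and their ground-truth iron-rim status under default params.
LESION_CLASSES = ("solid", "rim", "partial_rim", "veined")

#: Minimum solid-angle fraction of rim coverage for a lesion to count iron+.
DEFAULT_COVERAGE_FLOOR = 0.25

DEFAULT_CORE_CHI = 0.02  # ppm
DEFAULT_RIM_CHI = 0.10  # ppm
DEFAULT_VEIN_CHI = 0.30  # ppm


class PhantomError(ValueError):
    """Invalid phantom specification (overlap, out-of-bounds lesion, ...)."""


@dataclass(frozen=True)
class VeinSpec:
    """Cylindrical vein segment through a lesion centre."""

    axis: tuple[float, float, float]
    radius: float  # mm
    chi: float  # ppm

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", tuple(_as_unit(self.axis)))
        if self.radius <= 0:
            raise ValueError("vein radius must be > 0")


@dataclass(frozen=True)
class LesionSpec:
    """Geometric and magnetic description of one spherical lesion.

    ``rim_coverage`` is the fraction of the full solid angle covered by the
    rim, realised as a spherical cap of the rim annulus about ``rim_axis``.
    """

    lesion_id: str
    center: tuple[float, float, float]  # mm
    core_radius: float  # mm
    core_chi: float = DEFAULT_CORE_CHI  # ppm
    rim_chi: float = 0.0  # ppm
    rim_thickness: float = 0.0  # mm
    rim_coverage: float = 1.0
    rim_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    vein: VeinSpec | None = None
    class_label: str = "solid"

    def __post_init__(self) -> None:
        if self.core_radius <= 0:
            raise ValueError(f"{self.lesion_id}: core_radius must be > 0")
        if self.rim_thickness < 0:
            raise ValueError(f"{self.lesion_id}: rim_thickness must be >= 0")
        if not 0.0 <= self.rim_coverage <= 1.0:
            raise ValueError(f"{self.lesion_id}: rim_coverage must be in [0,1]")
        if self.rim_thickness > 0 and self.rim_chi < 0:
            raise ValueError(f"{self.lesion_id}: rim_chi must be >= 0 with a rim")
        object.__setattr__(self, "rim_axis", tuple(_as_unit(self.rim_axis)))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def outer_radius(self) -> float:
        return self.core_radius + self.rim_thickness


@dataclass(frozen=True)
class PhantomSpec:
    geometry: GridGeometry
    lesions: tuple[LesionSpec, ...]
    background_chi: float = 0.0  # ppm
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))


def validate_phantom(spec: PhantomSpec, margin_voxels: int = 4) -> None:
    """Reject overlapping or out-of-bounds lesions, naming the offender."""
    extent = np.asarray(spec.geometry.extent_mm)
    margin = margin_voxels * np.asarray(spec.geometry.voxel_size)
    for les in spec.lesions:
        c = np.asarray(les.center)
        if np.any(c - les.outer_radius < margin) or np.any(
            c + les.outer_radius > extent - margin
        ):
            raise PhantomError(
                f"lesion {les.lesion_id!r} extends outside the grid "
                f"(needs a {margin_voxels}-voxel margin)"
            )
    for i, a in enumerate(spec.lesions):
        for b in spec.lesions[i + 1 :]:
            d = np.linalg.norm(np.asarray(a.center) - np.asarray(b.center))
            if d <= a.outer_radius + b.outer_radius:
                raise PhantomError(
                    f"lesions {a.lesion_id!r} and {b.lesion_id!r} overlap"
                )


def lesion_masks(
    les: LesionSpec, geometry: GridGeometry
) -> dict[str, np.ndarray]:
    """Voxel-centre membership masks: ``core``, ``rim``, ``vein``.

    The rim mask is the spherical annulus ``(core_radius, outer_radius]``
    intersected with the spherical cap whose solid-angle fraction equals
    ``rim_coverage`` about ``rim_axis``.
    """
    xs, ys, zs = geometry.voxel_centers()
    cx, cy, cz = les.center
    dx, dy, dz = xs - cx, ys - cy, zs - cz
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    core = r <= les.core_radius
    rim = np.zeros(geometry.shape, dtype=bool)
    if les.rim_thickness > 0 and les.rim_coverage > 0:
        annulus = (r > les.core_radius) & (r <= les.outer_radius)
        # cap: angle from rim_axis <= theta_c with cos(theta_c) = 1 - 2*coverage
        ax = np.asarray(les.rim_axis)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_t = (dx * ax[0] + dy * ax[1] + dz * ax[2]) / np.where(r > 0, r, 1.0)
        rim = annulus & (cos_t >= 1.0 - 2.0 * les.rim_coverage)
    vein = np.zeros(geometry.shape, dtype=bool)
    if les.vein is not None:
        ax = np.asarray(les.vein.axis)
        t = dx * ax[0] + dy * ax[1] + dz * ax[2]  # axial coordinate
        perp2 = (dx * dx + dy * dy + dz * dz) - t * t
        # vein is a stick through the core only (keeps the phantom local)
        vein = (perp2 <= les.vein.radius**2) & (np.abs(t) <= les.core_radius)
    return {"core": core, "rim": rim, "vein": vein}


def build_susceptibility_map(spec: PhantomSpec) -> SusceptibilityMap:
    """Voxelize a phantom spec into a susceptibility map (ppm).

    Assignment order per voxel: background < core < rim < vein; membership is
    by voxel centre (no antialiasing — the resolution-convergence test bounds
    the discretization error).
    """
    validate_phantom(spec)
    chi = np.full(spec.geometry.shape, float(spec.background_chi))
    for les in spec.lesions:
        masks = lesion_masks(les, spec.geometry)
        chi[masks["core"]] = les.core_chi
        chi[masks["rim"]] = les.rim_chi
        if les.vein is not None:
            chi[masks["vein"]] = les.vein.chi
    return SusceptibilityMap(chi, spec.geometry)


def iron_rim_status(
    les: LesionSpec, coverage_floor: float = DEFAULT_COVERAGE_FLOOR
) -> str:
    """Ground-truth label: 'iron+' iff the lesion has a real rim with
    sufficient angular coverage, else 'iron-'."""
    positive = (
        les.rim_thickness > 0
        and les.rim_chi > 0
        and les.rim_coverage >= coverage_floor
    )
    return "iron+" if positive else "iron-"


def ground_truth(
    specs: PhantomSpec | Sequence[PhantomSpec],
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
) -> pd.DataFrame:
    """Deterministic truth table for one phantom or a cohort of phantoms.

    Returns a DataFrame with columns ``lesion_id``, ``class_label``,
    ``iron_rim_status``.
    """
    if isinstance(specs, PhantomSpec):
        specs = [specs]
    rows = []
    for spec in specs:
        for les in spec.lesions:
            rows.append(
                {
                    "lesion_id": les.lesion_id,
                    "class_label": les.class_label,
                    "iron_rim_status": iron_rim_status(les, coverage_floor),
                }
            )
    return pd.DataFrame(rows, columns=["lesion_id", "class_label", "iron_rim_status"])


#: Default sampling ranges for cohort generation (uniform draws), chosen as
#: realistic white-matter lesion geometry at 0.5 mm isotropic resolution.
DEFAULT_CLASS_PARAMS: dict[str, dict] = {
    "core_radius": (3.0, 5.0),  # mm → 6-10 mm diameter lesions
    "core_chi": (0.01, 0.03),  # ppm, demyelination contrast
    "rim_chi": (0.06, 0.14),  # ppm, iron rim contrast
    "rim_thickness": (0.8, 1.6),  # mm, ~2-3 voxels
    "partial_coverage": (0.3, 0.6),  # solid-angle fraction, above the floor
    "vein_radius": (0.5, 0.8),  # mm
    "vein_chi": (DEFAULT_VEIN_CHI, DEFAULT_VEIN_CHI),
    "center_jitter": 3.0,  # mm, uniform cube about grid centre
}


def _draw(rng: np.random.Generator, lo_hi) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi))


def _random_unit(rng: np.random.Generator) -> tuple[float, float, float]:
    v = rng.normal(size=3)
    return tuple(_as_unit(v))


def generate_cohort(
    n_per_class: int,
    classes: Sequence[str] = LESION_CLASSES,
    class_params: Mapping | None = None,
    geometry: GridGeometry | None = None,
    seed: int = 0,
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
    max_retries: int = 50,
) -> tuple[list[PhantomSpec], pd.DataFrame]:
    """Generate a seeded cohort of single-lesion phantoms plus truth table.

    One phantom per lesion (as in the study, where each lesion of interest
    was excised and read independently). ``n_per_class = 8`` with the four
    default classes gives the study-scale 32 lesions.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    unknown = set(classes) - set(LESION_CLASSES)
    if unknown:
        raise ValueError(f"unknown lesion classes: {sorted(unknown)}")
    params = dict(DEFAULT_CLASS_PARAMS)
    if class_params:
        params.update(class_params)
    geometry = geometry or GridGeometry()
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    idx = 0
    for cls in classes:
        for _ in range(n_per_class):
            lesion_id = f"L{idx:03d}_{cls}"
            for attempt in range(max_retries):
                les = _draw_lesion(rng, lesion_id, cls, params, geometry)
                spec = PhantomSpec(
                    geometry=geometry, lesions=(les,), seed=int(seed) + idx
                )
                try:
                    validate_phantom(spec)
                except PhantomError:
                    continue
                specs.append(spec)
                break
            else:
                raise PhantomError(
                    f"could not place a {cls!r} lesion after {max_retries} tries"
                )
            idx += 1
    truth = ground_truth(specs, coverage_floor)
    return specs, truth


def _draw_lesion(
    rng: np.random.Generator,
    lesion_id: str,
    cls: str,
    params: Mapping,
    geometry: GridGeometry,
) -> LesionSpec:
    center = tuple(
        geometry.center_mm + rng.uniform(-params["center_jitter"], params["center_jitter"], 3)
    )
    common = dict(
        lesion_id=lesion_id,
        center=center,
        core_radius=_draw(rng, params["core_radius"]),
        core_chi=_draw(rng, params["core_chi"]),
        class_label=cls,
    )
    if cls == "solid":
        return LesionSpec(**common)
    if cls == "rim":
        return LesionSpec(
            **common,
            rim_chi=_draw(rng, params["rim_chi"]),
            rim_thickness=_draw(rng, params["rim_thickness"]),
            rim_coverage=1.0,
        )
    if cls == "partial_rim":
        return LesionSpec(
            **common,
            rim_chi=_draw(rng, params["rim_chi"]),
            rim_thickness=_draw(rng, params["rim_thickness"]),
            rim_coverage=_draw(rng, params["partial_coverage"]),
            rim_axis=_random_unit(rng),
        )
    if cls == "veined":
        return LesionSpec(
            **common,
            vein=VeinSpec(
                axis=_random_unit(rng),
                radius=_draw(rng, params["vein_radius"]),
                chi=_draw(rng, params["vein_chi"]),
            ),
        )
    raise ValueError(f"unknown class {cls!r}")  # pragma: no cover


def generate_rating_matrix(
    truth: pd.DataFrame,
    sensitivity_per_rater: Sequence[float],
    specificity_per_rater: Sequence[float],
    seed: int = 0,
    session: str = "session1",
) -> pd.DataFrame:
    """Simulate independent binary rim calls from imperfect raters.

    Each rater's call is a Bernoulli corruption of the ground truth at that
    rater's (sensitivity, specificity). Returns an items × raters DataFrame
    of ``'rim+'``/``'rim-'`` indexed by lesion_id, with ``attrs['session']``.
    """
    sens = np.asarray(sensitivity_per_rater, dtype=float)
    spec_ = np.asarray(specificity_per_rater, dtype=float)
    if sens.shape != spec_.shape:
        raise ValueError("sensitivity and specificity lists differ in length")
    if np.any((sens < 0) | (sens > 1) | (spec_ < 0) | (spec_ > 1)):
        raise ValueError("rates must be in [0, 1]")
    if sens.size < 2 or len(truth) < 2:
        raise ValueError("need >= 2 raters and >= 2 items")
    rng = np.random.default_rng(seed)
    is_pos = (truth["iron_rim_status"] == "iron+").to_numpy()
    calls = {}
    for j, (se, sp) in enumerate(zip(sens, spec_)):
        p_call_pos = np.where(is_pos, se, 1.0 - sp)
        calls[f"rater_{j + 1}"] = np.where(
            rng.random(is_pos.size) < p_call_pos, "rim+", "rim-"
        )
    out = pd.DataFrame(calls, index=pd.Index(truth["lesion_id"], name="lesion_id"))
    out.attrs["session"] = session
    return out
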