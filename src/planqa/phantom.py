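"""Synthetic pelvis phantoms and strategy-dependent dose simulation.

The generator emulates rectal VMAT plans: an elongated PTV placed
posteriorly in an elliptical body, a bladder anterior to the PTV whose
overlap with the PTV varies across patients, two lateral femoral heads,
and small bowel superior-anterior.  Dose inside the PTV is the prescription
level (auto-calibrated so D95 hits the prescription) plus Gaussian noise;
outside the PTV the dose falls off exponentially with Euclidean distance
to the PTV and is further reduced inside each organ at risk by a
strategy-dependent sparing factor.

Seven strategy presets ship with the package.  They were calibrated once
so that the qualitative behaviour of the planning strategies they stand
for holds on the default cohort: hybrid presets spare the bladder and
femoral heads more than easy/moderate script presets and stay stable
across goal settings; the hard script preset over-spares the organs at
risk at the cost of PTV homogeneity and conformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .dvh import dose_at_volume_values
from .grids import (
    REQUIRED_STRUCTURES,
    STRATEGY_LABELS,
    DoseGrid,
    Plan,
    StructureSet,
)

__all__ = [
    "StrategyParams",
    "STRATEGY_PRESETS",
    "CalibrationError",
    "PhantomSizeError",
    "generate_phantom",
    "simulate_dose",
    "predict_dose",
    "generate_cohort",
]


class CalibrationError(RuntimeError):
    """PTV D95 calibration failed to converge within the iteration bound."""


class PhantomSizeError(ValueError):
    """The requested grid cannot contain a phantom structure."""


@dataclass(frozen=True)
class StrategyParams:
    """Parametric stand-in for the dose distribution a planning strategy produces.

    Attributes
    ----------
    ptv_hotspot_mean
        Relative over-dose inside the PTV as a fraction of prescription.
        After D95 calibration this uniform term is absorbed into
        ``coverage_scale``; it matters for uncalibrated fields only.
    ptv_noise_sd
        Standard deviation of in-PTV dose noise, fraction of prescription.
        Drives D2, D98 and hence the homogeneity index.
    falloff_length
        Exponential falloff length of dose outside the PTV, mm.  Longer
        falloff spreads the high-dose region and degrades conformity.
    oar_sparing
        Per-structure multiplicative sparing factor in (0, 1] applied to
        voxels inside that organ (outside the PTV).
    coverage_scale
        Multiplier calibrating PTV D95 to the prescription; solved by
        :func:`simulate_dose` when left at its default of 1.0.
    """

    ptv_hotspot_mean: float = 0.0
    ptv_noise_sd: float = 0.0
    falloff_length: float = 22.0
    oar_sparing: Dict[str, float] = field(default_factory=dict)
    coverage_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.falloff_length <= 0:
            raise ValueError("falloff_length must be positive")
        if self.ptv_noise_sd < 0:
            raise ValueError("ptv_noise_sd must be non-negative")
        for name, s in self.oar_sparing.items():
            if not 0 < s <= 1:
                raise ValueError(f"sparing factor for {name!r} must be in (0, 1], got {s}")


def _params(hotspot, noise, falloff, bladder, femur, bowel) -> StrategyParams:
    return StrategyParams(
        ptv_hotspot_mean=hotspot,
        ptv_noise_sd=noise,
        falloff_length=falloff,
        oar_sparing={
            "bladder": bladder,
            "femur_head_L": femur,
            "femur_head_R": femur,
            "small_bowel": bowel,
        },
    )


#: Shipped strategy presets (calibrated once; see module docstring).
STRATEGY_PRESETS: Dict[str, StrategyParams] = {
    "manual": _params(0.02, 0.016, 41.0, 0.88, 0.85, 0.88),
    "script_easy": _params(0.04, 0.024, 41.0, 0.95, 0.95, 0.95),
    "script_moderate": _params(0.02, 0.014, 45.0, 0.85, 0.76, 0.85),
    "script_hard": _params(0.01, 0.035, 73.0, 0.40, 0.28, 0.45),
    "hybrid_easy": _params(0.03, 0.023, 39.0, 0.72, 0.78, 0.75),
    "hybrid_moderate": _params(0.02, 0.0135, 43.0, 0.66, 0.68, 0.70),
    "hybrid_hard": _params(0.01, 0.0145, 54.0, 0.56, 0.52, 0.62),
}


def _ellipsoid(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    """Boolean ellipsoid mask on voxel centers; axes ordered (z, y, x)."""
    coords = [
        (np.arange(n) * s - c) / a
        for n, s, c, a in zip(shape, spacing, center_mm, semi_axes_mm)
    ]
    zz = coords[0][:, None, None] ** 2
    yy = coords[1][None, :, None] ** 2
    xx = coords[2][None, None, :] ** 2
    return zz + yy + xx <= 1.0


def _check_fits(name, center_mm, semi_axes_mm, extent_mm) -> None:
    for c, a, e in zip(center_mm, semi_axes_mm, extent_mm):
        if c - a < 0 or c + a > e:
            raise PhantomSizeError(
                f"grid too small to place structure {name!r}: needs "
                f"[{c - a:.1f}, {c + a:.1f}] mm on an axis of extent {e:.1f} mm"
            )


def generate_phantom(
    grid_shape: Tuple[int, int, int] = (80, 80, 80),
    spacing: Tuple[float, float, float] = (2.5, 2.5, 2.5),
    seed: int = 0,
) -> StructureSet:
    """Generate one synthetic pelvis: seven structures on a shared grid.

    The bladder's anterior gap to the PTV is seed-varied so that the
    bladder–PTV overlap fraction spans [0, 0.3] of the PTV across patients,
    including the high-overlap anatomy where a fixed bladder goal becomes
    infeasible.  Structure sizes receive mild per-seed jitter.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in grid_shape)
    spacing = tuple(float(s) for s in spacing)
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    center = [e / 2 for e in extent]
    cz, cy, cx = center

    # per-seed anatomical jitter (mm)
    ptv_semi = (40.0 + rng.uniform(-3, 3), 25.0 + rng.uniform(-2, 2), 25.0 + rng.uniform(-2, 2))
    bladder_r = 25.0 + rng.uniform(-2, 2)
    femur_r = 20.0 + rng.uniform(-1.5, 1.5)
    femur_gap = 15.0 + rng.uniform(-3, 3)
    # anterior surface gap between PTV and bladder controls the overlap fraction
    bladder_gap = rng.uniform(-24.0, 0.0)

    ptv_center = (cz, cy - 20.0, cx)
    bladder_center = (cz, ptv_center[1] + ptv_semi[1] + bladder_r + bladder_gap, cx)
    femur_dx = ptv_semi[2] + femur_gap + femur_r
    body_semi = (min(90.0, extent[0] / 2 - spacing[0]),
                 min(75.0, extent[1] / 2 - spacing[1]),
                 min(95.0, extent[2] / 2 - spacing[2]))
    bowel_center = (cz + 55.0, cy + 20.0 + rng.uniform(-4, 4), cx + rng.uniform(-5, 5))
    bowel_semi = (20.0, 26.0, 32.0)

    placements = {
        "body": (center, body_semi),
        "PTV": (ptv_center, ptv_semi),
        "bladder": (bladder_center, (bladder_r,) * 3),
        "femur_head_L": ((cz, ptv_center[1] + 5.0, cx - femur_dx), (femur_r,) * 3),
        "femur_head_R": ((cz, ptv_center[1] + 5.0, cx + femur_dx), (femur_r,) * 3),
        "small_bowel": (bowel_center, bowel_semi),
    }
    for name, (c, a) in placements.items():
        _check_fits(name, c, a, extent)

    masks = {
        name: _ellipsoid(shape, spacing, c, a) for name, (c, a) in placements.items()
    }
    body = masks["body"]
    for name in ("PTV", "bladder", "femur_head_L", "femur_head_R", "small_bowel"):
        masks[name] &= body
    masks["small_bowel"] &= ~masks["PTV"]  # bowel never inside the target
    masks["CTV"] = ndimage.binary_erosion(masks["PTV"])

    structures = StructureSet(masks=masks, spacing=spacing)
    structures.validate(REQUIRED_STRUCTURES)
    return structures


def _calibrate_coverage(
    noise: np.ndarray, prescription: float, hotspot: float, tol: float = 1e-3, max_iter: int = 50
) -> float:
    """Solve coverage_scale so in-PTV D95 = prescription on this noise draw."""
    cs = 1.0 / (1.0 + hotspot)
    for _ in range(max_iter):
        inside = prescription * cs * (1.0 + hotspot) + noise
        d95 = dose_at_volume_values(inside, 95.0)
        if abs(d95 / prescription - 1.0) <= tol:
            return cs
        cs *= prescription / d95
    raise CalibrationError(
        f"PTV D95 calibration did not reach {tol:.0e} within {max_iter} iterations"
    )


def _dose_field(
    structures: StructureSet,
    params: StrategyParams,
    prescription: float,
    noise: np.ndarray | None,
) -> DoseGrid:
    ptv = structures["PTV"]
    n_ptv = int(ptv.sum())
    if noise is None:
        noise = np.zeros(n_ptv)
    cs = params.coverage_scale
    if cs == 1.0:
        cs = _calibrate_coverage(noise, prescription, params.ptv_hotspot_mean)
    level = prescription * cs * (1.0 + params.ptv_hotspot_mean)

    # Falloff starts at the calibrated coverage surface (D95 = prescription),
    # so conformity is set by falloff_length alone, not by in-PTV noise.
    # The smoothed distance keeps the 95% isodose shell continuously
    # valued on the coarse grid (see StructureSet.distance_to).
    dist = structures.distance_to("PTV", smooth_voxels=1.0)
    dose = prescription * np.exp(-dist / params.falloff_length)
    sparing = np.ones(structures.shape)
    for name, s in params.oar_sparing.items():
        if name in structures:
            region = structures[name] & ~ptv
            sparing[region] = np.minimum(sparing[region], s)
    dose *= sparing
    dose[ptv] = level + noise
    np.clip(dose, 0.0, None, out=dose)
    return DoseGrid(dose, spacing=structures.spacing, origin=structures.origin)


def simulate_dose(
    structures: StructureSet,
    params: StrategyParams,
    prescription: float = 5000.0,
    seed: int = 0,
) -> DoseGrid:
    """Simulate one plan's dose field for a strategy preset.

    Inside the PTV: prescription x coverage_scale x (1 + hotspot) plus
    Gaussian noise (sd = ptv_noise_sd x prescription); coverage_scale is
    auto-calibrated so PTV D95 lands within prescription +- 1%.  Outside:
    exponential falloff from the PTV boundary level, multiplied by the
    sparing factor of any organ at risk containing the voxel (minimum
    factor where organs overlap).  Deterministic for a fixed seed.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    ptv = structures["PTV"]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.ptv_noise_sd * prescription, size=int(ptv.sum()))
    return _dose_field(structures, params, prescription, noise)


def predict_dose(
    structures: StructureSet,
    predictor_params: StrategyParams,
    prescription: float = 5000.0,
) -> DoseGrid:
    """Noise-free achievable-dose surrogate from the same parametric model.

    Stands in for a trained dose predictor: given the patient's anatomy it
    returns the deterministic dose field the strategy parameters describe,
    which the hybrid workflow then reads dose-volume indices from.
    """
    return _dose_field(structures, predictor_params, prescription, noise=None)


def _substream(master_seed: int, *key: int) -> int:
    """Fixed mixing rule: per-patient / per-plan seeds from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), *key]).generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(
    n_patients: int,
    strategy_labels: Sequence[str] = STRATEGY_LABELS,
    master_seed: int = 0,
    grid_shape: Tuple[int, int, int] = (80, 80, 80),
    spacing: Tuple[float, float, float] = (2.5, 2.5, 2.5),
    prescription: float = 5000.0,
    presets: Dict[str, StrategyParams] | None = None,
) -> List[Plan]:
    """Generate ``n_patients`` phantoms with one plan per strategy each.

    All of a patient's plans share one StructureSet; sub-seeds are derived
    deterministically from ``master_seed`` so cohorts are reproducible and
    extensible (patient i's anatomy does not depend on n_patients).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    presets = dict(STRATEGY_PRESETS if presets is None else presets)
    unknown = [s for s in strategy_labels if s not in presets]
    if unknown:
        raise ValueError(
            f"unknown strategy labels {unknown}; valid labels: {sorted(presets)}"
        )
    plans: List[Plan] = []
    for i in range(n_patients):
        structures = generate_phantom(grid_shape, spacing, seed=_substream(master_seed, i, 0))
        for j, label in enumerate(strategy_labels):
            dose = simulate_dose(
                structures,
                presets[label],
                prescription=prescription,
                seed=_substream(master_seed, i, 1000 + j),
            )
            plans.append(
                Plan(
                    dose=dose,
                    structures=structures,
                    prescription=prescription,
                    strategy_label=label,
                    patient_id=i,
                )
            )
    return plans
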