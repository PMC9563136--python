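"""Core spatial containers: dose grids, structure sets and plans.

Doses are carried internally in cGy; axes are ordered (z, y, x) with
0-based indices, and a voxel's world position is ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np
from scipy import ndimage

STRATEGY_LABELS = (
    "manual",
    "script_easy",
    "script_moderate",
    "script_hard",
    "hybrid_easy",
    "hybrid_moderate",
    "hybrid_hard",
)

REQUIRED_STRUCTURES = (
    "PTV",
    "CTV",
    "bladder",
    "femur_head_L",
    "femur_head_R",
    "small_bowel",
    "body",
)


class CongruenceError(ValueError):
    """Dose grid and mask (or two masks) do not share the same geometry."""


class EmptyStructureError(ValueError):
    """An operation was asked to evaluate an empty structure mask."""


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D absorbed-dose scalar field on a regular grid.

    Parameters
    ----------
    values
        Dose per voxel in cGy, axes ordered (z, y, x).
    spacing
        Per-axis voxel size in mm, ordered (z, y, x).
    origin
        World coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"dose grid must be 3-D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose grid contains non-finite values")
        if values.min() < 0:
            raise ValueError("dose grid contains negative dose")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class StructureSet:
    """Named boolean masks sharing one grid geometry.

    ``masks`` maps structure name to a boolean array; all masks must be
    congruent (same shape).  ``spacing`` is carried so distance-based
    operations (falloff, margin expansion) do not need a DoseGrid.
    """

    masks: Dict[str, np.ndarray]
    spacing: Tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    _distance_cache: Dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise CongruenceError(f"masks have inconsistent shapes: {sorted(shapes)}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> Iterable[str]:
        return self.masks.keys()

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise CongruenceError(
                f"mask {name!r} shape {mask.shape} != structure-set shape {self.shape}"
            )
        self.masks[name] = mask

    def distance_to(self, name: str, smooth_voxels: float = 0.0) -> np.ndarray:
        """Euclidean distance (mm) from each voxel center to structure `name`.

        With ``smooth_voxels=0`` this is the plain voxel-center distance
        transform (the margin-expansion convention).  A positive value
        Gaussian-smooths the *signed* distance (outside minus inside, sigma
        in voxels) before clipping at zero: on a coarse grid the plain
        transform puts every structure-adjacent voxel at exactly one
        spacing, which quantizes any isodose surface of a falloff model to
        whole voxel layers; the smoothed map restores a continuously valued
        surface.  Cached per (structure, smoothing): the falloff model
        evaluates it once per phantom and reuses it across all strategy
        doses.
        """
        key = f"{name}@{smooth_voxels:g}"
        if key not in self._distance_cache:
            mask = self.masks[name]
            if not mask.any():
                raise EmptyStructureError(f"structure {name!r} is empty")
            dist = ndimage.distance_transform_edt(~mask, sampling=self.spacing)
            if smooth_voxels > 0:
                signed = dist - ndimage.distance_transform_edt(mask, sampling=self.spacing)
                dist = np.clip(ndimage.gaussian_filter(signed, sigma=smooth_voxels), 0.0, None)
            self._distance_cache[key] = dist
        return self._distance_cache[key]

    def validate(self, required: Iterable[str] = REQUIRED_STRUCTURES) -> None:
        """Check the pelvis-phantom containment invariants."""
        for name in required:
            if name not in self.masks:
                raise ValueError(f"missing required structure {name!r}")
        body = self.masks["body"]
        ptv = self.masks["PTV"]
        if not ptv.any():
            raise EmptyStructureError("PTV has no voxels")
        if np.any(ptv & ~body):
            raise ValueError("PTV is not contained in body")
        if np.any(self.masks["CTV"] & ~ptv):
            raise ValueError("CTV is not contained in PTV")
        for name, mask in self.masks.items():
            if name == "body":
                continue
            if np.any(mask & ~body):
                raise ValueError(f"structure {name!r} is not contained in body")


def check_congruent(dose: DoseGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.values.shape:
        raise CongruenceError(
            f"mask shape {mask.shape} does not match dose grid shape {dose.values.shape}"
        )
    return mask


@dataclass
class Plan:
    """One treatment plan: a dose field, the patient's structures and metadata."""

    dose: DoseGrid
    structures: StructureSet
    prescription: float = 5000.0
    fractions: int = 25
    strategy_label: str = "manual"
    patient_id: int = 0

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if self.strategy_label not in STRATEGY_LABELS:
            raise ValueError(
                f"unknown strategy label {self.strategy_label!r}; valid: {STRATEGY_LABELS}"
            )
        if self.dose.values.shape != self.structures.shape:
            raise CongruenceError("dose grid and structure set are not congruent")
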