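"""Cumulative dose-volume histograms and dose-volume indices.

Conventions (declared, since treatment-planning systems differ):

* full-voxel counting — no partial volumes, no interpolation;
* Dx is the minimum dose received by the hottest x% of the structure:
  with voxel doses sorted descending, Dx = s[k-1] for k = ceil(x/100 * N);
* Vx uses an inclusive threshold (dose >= threshold counts);
* indices are computed from the raw voxel doses, never from a binned curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .grids import DoseGrid, EmptyStructureError, check_congruent


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= each dose edge."""

    dose_edges: np.ndarray  # cGy, ascending
    volume_fraction: np.ndarray  # in [0, 1], non-increasing
    structure_name: str = ""
    voxel_count: int = 0

    def volume_at(self, dose: float) -> float:
        """Fraction of volume receiving >= `dose`, read off the curve edges."""
        idx = int(np.searchsorted(self.dose_edges, dose, side="left"))
        if idx >= len(self.dose_edges):
            return 0.0
        return float(self.volume_fraction[idx])

    def mean_dose(self) -> float:
        """Mean dose recovered from the curve: integral of V(d) dd (trapezoid)."""
        return float(np.trapezoid(self.volume_fraction, self.dose_edges))


def _masked_doses(dose: DoseGrid, mask: np.ndarray) -> np.ndarray:
    mask = check_congruent(dose, mask)
    values = dose.values[mask]
    if values.size == 0:
        raise EmptyStructureError("mask selects no voxels")
    return values


def cumulative_dvh(
    dose: DoseGrid, mask: np.ndarray, bin_width: float = 10.0, structure_name: str = ""
) -> DVHCurve:
    """Cumulative DVH of the masked voxels with edges 0, bin_width, 2*bin_width, ...

    The edge range extends one bin beyond the maximum dose so the curve
    always ends at volume fraction 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = _masked_doses(dose, mask)
    n = values.size
    top = (math.floor(values.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    sorted_vals = np.sort(values)
    # voxels with dose >= edge  ==  n - (# voxels strictly below edge)
    below = np.searchsorted(sorted_vals, edges, side="left")
    fraction = (n - below) / n
    return DVHCurve(edges, fraction, structure_name=structure_name, voxel_count=n)


def dose_at_volume_values(values: np.ndarray, x: float) -> float:
    """Dx on a flat array of voxel doses (shared with the phantom calibrator)."""
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    n = values.size
    k = math.ceil(x / 100.0 * n)
    sorted_desc = np.sort(values)[::-1]
    return float(sorted_desc[k - 1])


def dose_at_volume(dose: DoseGrid, mask: np.ndarray, x: float) -> float:
    """Dx: minimum dose received by the hottest x% of the structure, cGy."""
    return dose_at_volume_values(_masked_doses(dose, mask), x)


def volume_at_dose(dose: DoseGrid, mask: np.ndarray, threshold: float) -> float:
    """Vx: percent of the structure's volume receiving >= `threshold` cGy."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values = _masked_doses(dose, mask)
    return float(100.0 * np.count_nonzero(values >= threshold) / values.size)


def mean_max_dose(dose: DoseGrid, mask: np.ndarray) -> Tuple[float, float]:
    """(mean, max) of in-mask voxel doses, cGy."""
    values = _masked_doses(dose, mask)
    return float(values.mean()), float(values.max())
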