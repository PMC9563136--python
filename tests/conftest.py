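import numpy as np
import pytest

from planqa import DoseGrid, Plan, StructureSet, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default 80^3 / 2.5 mm pelvis phantom, seed 7."""
    return generate_phantom((80, 80, 80), (2.5, 2.5, 2.5), seed=7)


def _box(shape, lo, hi):
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


@pytest.fixture
def tiny_structures():
    """Hand-built 20^3 structure set with all required structures (box shapes)."""
    shape = (20, 20, 20)
    masks = {
        "body": _box(shape, (1, 1, 1), (19, 19, 19)),
        "PTV": _box(shape, (7, 7, 7), (13, 13, 13)),
        "CTV": _box(shape, (8, 8, 8), (12, 12, 12)),
        "bladder": _box(shape, (7, 13, 7), (13, 17, 13)),
        "femur_head_L": _box(shape, (7, 7, 1), (13, 13, 5)),
        "femur_head_R": _box(shape, (7, 7, 15), (13, 13, 19)),
        "small_bowel": _box(shape, (14, 13, 7), (18, 17, 13)),
    }
    return StructureSet(masks=masks, spacing=(2.5, 2.5, 2.5))


@pytest.fixture
def uniform_plan(tiny_structures):
    """Uniform prescription dose everywhere in the body."""
    dose = np.where(tiny_structures["body"], 5000.0, 0.0)
    return Plan(
        dose=DoseGrid(dose, spacing=tiny_structures.spacing),
        structures=tiny_structures,
        prescription=5000.0,
        strategy_label="manual",
    )


@pytest.fixture
def zero_oar_plan(tiny_structures):
    """Prescription dose inside the PTV, zero dose everywhere else."""
    dose = np.where(tiny_structures["PTV"], 5000.0, 0.0)
    return Plan(
        dose=DoseGrid(dose, spacing=tiny_structures.spacing),
        structures=tiny_structures,
        prescription=5000.0,
        strategy_label="manual",
    )
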