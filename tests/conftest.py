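import numpy as np
import pytest

from paretodose.cohort import PhantomConfig, generate_cohort_in_memory
from paretodose.grids import (PlanRecord, PriorityVector, StructureSet,
                              VoxelGrid)


def toy_phantom_config(n_patients=1, n_slices=8, n_rows=16, n_cols=16, seed=5,
                       **kw):
    return PhantomConfig(n_patients=n_patients, n_slices=n_slices,
                         n_rows=n_rows, n_cols=n_cols, seed=seed, **kw)


@pytest.fixture(scope="session")
def toy_plan():
    """One small phantom plan with a surrogate reference dose."""
    cfg = toy_phantom_config()
    return generate_cohort_in_memory(cfg, [PriorityVector(2.0, 1.0, 3.0)])[0]


@pytest.fixture(scope="session")
def toy_structures(toy_plan):
    return toy_plan.structures


def random_structure_set(rng, shape=(6, 16, 16), spacing=(3.0, 1.0, 1.0)):
    """A random (not anatomically shaped) but contract-valid structure set."""
    body = np.zeros(shape)
    body[:, 2:-2, 2:-2] = 1.0
    masks = {"body": body}
    for name in ("ptv", "bladder", "rectum"):
        m = (rng.random(shape) < 0.08) & (body > 0)
        masks[name] = m.astype(float)
    # PTV must be non-empty
    masks["ptv"][shape[0] // 2, shape[1] // 2, shape[2] // 2] = 1.0
    return StructureSet(masks={
        k: VoxelGrid(values=v, spacing=spacing) for k, v in masks.items()})
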