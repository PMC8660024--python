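"""Shared fixtures: one small synthetic dataset per scenario, built once."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from braintx import io as btio
from braintx.simulate import (
    SimulationParams,
    recovery_params,
    simulate_dataset,
)
from braintx.types import Atlas


#: deterministic seed for every fixture dataset in the suite
SUITE_SEED = 11


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default-condition synthetic dataset, written to disk once."""
    root = tmp_path_factory.mktemp("sim")
    return simulate_dataset(SimulationParams(seed=SUITE_SEED), root)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Mild-batch-effect dataset used by the parameter-recovery tests."""
    return simulate_dataset(recovery_params(SUITE_SEED))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, reduced-size dataset for pipeline plumbing tests."""
    params = SimulationParams(
        seed=SUITE_SEED, n_genes=30, n_regions=10, n_samples_per_donor=20,
        n_donors=4, n_bilateral_donors=2,
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def centroids(dataset):
    return btio.region_centroids(dataset.atlas)


def make_volume_atlas(labels, affine=None, hemispheres=None, classes=None):
    """Tiny hand-built volumetric atlas for targeted assignment tests."""
    labels = np.asarray(labels, int)
    if affine is None:
        affine = np.eye(4)
    region_ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    meta = pd.DataFrame(
        {
            "region_id": region_ids,
            "label": [f"R{r}" for r in region_ids],
            "hemisphere": [
                (hemispheres or {}).get(r, "L") for r in region_ids
            ],
            "structure_class": [
                (classes or {}).get(r, "cortex") for r in region_ids
            ],
        }
    ).set_index("region_id")
    return Atlas(space="volume", regions=meta, label_array=labels,
                 affine=np.asarray(affine, float))


def make_samples(rows):
    """Sample table from (well_id, donor, hemi, x, y, z[, cls]) tuples."""
    records = []
    for row in rows:
        well, donor, hemi, x, y, z = row[:6]
        cls = row[6] if len(row) > 6 else "cortex"
        records.append(
            {
                "well_id": well, "donor_id": donor,
                "structure_acronym": "AA", "slab_type": "CX",
                "hemisphere": hemi, "mni_x": x, "mni_y": y, "mni_z": z,
                "structure_class": cls,
            }
        )
    return pd.DataFrame(records).set_index("well_id")
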