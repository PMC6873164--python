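import numpy as np
import pandas as pd
import pytest

from mmconn import (
    AtlasSpec,
    Coupling,
    ProjectionConfig,
    RegionalCohort,
    SimulationConfig,
    fit_bagged_basis,
    generate_study,
)


@pytest.fixture(scope="session")
def tiny_study():
    """A small simulated study shared by projection/network tests."""
    cfg = SimulationConfig(
        K=8,
        voxels_per_region=(6, 10),
        group_sizes=(12, 12, 8, 8),
        effect_size=1.5,
        couplings=(Coupling(0, 1, 2.0, 2.0),),
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def tiny_basis(tiny_study):
    aux, _, _ = tiny_study
    return fit_bagged_basis(aux, ProjectionConfig(T=6, S=3, seed=5))


def random_cohort(rng, K=4, n_subjects=5, modalities=("structural", "metabolic"),
                  vox_range=(2, 6), with_meta=True):
    """Build a random in-memory cohort for I/O round-trip tests."""
    spec = AtlasSpec(tuple(range(1, K + 1)))
    data = {
        m: {
            k: rng.normal(size=(n_subjects, rng.integers(*vox_range)))
            for k in spec.region_ids
        }
        for m in modalities
    }
    # voxel counts must agree across modalities
    for k in spec.region_ids:
        n_k = data[modalities[0]][k].shape[1]
        for m in modalities[1:]:
            data[m][k] = rng.normal(size=(n_subjects, n_k))
    if with_meta:
        meta = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n_subjects)],
                "group": rng.choice(["AD", "NC", "sMCI", "pMCI"], size=n_subjects),
                "age": rng.uniform(60, 90, size=n_subjects).round(1),
                "sex": rng.choice(["M", "F"], size=n_subjects),
            }
        )
    else:
        meta = pd.DataFrame()
    return RegionalCohort(spec, tuple(modalities), data, meta)
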