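"""Synthetic multi-modal cohorts with planted group effects and couplings.

Generates an auxiliary cohort (AD + NC) and a target cohort (sMCI + pMCI)
of region-wise voxel data in two modalities, so that every downstream stage
(bagged PCA projection, multi-task connectivity, classification) can be
exercised and validated without access to real neuroimaging data.

Generative model, per subject, region k, modality m::

    x = baseline_{k,m}
        + g * a_group * effect_size_{k,m} * effect_map_{k,m}
        + sum_{couplings through k} z_subject * loading_m * coupling_map
        + N(0, noise_sd^2)

where ``g`` is 1 for the AD/pMCI-side shift and 0 for NC, ``a_group`` is 1
for AD, ``a_sMCI``/``a_pMCI`` for the MCI subtypes (attenuation toward
NC/AD), ``effect_map`` is a fixed unit-norm voxel pattern, and ``z_subject``
is a per-subject standard-normal latent shared by coupled region pairs in
both modalities (the "connectivity" ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regional_io import DEFAULT_MODALITIES, AtlasSpec, InputError, RegionalCohort


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Coupling:
    """A planted latent link between two regions.

    ``loading_structural`` / ``loading_metabolic`` scale how strongly the
    shared per-subject latent factor loads on each modality's voxel pattern.
    """

    region_a: int
    region_b: int
    loading_structural: float
    loading_metabolic: float

    @property
    def loadings(self) -> tuple[float, float]:
        return (self.loading_structural, self.loading_metabolic)


@dataclass
class SimulationConfig:
    K: int = 30
    voxels_per_region: tuple[int, int] = (20, 40)
    group_sizes: tuple[int, int, int, int] = (60, 60, 40, 40)  # AD, NC, sMCI, pMCI
    effect_size: float = 1.5
    mci_attenuation: tuple[float, float] = (0.2, 0.8)  # (a_sMCI, a_pMCI)
    couplings: tuple[Coupling, ...] = ()
    modality_specific_couplings: bool = False
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        a_s, a_p = self.mci_attenuation
        if not (0.0 <= a_s <= a_p <= 1.0):
            raise ConfigError("need 0 <= a_sMCI <= a_pMCI <= 1")
        if any(n < 2 for n in self.group_sizes):
            raise ConfigError("every group needs at least 2 subjects")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.K < 2:
            raise ConfigError("K must be >= 2")
        lo, hi = self.voxels_per_region
        if not (1 <= lo <= hi):
            raise ConfigError("invalid voxels_per_region range")
        self.couplings = tuple(
            c if isinstance(c, Coupling) else Coupling(*c) for c in self.couplings
        )
        for c in self.couplings:
            for r in (c.region_a, c.region_b):
                if not (0 <= r < self.K):
                    raise ConfigError(f"coupling names region {r} outside 0..{self.K - 1}")
            if c.region_a == c.region_b:
                raise ConfigError("coupling endpoints must differ")


@dataclass
class GroundTruth:
    """What was planted: coupling support and per-region effect directions."""

    adjacency: np.ndarray  # K x K binary, symmetric, zero diagonal
    effect_maps: dict[str, dict[int, np.ndarray]]  # modality -> region -> unit vec
    effect_sizes: dict[str, dict[int, float]]

    def adjacency_tsv(self, path) -> None:
        pd.DataFrame(self.adjacency.astype(int)).to_csv(path, sep="\t", index=False)


def default_config(seed: int = 20191115) -> SimulationConfig:
    """The frozen desk-scale study configuration used throughout the tests.

    K=30 regions of 20-40 voxels, groups (60 AD, 60 NC, 40 sMCI, 40 pMCI),
    six coupled region pairs with equal loadings of 2.0 on both modalities,
    an AD-vs-NC effect size of 1.5 standardized units per region, MCI
    attenuations 0.2 / 0.8, unit voxel noise.
    """
    couplings = tuple(
        Coupling(a, b, 2.0, 2.0)
        for a, b in [(0, 1), (4, 9), (7, 13), (12, 20), (17, 25), (22, 28)]
    )
    return SimulationConfig(couplings=couplings, seed=seed)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _unit_zero_mean(v: np.ndarray) -> np.ndarray:
    """Unit-norm pattern orthogonal to the constant vector.

    Planted effect patterns redistribute signal within a region without
    moving its mean, so regional-mean summaries carry no first-order group
    signal and the contrast isolates pattern-level information.
    """
    v = v - v.mean()
    return v / np.linalg.norm(v)


def generate_study(
    config: SimulationConfig,
) -> tuple[RegionalCohort, RegionalCohort, GroundTruth]:
    """Generate (auxiliary AD+NC cohort, target sMCI+pMCI cohort, truth).

    Both cohorts share region definitions, voxel counts and orderings; all
    randomness flows from ``config.seed`` so the same config reproduces the
    same cohorts bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    K = config.K
    modalities = DEFAULT_MODALITIES
    region_ids = tuple(range(1, K + 1))
    spec = AtlasSpec(region_ids)
    lo, hi = config.voxels_per_region
    n_vox = rng.integers(lo, hi + 1, size=K)

    # Fixed structural pieces of the generative model.
    baselines = {
        m: {k: rng.normal(0.0, 1.0, size=n_vox[i]) for i, k in enumerate(region_ids)}
        for m in modalities
    }
    effect_maps = {
        m: {k: _unit_zero_mean(rng.normal(size=n_vox[i])) for i, k in enumerate(region_ids)}
        for m in modalities
    }
    effect_sizes = {
        m: {k: float(config.effect_size) for k in region_ids} for m in modalities
    }
    coupling_maps: list[dict[str, dict[int, np.ndarray]]] = []
    for c in config.couplings:
        maps: dict[str, dict[int, np.ndarray]] = {}
        for m in modalities:
            maps[m] = {}
            for r in (c.region_a, c.region_b):
                maps[m][r] = _unit_zero_mean(rng.normal(size=n_vox[r]))
        coupling_maps.append(maps)

    adjacency = np.zeros((K, K), dtype=np.int8)
    for c in config.couplings:
        adjacency[c.region_a, c.region_b] = 1
        adjacency[c.region_b, c.region_a] = 1

    n_ad, n_nc, n_smci, n_pmci = config.group_sizes
    a_smci, a_pmci = config.mci_attenuation

    def make_group(group: str, n: int, shift: float, id_prefix: str) -> tuple[dict, pd.DataFrame]:
        z = rng.standard_normal((n, len(config.couplings)))
        if config.modality_specific_couplings:
            z2 = rng.standard_normal((n, len(config.couplings)))
        data = {m: {} for m in modalities}
        for mi, m in enumerate(modalities):
            zm = z if (mi == 0 or not config.modality_specific_couplings) else z2
            for i, k in enumerate(region_ids):
                x = np.tile(baselines[m][k], (n, 1))
                x = x + shift * effect_sizes[m][k] * effect_maps[m][k]
                for ci, c in enumerate(config.couplings):
                    r = k - 1  # 0-based region index used in couplings
                    if r in (c.region_a, c.region_b):
                        loading = c.loadings[mi] if mi < 2 else c.loadings[-1]
                        x = x + np.outer(zm[:, ci] * loading, coupling_maps[ci][m][r])
                x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
                data[m][k] = x
        ages = rng.normal(75.0, 6.0, size=n).round(1)
        sexes = rng.choice(["M", "F"], size=n)
        meta = pd.DataFrame(
            {
                "subject_id": [f"{id_prefix}{i:03d}" for i in range(n)],
                "group": group,
                "age": ages,
                "sex": sexes,
            }
        )
        return data, meta

    groups = [
        ("AD", n_ad, 1.0, "AD"),
        ("NC", n_nc, 0.0, "NC"),
        ("sMCI", n_smci, a_smci, "S"),
        ("pMCI", n_pmci, a_pmci, "P"),
    ]
    parts = {g[0]: make_group(*g) for g in groups}

    def assemble(names: Sequence[str]) -> RegionalCohort:
        data = {
            m: {
                k: np.vstack([parts[g][0][m][k] for g in names])
                for k in region_ids
            }
            for m in modalities
        }
        meta = pd.concat([parts[g][1] for g in names], ignore_index=True)
        return RegionalCohort(spec, modalities, data, meta)

    aux = assemble(["AD", "NC"])
    target = assemble(["sMCI", "pMCI"])
    truth = GroundTruth(adjacency=adjacency, effect_maps=effect_maps, effect_sizes=effect_sizes)
    return aux, target, truth
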