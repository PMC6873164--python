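"""Data model and I/O for parcellated multi-modal regional voxel data.

The universal input object is a :class:`RegionalCohort`: for every subject,
every imaging modality (gray-matter volume density from T1 MRI and
intensity-normalized FDG uptake by default) and every atlas region, a fixed
ordered vector of voxel values.  Cohorts are persisted as one hierarchical
HDF5 container (group per modality, dataset per region) plus a sidecar
tab-separated metadata table.

Voxel ordering within a region is the ascending C-order linear index of the
atlas grid; the axis order is recorded in the container header so that
extraction is reproducible across runs and platforms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

#: Canonical modality names, in fixed order.
STRUCTURAL = "structural"
METABOLIC = "metabolic"
DEFAULT_MODALITIES = (STRUCTURAL, METABOLIC)

#: Diagnostic groups.
GROUPS = ("AD", "NC", "sMCI", "pMCI")

_AXIS_ORDER = "C"  # ascending linear index, C (row-major) raveling


class InputError(ValueError):
    """Malformed input data (shape mismatch, bad labels, ...)."""


class ParseError(ValueError):
    """Malformed cohort container."""


@dataclass(frozen=True)
class AtlasSpec:
    """An atlas parcellation: ordered positive integer region labels.

    Label 0 is reserved for background.  Labels need not be contiguous.
    """

    region_ids: tuple[int, ...]
    region_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.region_ids)
        object.__setattr__(self, "region_ids", ids)
        if len(ids) < 2:
            raise InputError("an atlas needs at least 2 regions")
        if len(set(ids)) != len(ids):
            raise InputError("region ids must be unique")
        if any(i <= 0 for i in ids):
            raise InputError("region ids must be strictly positive (0 is background)")
        if self.region_names is not None and len(self.region_names) != len(ids):
            raise InputError("region_names length must match region_ids")

    @property
    def K(self) -> int:
        return len(self.region_ids)


@dataclass
class RegionalCohort:
    """Aligned per-subject, per-modality, per-region voxel matrices.

    Parameters
    ----------
    atlas
        Region definition; fixes K and the region order.
    modalities
        Ordered modality names (M >= 1; default structural + metabolic).
    data
        ``data[modality][region_id]`` is an ``n_subjects x n_k`` float array.
        The subject row order is identical across every (modality, region).
    metadata
        DataFrame with columns ``subject_id, group, age, sex``; one row per
        subject, in the same order as the matrix rows.
    voxel_order
        Optional ``region_id -> linear voxel indices`` map recording where in
        the source grid each column came from.
    """

    atlas: AtlasSpec
    modalities: tuple[str, ...]
    data: dict[str, dict[int, np.ndarray]]
    metadata: pd.DataFrame
    voxel_order: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modalities = tuple(self.modalities)
        if not self.modalities:
            raise InputError("at least one modality required")
        n = self.n_subjects
        for m in self.modalities:
            if m not in self.data:
                raise InputError(f"modality {m!r} missing from data")
            for k in self.atlas.region_ids:
                if k not in self.data[m]:
                    raise InputError(f"region {k} missing from modality {m!r}")
                mat = np.asarray(self.data[m][k], dtype=np.float64)
                if mat.ndim != 2 or mat.shape[0] != n or mat.shape[1] < 1:
                    raise InputError(
                        f"region {k} modality {m!r}: expected {n} x n_k matrix, "
                        f"got shape {mat.shape}"
                    )
                if not np.all(np.isfinite(mat)):
                    raise InputError(f"non-finite values in region {k}, modality {m!r}")
                self.data[m][k] = mat
        if not self.metadata.empty:
            required = {"subject_id", "group", "age", "sex"}
            missing = required - set(self.metadata.columns)
            if missing:
                raise InputError(f"metadata missing columns: {sorted(missing)}")
            if self.metadata["subject_id"].duplicated().any():
                raise InputError("duplicate subject_ids")
            bad = set(self.metadata["group"]) - set(GROUPS)
            if bad:
                raise InputError(f"unknown groups: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        if not self.metadata.empty:
            return len(self.metadata)
        first = self.data[self.modalities[0]][self.atlas.region_ids[0]]
        return np.asarray(first).shape[0]

    @property
    def K(self) -> int:
        return self.atlas.K

    def n_voxels(self, region_id: int) -> int:
        return self.data[self.modalities[0]][region_id].shape[1]

    def subset(self, row_index: np.ndarray | Sequence[int]) -> "RegionalCohort":
        """Return a cohort restricted to (or reordered by) the given rows."""
        idx = np.asarray(row_index)
        data = {
            m: {k: self.data[m][k][idx] for k in self.atlas.region_ids}
            for m in self.modalities
        }
        meta = (
            self.metadata.iloc[idx].reset_index(drop=True)
            if not self.metadata.empty
            else self.metadata
        )
        return RegionalCohort(self.atlas, self.modalities, data, meta, dict(self.voxel_order))

    def restrict_groups(self, groups: Sequence[str]) -> "RegionalCohort":
        mask = self.metadata["group"].isin(list(groups)).to_numpy()
        return self.subset(np.flatnonzero(mask))

    def subject_voxels(self, row: int, modality: str, region_id: int) -> np.ndarray:
        return self.data[modality][region_id][row]

    def regional_means(self) -> np.ndarray:
        """n_subjects x (M*K) matrix of per-region mean voxel values."""
        cols = [
            self.data[m][k].mean(axis=1)
            for m in self.modalities
            for k in self.atlas.region_ids
        ]
        return np.column_stack(cols)

    def equals(self, other: "RegionalCohort") -> bool:
        if self.modalities != other.modalities:
            return False
        if self.atlas.region_ids != other.atlas.region_ids:
            return False
        for m in self.modalities:
            for k in self.atlas.region_ids:
                if not np.array_equal(self.data[m][k], other.data[m][k]):
                    return False
        if self.metadata.empty != other.metadata.empty:
            return False
        if not self.metadata.empty and not self.metadata.reset_index(drop=True).equals(
            other.metadata.reset_index(drop=True)
        ):
            return False
        return True


def _as_array(vol) -> np.ndarray:
    """Accept numpy arrays, nibabel images, or NIfTI paths."""
    if isinstance(vol, (str, Path)):
        import nibabel as nib

        return np.asanyarray(nib.load(os.fspath(vol)).dataobj)
    if hasattr(vol, "dataobj"):  # nibabel SpatialImage
        return np.asanyarray(vol.dataobj)
    return np.asarray(vol)


def extract_regional_data(
    volumes: Mapping[str, Sequence],
    atlas_volume,
    spec: AtlasSpec,
    metadata: pd.DataFrame | None = None,
) -> RegionalCohort:
    """Extract per-region voxel matrices from 3-D volumes on a common grid.

    Parameters
    ----------
    volumes
        ``modality -> list of per-subject 3-D arrays`` (or nibabel images /
        NIfTI paths), all on the atlas grid.
    atlas_volume
        Integer label volume; 0 is background, every other label must be in
        ``spec.region_ids``.

    Region k's columns are the voxel values at ``atlas == k`` in ascending
    C-order linear index, identically ordered for all subjects and modalities.
    """
    atlas = _as_array(atlas_volume)
    atlas_flat = np.round(atlas).astype(np.int64).ravel(order=_AXIS_ORDER)
    labels = set(np.unique(atlas_flat)) - {0}
    unknown = labels - set(spec.region_ids)
    if unknown:
        raise InputError(f"atlas contains labels not in the spec: {sorted(unknown)}")

    voxel_order: dict[int, np.ndarray] = {}
    for k in spec.region_ids:
        idx = np.flatnonzero(atlas_flat == k)
        if idx.size == 0:
            raise InputError(f"region {k} has zero voxels in the atlas")
        voxel_order[k] = idx

    modalities = tuple(volumes.keys())
    n_subjects = len(next(iter(volumes.values())))
    data: dict[str, dict[int, np.ndarray]] = {m: {} for m in modalities}
    flat_rows: dict[str, np.ndarray] = {}
    for m in modalities:
        vols = volumes[m]
        if len(vols) != n_subjects:
            raise InputError("subject counts differ across modalities")
        rows = []
        for v in vols:
            arr = _as_array(v).astype(np.float64)
            if arr.shape != atlas.shape:
                raise InputError(
                    f"volume grid {arr.shape} does not match atlas grid {atlas.shape}"
                )
            rows.append(arr.ravel(order=_AXIS_ORDER))
        flat_rows[m] = np.vstack(rows)
    for m in modalities:
        for k in spec.region_ids:
            data[m][k] = flat_rows[m][:, voxel_order[k]]

    meta = metadata if metadata is not None else pd.DataFrame()
    return RegionalCohort(spec, modalities, data, meta, voxel_order)


# ---------------------------------------------------------------------------
# Container I/O: HDF5 (matrices, orderings) + sidecar TSV (metadata)
# ---------------------------------------------------------------------------


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.tsv")


def write_cohort(cohort: RegionalCohort, path: str | Path) -> Path:
    """Persist a cohort: HDF5 container + ``<path>.meta.tsv`` sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "mmconn-regional-cohort"
        f.attrs["version"] = 1
        f.attrs["axis_order"] = _AXIS_ORDER
        f.attrs["modalities"] = list(cohort.modalities)
        f.attrs["region_ids"] = np.asarray(cohort.atlas.region_ids, dtype=np.int64)
        if cohort.atlas.region_names is not None:
            f.attrs["region_names"] = list(cohort.atlas.region_names)
        for m in cohort.modalities:
            g = f.create_group(m)
            for k in cohort.atlas.region_ids:
                g.create_dataset(f"region_{k}", data=cohort.data[m][k])
        if cohort.voxel_order:
            g = f.create_group("voxel_order")
            for k, idx in cohort.voxel_order.items():
                g.create_dataset(f"region_{k}", data=np.asarray(idx, dtype=np.int64))
    meta = cohort.metadata if not cohort.metadata.empty else pd.DataFrame(
        columns=["subject_id", "group", "age", "sex"]
    )
    meta.to_csv(_meta_path(path), sep="\t", index=False)
    return path


def read_cohort(path: str | Path) -> RegionalCohort:
    """Read a cohort written by :func:`write_cohort`; round-trip is lossless."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "mmconn-regional-cohort":
            raise ParseError(f"{path} is not an mmconn cohort container")
        modalities = tuple(str(m) for m in f.attrs["modalities"])
        region_ids = tuple(int(i) for i in f.attrs["region_ids"])
        names = f.attrs.get("region_names")
        spec = AtlasSpec(region_ids, tuple(str(n) for n in names) if names is not None else None)
        data: dict[str, dict[int, np.ndarray]] = {}
        missing: list[str] = []
        for m in modalities:
            if m not in f:
                missing.append(f"modality group {m!r}")
                continue
            data[m] = {}
            for k in region_ids:
                key = f"region_{k}"
                if key not in f[m]:
                    missing.append(f"{m}/{key}")
                    continue
                data[m][k] = f[m][key][()]
        if missing:
            raise ParseError(f"container {path} is missing: {missing}")
        voxel_order = {}
        if "voxel_order" in f:
            for key in f["voxel_order"]:
                voxel_order[int(key.removeprefix("region_"))] = f["voxel_order"][key][()]
    mp = _meta_path(path)
    if not mp.exists():
        raise ParseError(f"metadata sidecar {mp} not found")
    meta = pd.read_csv(mp, sep="\t", dtype={"subject_id": str})
    if meta.empty:
        meta = pd.DataFrame()
    return RegionalCohort(spec, modalities, data, meta, voxel_order)


def write_network_tsv(weights: np.ndarray, region_ids: Sequence[int], path: str | Path) -> None:
    """Export a K x K network matrix as TSV with region-id headers."""
    df = pd.DataFrame(weights, index=list(region_ids), columns=list(region_ids))
    df.to_csv(path, sep="\t", index_label="region")


def read_network_tsv(path: str | Path) -> tuple[np.ndarray, list[int]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=np.float64), [int(c) for c in df.columns]
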