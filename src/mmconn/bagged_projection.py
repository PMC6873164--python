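"""Bootstrap-aggregated regional PCA and target-domain projection.

The auxiliary cohort (AD + NC) is resampled with replacement T times,
stratified so each replicate keeps the original group sizes.  For every
replicate, region and modality, the top S principal components of the
regional voxel matrix are computed (via SVD of the mean-centered resample)
and stored together with the resample's centering vector.  A target-domain
subject is then projected region by region onto each replicate's components,
yielding, per modality and PC index i, a T x K matrix whose rows index
bootstrap replicates and columns index brain regions — the design matrices
of the downstream region-wise multi-task regressions.

Bootstrap indices are shared across regions and modalities within a
replicate, so row t of every projected matrix refers to the same resample.
PCA here is unsupervised on the pooled AD+NC resample; diagnosis labels
enter only through the stratified resampling.  Eigenvector signs are aligned
to full-sample reference components so projections are stable across
replicates and runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .regional_io import InputError, RegionalCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProjectionConfig:
    T: int = 200  # bootstrap replicates
    S: int = 12  # retained principal components per region
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise InputError("T must be >= 1")
        if self.S < 1:
            raise InputError("S must be >= 1")


@dataclass
class BaggedBasis:
    """T bootstrap replicates of per-region, per-modality PCA bases.

    ``components[m][k]`` has shape (T, n_k, S): for replicate t, the columns
    of ``components[m][k][t]`` are unit-norm, mutually orthogonal
    eigenvectors of the resample's voxel covariance, in descending
    eigenvalue order, sign-aligned to the full-sample reference PCA.
    ``centers[m][k]`` has shape (T, n_k): the resample means used for
    centering, applied identically when projecting target subjects.
    """

    config: ProjectionConfig
    region_ids: tuple[int, ...]
    modalities: tuple[str, ...]
    resample_indices: np.ndarray  # T x n_aux, shared by all (k, m)
    components: dict[str, dict[int, np.ndarray]]
    centers: dict[str, dict[int, np.ndarray]]

    @property
    def T(self) -> int:
        return self.config.T

    @property
    def S(self) -> int:
        return self.config.S


@dataclass
class ProjectedSubject:
    """One target-domain subject in the bagged PC space.

    ``tensors[m]`` has shape (T, K, S); slice ``tensors[m][:, :, i]`` is the
    T x K design matrix for PC index i of modality m.
    """

    tensors: dict[str, np.ndarray]
    region_ids: tuple[int, ...]

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.tensors.keys())

    @property
    def S(self) -> int:
        return next(iter(self.tensors.values())).shape[2]

    def pc_matrix(self, modality: str, pc_index: int) -> np.ndarray:
        """The T x K matrix X_PCi for 0-based PC index ``pc_index``."""
        return self.tensors[modality][:, :, pc_index]


def _orthonormal_completion(Q: np.ndarray, n_needed: int) -> np.ndarray:
    """Deterministically extend orthonormal columns Q to n_needed columns."""
    n, have = Q.shape
    cols = [Q[:, j] for j in range(have)]
    e = 0
    while len(cols) < n_needed:
        v = np.zeros(n)
        v[e % n] = 1.0
        for c in cols:
            v = v - (c @ v) * c
        nrm = np.linalg.norm(v)
        if nrm > 1e-10:
            cols.append(v / nrm)
        e += 1
        if e > 10 * n:  # pragma: no cover - defensive
            raise RuntimeError("orthonormal completion failed")
    return np.column_stack(cols)


def _align_sign(vecs: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so dot with reference column is >= 0.

    Exact-zero dot products fall back to making the largest-|loading|
    element positive.
    """
    out = vecs.copy()
    for j in range(vecs.shape[1]):
        d = float(reference[:, j] @ vecs[:, j]) if j < reference.shape[1] else 0.0
        if d < 0:
            out[:, j] = -out[:, j]
        elif d == 0.0:
            i = int(np.argmax(np.abs(out[:, j])))
            if out[i, j] < 0:
                out[:, j] = -out[:, j]
    return out


def _pca_eigvecs(X: np.ndarray, S: int) -> np.ndarray:
    """Top-S eigenvectors (columns) of the covariance of rows of X.

    Computed by SVD of the centered data matrix for numerical stability.
    Rank-deficient directions are completed deterministically.
    """
    Xc = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * max(s[0], 1.0)))
    V = Vt[: min(S, rank)].T
    if V.shape[1] < S:
        logger.warning(
            "resample covariance rank %d < S=%d; completing with deterministic "
            "orthonormal directions",
            rank,
            S,
        )
        V = _orthonormal_completion(V, S)
    return V


def fit_bagged_basis(aux: RegionalCohort, config: ProjectionConfig) -> BaggedBasis:
    """Train the bagged PCA basis on the auxiliary AD+NC cohort.

    For each of the T replicates one stratified bootstrap resample (n_AD
    subjects drawn with replacement from AD, n_NC from NC) is shared by all
    regions and modalities; per (replicate, region, modality) the top S
    principal components and the resample mean are stored.
    """
    groups = set(aux.metadata["group"]) if not aux.metadata.empty else set()
    if groups != {"AD", "NC"}:
        raise InputError(f"auxiliary cohort must contain exactly AD and NC, got {sorted(groups)}")
    S, T = config.S, config.T
    max_S = min(
        min(aux.n_voxels(k) for k in aux.atlas.region_ids), aux.n_subjects
    )
    if S > max_S:
        raise InputError(
            f"S={S} infeasible: the smallest region / cohort supports at most S={max_S}"
        )

    rng = np.random.default_rng(config.seed)
    labels = aux.metadata["group"].to_numpy()
    idx_ad = np.flatnonzero(labels == "AD")
    idx_nc = np.flatnonzero(labels == "NC")
    resamples = np.empty((T, aux.n_subjects), dtype=np.int64)
    for t in range(T):
        resamples[t, : idx_ad.size] = rng.choice(idx_ad, size=idx_ad.size, replace=True)
        resamples[t, idx_ad.size :] = rng.choice(idx_nc, size=idx_nc.size, replace=True)

    components: dict[str, dict[int, np.ndarray]] = {m: {} for m in aux.modalities}
    centers: dict[str, dict[int, np.ndarray]] = {m: {} for m in aux.modalities}
    for m in aux.modalities:
        for k in aux.atlas.region_ids:
            X = aux.data[m][k]
            reference = _pca_eigvecs(X, S)
            comp = np.empty((T, X.shape[1], S))
            cent = np.empty((T, X.shape[1]))
            for t in range(T):
                Xt = X[resamples[t]]
                cent[t] = Xt.mean(axis=0)
                comp[t] = _align_sign(_pca_eigvecs(Xt, S), reference)
            components[m][k] = comp
            centers[m][k] = cent
    return BaggedBasis(
        config=config,
        region_ids=aux.atlas.region_ids,
        modalities=aux.modalities,
        resample_indices=resamples,
        components=components,
        centers=centers,
    )


def project_subject(
    subject_voxels: dict[str, dict[int, np.ndarray]],
    basis: BaggedBasis,
    S: int | None = None,
) -> ProjectedSubject:
    """Project one subject's regional voxel vectors onto the bagged basis.

    ``subject_voxels[m][k]`` is the length-n_k voxel vector of region k in
    modality m.  Entry (t, k, i) of the output tensor is
    ``dot(eigenvector(t, k, m, i), voxels - centering(t, k, m))``.
    """
    S = basis.S if S is None else S
    if S > basis.S:
        raise InputError(f"requested S={S} exceeds stored S={basis.S}")
    T, K = basis.T, len(basis.region_ids)
    tensors: dict[str, np.ndarray] = {}
    for m in basis.modalities:
        out = np.empty((T, K, S))
        for ki, k in enumerate(basis.region_ids):
            x = np.asarray(subject_voxels[m][k], dtype=np.float64)
            comp = basis.components[m][k]
            if x.shape[0] != comp.shape[1]:
                raise InputError(
                    f"region {k}: subject has {x.shape[0]} voxels, basis expects {comp.shape[1]}"
                )
            centered = x[None, :] - basis.centers[m][k]  # T x n_k
            # (T, n_k) x (T, n_k, S) -> (T, S)
            out[:, ki, :] = np.einsum("tn,tns->ts", centered, comp[:, :, :S])
        tensors[m] = out
    return ProjectedSubject(tensors=tensors, region_ids=basis.region_ids)


def project_cohort(cohort: RegionalCohort, basis: BaggedBasis, S: int | None = None) -> list[ProjectedSubject]:
    """Project every subject of a target cohort."""
    out = []
    for row in range(cohort.n_subjects):
        voxels = {
            m: {k: cohort.data[m][k][row] for k in cohort.atlas.region_ids}
            for m in cohort.modalities
        }
        out.append(project_subject(voxels, basis, S))
    return out
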