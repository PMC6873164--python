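"""Multi-modal connectivity: l2,1 multi-task sparse regression + bin2dec edges.

For each target region k and each retained PC index i, every modality's
projected T x K matrix acts as one regression task: the target vector is
region k's projected column, the design is the full matrix with column k
zeroed, and a multi-task group-sparse (l1/l2, "l2,1") penalty couples the
tasks so that a regressor region is selected only if it predicts the target
jointly across modalities:

    min_W  1/2 sum_m ||y^m - X^m w^m||_2^2  +  lambda * sum_j ||W_j.||_2

where W is K x M and row j collects region j's coefficients across tasks.
lambda is expressed as a fraction of lambda_max, the smallest penalty that
zeroes every coefficient, so the same ratio is meaningful across problems.

The S per-PC supports of each regressor row are read as an S-bit binary
number (PC 1 = most significant bit) and normalized by 2^S - 1, giving an
edge weight in [0, 1] that favours agreement on the top-ranked PCs.  The
resulting K x K network is asymmetric and quantized to multiples of
1/(2^S - 1).

The solver is an accelerated proximal-gradient (FISTA) method with a
function-value monotonicity safeguard; the group soft-threshold prox yields
exact zero rows, so support extraction needs no epsilon.  In
``l1_single_task`` mode with M = 1 the penalty reduces to the lasso.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .bagged_projection import ProjectedSubject
from .regional_io import InputError

logger = logging.getLogger(__name__)


class PenaltyMode(str, Enum):
    L21_MULTITASK = "l21_multitask"
    L1_SINGLE_TASK = "l1_single_task"


@dataclass(frozen=True)
class SolverConfig:
    lambda_ratio: float = 0.006
    tol: float = 1e-8
    max_iter: int = 5000
    penalty_mode: PenaltyMode = PenaltyMode.L21_MULTITASK
    kkt_tol: float = 1e-6  # early-exit optimality threshold

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_ratio <= 1.0):
            raise InputError("lambda_ratio must lie in (0, 1]")
        if self.tol <= 0 or self.kkt_tol <= 0:
            raise InputError("tolerances must be positive")


@dataclass
class MultiTaskCoefficients:
    """K x M coefficients for one (target region, PC index) regression."""

    W: np.ndarray
    target_index: int
    converged: bool
    n_iter: int
    objective: float

    def __post_init__(self) -> None:
        if self.target_index >= 0:
            assert np.all(self.W[self.target_index] == 0.0)


@dataclass
class ConnectivityNetwork:
    """Asymmetric K x K edge-weight matrix for one subject.

    Entry (k, j) is the encoded weight of regressor region j for target
    region k; every entry lies on the grid m/(2^S - 1), the diagonal is 0.
    """

    weights: np.ndarray
    S: int
    region_ids: tuple[int, ...]
    config: SolverConfig

    @property
    def K(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# Penalty primitives
# ---------------------------------------------------------------------------


def _row_norms(W: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(W * W, axis=1))


def _penalty(W: np.ndarray, lam: float, mode: PenaltyMode) -> float:
    if mode is PenaltyMode.L21_MULTITASK:
        return lam * float(_row_norms(W).sum())
    return lam * float(np.abs(W).sum())


def _prox(W: np.ndarray, thr: float, mode: PenaltyMode) -> np.ndarray:
    """Group (row-wise l2) or elementwise soft threshold; exact zeros."""
    if mode is PenaltyMode.L21_MULTITASK:
        norms = _row_norms(W)
        scale = np.zeros_like(norms)
        nz = norms > thr
        scale[nz] = 1.0 - thr / norms[nz]
        return W * scale[:, None]
    return np.sign(W) * np.maximum(np.abs(W) - thr, 0.0)


def _objective(
    W: np.ndarray,
    designs: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    lam: float,
    mode: PenaltyMode,
) -> float:
    loss = 0.0
    for m, (X, y) in enumerate(zip(designs, targets)):
        r = y - X @ W[:, m]
        loss += 0.5 * float(r @ r)
    return loss + _penalty(W, lam, mode)


def _gradient(
    W: np.ndarray, designs: Sequence[np.ndarray], targets: Sequence[np.ndarray]
) -> np.ndarray:
    G = np.empty_like(W)
    for m, (X, y) in enumerate(zip(designs, targets)):
        G[:, m] = X.T @ (X @ W[:, m] - y)
    return G


def lambda_max(
    designs: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    mode: PenaltyMode = PenaltyMode.L21_MULTITASK,
) -> float:
    """Smallest penalty level at which the solution is identically zero.

    For the row-wise l2,1 penalty this is the largest, over regressor
    columns j, l2-norm across tasks of <X^m[:, j], y^m>; for the plain l1
    penalty the max is over individual |<x_j, y>|.  A zeroed target column
    contributes 0 and never attains the max.
    """
    corr = np.column_stack([X.T @ y for X, y in zip(designs, targets)])
    if mode is PenaltyMode.L21_MULTITASK:
        val = float(_row_norms(corr).max(initial=0.0))
    else:
        val = float(np.abs(corr).max(initial=0.0))
    if val == 0.0:
        logger.warning("all regressors orthogonal to the targets; lambda_max = 0")
    return val


def solve_multitask_l21(
    designs: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    config: SolverConfig,
    target_index: int | None = None,
    lam: float | None = None,
) -> MultiTaskCoefficients:
    """Minimize the penalized multi-task least-squares objective.

    ``lam`` defaults to ``config.lambda_ratio * lambda_max(designs, targets)``.
    Returns exact zero rows (group soft-threshold prox); the target region's
    own row is structurally zero because its design column is zero.

    Convergence: relative objective change < tol on 5 consecutive iterations
    or KKT residual < 1e-6, whichever happens first.
    """
    designs = [np.asarray(X, dtype=np.float64) for X in designs]
    targets = [np.asarray(y, dtype=np.float64) for y in targets]
    M = len(designs)
    K = designs[0].shape[1]
    mode = config.penalty_mode
    if mode is PenaltyMode.L1_SINGLE_TASK and M != 1:
        raise InputError("l1_single_task mode expects exactly one task")
    for X, y in zip(designs, targets):
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise InputError("non-finite values in solver input")

    lmax = lambda_max(designs, targets, mode)
    if lam is None:
        lam = config.lambda_ratio * lmax
    if lmax == 0.0 or lam >= lmax:
        W = np.zeros((K, M))
        return MultiTaskCoefficients(
            W, target_index if target_index is not None else -1, True, 0,
            _objective(W, designs, targets, lam, mode),
        )

    # Lipschitz constant of the smooth part: max_m sigma_max(X^m)^2.
    L = max(float(np.linalg.norm(X, 2)) ** 2 for X in designs)
    if L == 0.0:
        W = np.zeros((K, M))
        return MultiTaskCoefficients(W, target_index or -1, True, 0, lam * 0.0)

    W = np.zeros((K, M))
    Z = W.copy()
    t_mom = 1.0
    f_prev = _objective(W, designs, targets, lam, mode)
    small_steps = 0
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        G = _gradient(Z, designs, targets)
        W_new = _prox(Z - G / L, lam / L, mode)
        f_new = _objective(W_new, designs, targets, lam, mode)
        if f_new > f_prev:
            # monotone safeguard: fall back to a plain proximal step from W
            G = _gradient(W, designs, targets)
            W_new = _prox(W - G / L, lam / L, mode)
            f_new = _objective(W_new, designs, targets, lam, mode)
            t_mom = 1.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        Z = W_new + ((t_mom - 1.0) / t_next) * (W_new - W)
        t_mom = t_next
        rel = abs(f_prev - f_new) / max(abs(f_prev), 1.0)
        W = W_new
        small_steps = small_steps + 1 if rel < config.tol else 0
        f_prev = f_new
        # KKT check is as costly as a gradient step; poll it periodically.
        if small_steps >= 5 or (
            it % 10 == 0
            and kkt_residual(W, designs, targets, lam, mode) < config.kkt_tol
        ):
            converged = True
            break
    if not converged:
        logger.warning("solver hit max_iter=%d without converging", config.max_iter)
    if target_index is not None:
        W[target_index] = 0.0
    return MultiTaskCoefficients(
        W, target_index if target_index is not None else -1, converged, it, f_prev
    )


def kkt_residual(
    W: np.ndarray,
    designs: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    lam: float,
    mode: PenaltyMode = PenaltyMode.L21_MULTITASK,
) -> float:
    """Max violation of the first-order optimality conditions.

    Active rows must satisfy grad_j = -lam * W_j / ||W_j||; inactive rows
    need ||grad_j|| <= lam.
    """
    G = _gradient(W, designs, targets)
    if mode is PenaltyMode.L1_SINGLE_TASK:
        g = G[:, 0]
        w = W[:, 0]
        res = 0.0
        active = w != 0
        res = max(res, float(np.max(np.abs(g[active] + lam * np.sign(w[active])), initial=0.0)))
        res = max(res, float(np.max(np.abs(g[~active]), initial=0.0) - lam) if (~active).any() else 0.0)
        return max(res, 0.0)
    norms = _row_norms(W)
    active = norms > 0
    res = 0.0
    if active.any():
        expected = -lam * W[active] / norms[active, None]
        res = max(res, float(np.max(np.abs(G[active] - expected))))
    if (~active).any():
        res = max(res, max(float(_row_norms(G[~active]).max()) - lam, 0.0))
    return res


def extract_support(coeffs: MultiTaskCoefficients) -> np.ndarray:
    """Binary K-vector: 1 where a coefficient row has any nonzero entry."""
    return (np.any(coeffs.W != 0.0, axis=1)).astype(np.int8)


def encode_weight(v: np.ndarray) -> float:
    """bin2dec edge weight: read v as binary (index 0 = PC 1 = MSB) / (2^S-1).

    All-ones maps to 1, all-zeros to 0; a support only on PC 1 outweighs any
    combination of supports on all lower-ranked PCs.
    """
    v = np.asarray(v)
    if v.size == 0:
        raise InputError("empty support vector")
    if not np.all((v == 0) | (v == 1)):
        raise InputError("support vector must be binary")
    S = v.size
    num = 0
    for bit in v.astype(int):
        num = (num << 1) | bit
    return num / (2**S - 1)


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Z-score each column over rows, then scale to unit l2-norm.

    Constant columns cannot be standardized and are set to zero (logged),
    which structurally excludes them from selection.
    """
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    degenerate = sd < 1e-12
    if degenerate.any():
        logger.warning("%d constant design column(s) zeroed", int(degenerate.sum()))
    out = np.zeros_like(Xc)
    cols = ~degenerate
    Z = Xc[:, cols] / sd[cols]
    nrm = np.linalg.norm(Z, axis=0)
    out[:, cols] = Z / nrm
    return out


def build_network(
    projected: ProjectedSubject,
    config: SolverConfig,
    S: int | None = None,
) -> ConnectivityNetwork:
    """Build one subject's K x K multi-modal connectivity network.

    For every target region k and PC index i: standardize the T x K design
    of each modality, zero column k, regress region k's centered projected
    column on the rest with the multi-task l2,1 penalty (lambda =
    lambda_ratio x that problem's lambda_max), and binarize the support.
    The S supports per regressor are bin2dec-encoded into row k of the
    weight matrix.
    """
    S = projected.S if S is None else S
    if S > projected.S:
        raise InputError(f"requested S={S} exceeds projected S={projected.S}")
    modalities = projected.modalities
    if config.penalty_mode is PenaltyMode.L1_SINGLE_TASK and len(modalities) != 1:
        raise InputError("l1_single_task mode requires a single-modality projection")
    K = len(projected.region_ids)
    # Pre-standardize each (modality, PC) design once; targets are centered
    # original columns.
    std_designs = {
        (m, i): standardize_columns(projected.pc_matrix(m, i))
        for m in modalities
        for i in range(S)
    }
    raw = {(m, i): projected.pc_matrix(m, i) for m in modalities for i in range(S)}

    V_all = np.zeros((K, K, S), dtype=np.int8)  # target k, regressor j, pc i
    for k in range(K):
        for i in range(S):
            designs = []
            targets = []
            for m in modalities:
                X = std_designs[(m, i)].copy()
                X[:, k] = 0.0
                y = raw[(m, i)][:, k]
                y = y - y.mean()
                designs.append(X)
                targets.append(y)
            coeffs = solve_multitask_l21(designs, targets, config, target_index=k)
            V_all[k, :, i] = extract_support(coeffs)

    weights = np.zeros((K, K))
    for k in range(K):
        for j in range(K):
            if j == k:
                continue
            weights[k, j] = encode_weight(V_all[k, j])
    return ConnectivityNetwork(
        weights=weights, S=S, region_ids=projected.region_ids, config=config
    )


def build_networks(
    projections: Sequence[ProjectedSubject],
    config: SolverConfig,
    S: int | None = None,
) -> list[ConnectivityNetwork]:
    return [build_network(p, config, S) for p in projections]
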