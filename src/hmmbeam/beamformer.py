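"""Stationary and state-adaptive LCMV source reconstruction.

The LCMV spatial filter for a source with oriented lead field ``h`` and data
covariance ``C`` is ``W = (h' C^-1 h)^-1 h' C^-1``: unit gain at the target
(``W h = 1``) and minimum output variance.  In the adaptive mode the
covariance -- and hence the weights and the estimator's standard deviation --
switches with the decoded state sequence: weights are computed once per
state from the state-pooled covariance and gathered by the per-sample label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh, svd

from .datasets import SensorDataset, StateSequence

logger = logging.getLogger(__name__)

__all__ = [
    "LeadFieldSet",
    "CovarianceSet",
    "SourceEstimate",
    "reduce_subspace",
    "estimate_covariances",
    "optimal_orientation",
    "lcmv_weights",
    "source_std",
    "reconstruct",
    "sliding_window_labels",
]

#: default cap on the covariance condition number before weights error out
DEFAULT_COND_CAP = 1e12


@dataclass
class LeadFieldSet:
    """Per-voxel forward fields.

    ``voxels`` are grid coordinates in MNI mm; ``fields`` has shape
    (n_voxels, n_channels, n_components) with 3 components for free
    orientation or 1 for a fixed orientation.  Voxel ordering is
    x-fastest.
    """

    voxels: np.ndarray          # (V, 3) MNI mm
    fields: np.ndarray          # (V, N, 3) or (V, N, 1)
    grid_spacing: float = 6.0   # mm

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, float))
        self.fields = np.asarray(self.fields, float)
        if self.fields.ndim != 3:
            raise ValueError("fields must be (voxels, channels, components)")
        if self.fields.shape[2] not in (1, 3):
            raise ValueError("fields must have 1 or 3 orientation components")
        if not np.isfinite(self.fields).all():
            raise ValueError("lead fields contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.fields.shape[0]

    @property
    def n_channels(self) -> int:
        return self.fields.shape[1]


@dataclass
class CovarianceSet:
    full: np.ndarray                 # (N, N)
    per_state: np.ndarray            # (K, N, N)
    counts: np.ndarray               # (K,)
    regularisation: float = 0.0

    @property
    def K(self) -> int:
        return self.per_state.shape[0]


@dataclass
class SourceEstimate:
    """Per-voxel mean and standard-deviation time courses.

    ``std`` is strictly positive; with a single state it is constant over
    time.  ``orientation`` is (V, 3) in stationary mode and (K, V, 3) when
    the orientation is re-estimated per state.
    """

    mean: np.ndarray                 # (V, T)
    std: np.ndarray                  # (V, T)
    orientation: np.ndarray
    state_labels: StateSequence | None = None
    fs: float = 1.0


# ---------------------------------------------------------------------------


def reduce_subspace(
    data: SensorDataset, lf: LeadFieldSet, rank: int
) -> tuple[SensorDataset, LeadFieldSet, np.ndarray]:
    """Project data and lead fields onto the top principal sensor axes.

    The projector is the (rank x N) matrix of leading eigenvectors of the
    sensor covariance, ordered by decreasing eigenvalue; each eigenvector's
    sign is fixed so its largest-magnitude component is positive.
    """
    N = data.n_channels
    if not 1 <= rank <= N:
        raise ValueError(f"rank must be in [1, {N}], got {rank}")
    C = np.atleast_2d(np.cov(data.data))
    evals, evecs = eigh(C)
    order = np.argsort(evals)[::-1][:rank]
    P = evecs[:, order].T  # (rank, N)
    for i in range(rank):
        j = int(np.argmax(np.abs(P[i])))
        if P[i, j] < 0:
            P[i] *= -1.0
    red_data = SensorDataset(data=P @ data.data, fs=data.fs)
    red_fields = np.einsum("rn,vnc->vrc", P, lf.fields)
    red_lf = LeadFieldSet(
        voxels=lf.voxels, fields=red_fields, grid_spacing=lf.grid_spacing
    )
    return red_data, red_lf, P


def _sample_cov(Y: np.ndarray) -> np.ndarray:
    """Unbiased sample covariance with mean removal, (T-1) denominator."""
    return np.atleast_2d(np.cov(Y))


def estimate_covariances(
    data: SensorDataset,
    u: StateSequence | None = None,
    reg: float = 0.0,
) -> CovarianceSet:
    """Full and state-pooled sensor covariance matrices.

    Per-state covariances pool the samples whose decoded label is that state,
    with state-specific mean and (T_k - 1) denominator.  ``reg`` adds
    diagonal loading ``reg * mean(diag)``; loading is also applied (and
    logged) when a matrix is not positive definite without it.
    """
    Y = data.data
    N, T = Y.shape
    full = _sample_cov(Y)
    if u is None:
        per_state = full[None].copy()
        counts = np.array([T])
    else:
        if u.n_samples != T:
            raise ValueError("state sequence length does not match data")
        K = u.K
        per_state = np.empty((K, N, N))
        counts = np.empty(K, dtype=int)
        for k in range(K):
            idx = u.labels == k + 1
            counts[k] = int(idx.sum())
            if counts[k] < N + 1:
                raise ValueError(
                    f"state {k + 1} has only {counts[k]} samples for "
                    f"dimension {N}; lower K, merge states, or increase reg"
                )
            # a state covering every sample reuses the full-covariance
            # computation so the degenerate case is exact
            per_state[k] = full if counts[k] == T else _sample_cov(Y[:, idx])
    used_reg = float(reg)
    mats = [full] + [per_state[k] for k in range(per_state.shape[0])]
    for M in mats:
        if used_reg > 0:
            M += used_reg * np.mean(np.diag(M)) * np.eye(N)
        try:
            cholesky(M, lower=True)
        except np.linalg.LinAlgError:
            if reg == 0.0:
                raise ValueError(
                    "rank-deficient within-state covariance with reg=0; "
                    "pass reg > 0 or reduce the subspace rank"
                )
            raise
    if used_reg > 0:
        logger.info("diagonal loading applied: reg=%.3g", used_reg)
    return CovarianceSet(
        full=full, per_state=per_state, counts=counts, regularisation=used_reg
    )


def _fix_sign(v: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(v) > 1e-12 * np.abs(v).max())
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def optimal_orientation(H3: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Source orientation maximising the beamformed output SNR (pseudo-Z).

    The beamformer output power along unit orientation ``eta`` is
    ``1/(h' C^-1 h)`` with ``h = H eta``, and its white-noise gain is
    ``h' C^-2 h / (h' C^-1 h)^2``; their ratio -- the pseudo-Z statistic --
    is maximised by the largest generalized eigenvector of the pencil
    ``(H' C^-1 H, H' C^-2 H)``.  Normalising by the noise gain is essential:
    the raw output power is dominated by noise amplification along weak
    lead-field directions when the source is far below sensor noise.  When
    the pseudo-Z is flat (e.g. ``C`` proportional to identity) the tie is
    broken by the largest forward gain ``||H eta||``.  Sign convention:
    first nonzero component positive.  Raises on rank-deficient ``H3``.
    """
    H3 = np.asarray(H3, float)
    if H3.ndim != 2 or H3.shape[1] != 3:
        raise ValueError("H3 must be N x 3")
    s = svd(H3, compute_uv=False)
    if s[-1] <= 1e-10 * s[0]:
        raise ValueError(
            "lead field matrix is rank deficient; restrict the orientation "
            "search to its column space"
        )
    return _orientation_in_subspace(H3, C, rank=3)


def _orientation_in_subspace(
    H3: np.ndarray, C: np.ndarray, rank: int | None = None
) -> np.ndarray:
    """Pseudo-Z-maximising orientation restricted to the lead field column
    space.

    Spherical-conductor MEG lead fields are blind to the radial direction, so
    the N x 3 matrix has numerical rank 2; the search is then confined to the
    2-D tangential subspace.
    """
    U, s, Vt = svd(H3, full_matrices=False)
    if rank is None:
        rank = int(np.sum(s > 1e-10 * s[0]))
        rank = max(rank, 1)
    Vr = Vt[:rank].T                      # (3, r)
    Hr = H3 @ Vr                          # (N, r)
    cf = cho_factor(C, lower=True)
    CiH = cho_solve(cf, Hr)
    M1 = Hr.T @ CiH                       # H' C^-1 H
    M2 = CiH.T @ CiH                      # H' C^-2 H
    evals, evecs = eigh(M1, M2)
    top = evals[-1]
    tied = evals >= top * (1.0 - 1e-9)
    if tied.sum() > 1:
        # pseudo-Z flat on this subspace: fall back to the largest forward
        # gain ||H eta|| per unit Euclidean orientation (evecs are
        # M2-orthonormal, so solve in that metric explicitly)
        Wt = evecs[:, tied]
        G1 = Wt.T @ (Hr.T @ Hr) @ Wt
        G0 = Wt.T @ Wt
        gvals, gvecs = eigh(G1, G0)
        w = Wt @ gvecs[:, -1]
    else:
        w = evecs[:, -1]
    eta = Vr @ w
    eta = eta / np.linalg.norm(eta)
    return _fix_sign(eta)


def lcmv_weights(
    h: np.ndarray, C: np.ndarray, cond_cap: float = DEFAULT_COND_CAP
) -> np.ndarray:
    """LCMV weight row vector ``W = (h' C^-1 h)^-1 h' C^-1``.

    Satisfies ``W @ h == 1``.  Raises if the covariance condition number
    exceeds ``cond_cap``.
    """
    h = np.asarray(h, float).ravel()
    if not np.any(h):
        raise ValueError("lead field must be nonzero")
    C = np.asarray(C, float)
    evals = np.linalg.eigvalsh(C)
    if evals[0] <= 0 or evals[-1] / evals[0] > cond_cap:
        raise ValueError(
            f"covariance condition number {evals[-1] / max(evals[0], 1e-300):.3g} "
            f"exceeds cap {cond_cap:.3g}; add diagonal loading (reg) or reduce "
            "the subspace rank"
        )
    cf = cho_factor(C, lower=True)
    x = cho_solve(cf, h)
    return x / (h @ x)


def source_std(W: np.ndarray, C: np.ndarray) -> float:
    """Standard deviation of the beamformed estimate, ``(W C W')^{1/2}``."""
    W = np.asarray(W, float).ravel()
    return float(np.sqrt(W @ np.asarray(C, float) @ W))


def reconstruct(
    data: SensorDataset,
    lf: LeadFieldSet,
    covs: CovarianceSet,
    u: StateSequence | None = None,
    orientation_mode: str = "per-state",
    cond_cap: float = DEFAULT_COND_CAP,
) -> SourceEstimate:
    """Beamform every voxel, stationary or state-adaptive.

    Stationary mode (``u is None``): one weight vector per voxel from the
    full covariance; the std is constant over time.  Adaptive mode: per
    state, the orientation (unless ``orientation_mode='global'``) and the
    weights are computed from the state covariance, then gathered by the
    per-sample label; the std time course switches with the state.  A
    fixed sliding-window reconstruction is the same code path with block
    labels (see :func:`sliding_window_labels`).
    """
    Y = data.data
    N, T = Y.shape
    if lf.n_channels != N:
        raise ValueError("lead field channel dimension does not match data")
    if orientation_mode not in ("per-state", "global"):
        raise ValueError("orientation_mode must be 'per-state' or 'global'")
    V = lf.n_voxels
    oriented = lf.fields.shape[2] == 1

    if u is None:
        C = covs.full
        mean = np.empty((V, T))
        std = np.empty((V, T))
        orientation = np.zeros((V, 3))
        for v in range(V):
            H = lf.fields[v]
            if oriented:
                h = H[:, 0]
                eta = np.array([1.0, 0.0, 0.0])
            else:
                eta = _orientation_in_subspace(H, C)
                h = H @ eta
            W = lcmv_weights(h, C, cond_cap)
            mean[v] = W @ Y
            std[v] = source_std(W, C)
            orientation[v] = eta
        return SourceEstimate(
            mean=mean, std=std, orientation=orientation, state_labels=None,
            fs=data.fs,
        )

    if u.n_samples != T:
        raise ValueError("state sequence length does not match data")
    K = u.K
    if covs.per_state.shape[0] != K:
        raise ValueError(
            f"covariance set has {covs.per_state.shape[0]} states but labels "
            f"reference K={K}"
        )
    present = np.unique(u.labels)
    mean = np.empty((V, T))
    std = np.empty((V, T))
    orientation = np.zeros((K, V, 3))
    if orientation_mode == "global":
        eta_global = np.empty((V, 3))
        for v in range(V):
            H = lf.fields[v]
            if oriented:
                eta_global[v] = np.array([1.0, 0.0, 0.0])
            else:
                eta_global[v] = _orientation_in_subspace(H, covs.full)
    for k in present - 1:
        Ck = covs.per_state[k]
        idx = u.labels == k + 1
        # reuse the original array when the state covers everything so the
        # single-state case is bitwise identical to the stationary path
        Yk = Y if idx.all() else Y[:, idx]
        for v in range(V):
            H = lf.fields[v]
            if oriented:
                h = H[:, 0]
                eta = np.array([1.0, 0.0, 0.0])
            elif orientation_mode == "global":
                eta = eta_global[v]
                h = H @ eta
            else:
                eta = _orientation_in_subspace(H, Ck)
                h = H @ eta
            W = lcmv_weights(h, Ck, cond_cap)
            mean[v, idx] = W @ Yk
            std[v, idx] = source_std(W, Ck)
            orientation[k, v] = eta
    return SourceEstimate(
        mean=mean, std=std, orientation=orientation, state_labels=u, fs=data.fs
    )


def sliding_window_labels(T: int, fs: float, window_s: float) -> StateSequence:
    """Fixed consecutive equal-width blocks as a state sequence.

    Every block of ``window_s`` seconds becomes its own 'state', so the
    adaptive reconstruction code path turns into the fixed sliding-window
    comparator.
    """
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError("window shorter than one sample")
    labels = np.arange(T) // w + 1
    return StateSequence(labels=labels, K=int(labels.max()), fs=fs)
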