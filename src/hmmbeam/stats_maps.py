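"""Seed-based correlation maps, GLM t-statistics and map thresholding.

Temporal autocorrelation of envelope series is not corrected: t-statistics
use the naive dof = T - P, matching the uncorrected-statistics convention of
beamformer envelope analyses.  Multiple-testing correction is not applied;
the display operation is percentile thresholding of the in-mask values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import StateSequence

__all__ = [
    "DesignMatrix",
    "StatMap",
    "build_boxcar_design",
    "leakage_regress",
    "glm_tstat",
    "seed_map",
    "fixed_effects",
    "percentile_threshold",
]

#: cap applied to t-statistics when the residual variance underflows
T_CAP = 1e8


@dataclass
class DesignMatrix:
    matrix: np.ndarray                 # (T_out, P)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if not self.names:
            self.names = [f"reg{i}" for i in range(self.matrix.shape[1])]
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def P(self) -> int:
        return self.matrix.shape[1]


@dataclass
class StatMap:
    """Per-voxel scalar statistic with an in-brain mask and a display mask.

    ``values`` always holds the full statistic; thresholding only narrows
    ``display_mask`` (so re-thresholding at the same percentile is
    idempotent).  ``masked_values`` puts NaN outside the display mask.
    """

    values: np.ndarray
    dof: float
    grid: np.ndarray | None = None     # (V, 3) MNI mm
    mask: np.ndarray | None = None     # in-brain mask
    display_mask: np.ndarray | None = None
    flags: np.ndarray | None = None    # voxels where a guard fired
    betas: np.ndarray | None = None    # effect estimates behind the t values
    variances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.dof <= 0:
            raise ValueError("dof must be positive")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        if self.display_mask is None:
            self.display_mask = self.mask.copy()

    @property
    def masked_values(self) -> np.ndarray:
        out = np.where(self.display_mask, self.values, np.nan)
        return out


def build_boxcar_design(
    condition_labels: np.ndarray,
    conditions: list | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """0/1 boxcar regressors from a per-sample condition label series.

    With ``intercept=True`` the first condition acts as the reference (its
    boxcar is dropped so the design stays full rank); contrasts on the
    remaining columns are differences versus that reference.
    """
    condition_labels = np.asarray(condition_labels)
    if conditions is None:
        conditions = list(np.unique(condition_labels))
    cols = []
    names = []
    start = 1 if intercept else 0
    if intercept:
        cols.append(np.ones(condition_labels.size))
        names.append("intercept")
    for c in conditions[start:] if intercept else conditions:
        cols.append((condition_labels == c).astype(float))
        names.append(str(c))
    return DesignMatrix(matrix=np.column_stack(cols), names=names)


def leakage_regress(
    seed_raw: np.ndarray,
    test_raw: np.ndarray,
    u: StateSequence | None = None,
) -> np.ndarray:
    """Remove zero-lag leakage of the seed from test time series.

    Within each state's samples (or globally when no state sequence is
    given), the test series is regressed on the seed (with intercept) by
    ordinary least squares and the residual returned; the within-state
    zero-lag covariance between seed and residual is then zero.
    """
    seed = np.asarray(seed_raw, float).ravel()
    test = np.asarray(test_raw, float)
    single = test.ndim == 1
    test = np.atleast_2d(test)
    if test.shape[1] != seed.size:
        raise ValueError("seed and test series must have equal length")
    out = test.copy()
    if u is None:
        groups = [np.ones(seed.size, dtype=bool)]
    else:
        if u.n_samples != seed.size:
            raise ValueError("state sequence length does not match series")
        groups = [u.labels == k + 1 for k in range(u.K)]
    for gi, idx in enumerate(groups):
        n = int(idx.sum())
        if n < 2:
            continue
        s = seed[idx]
        if s.var() == 0:
            warnings.warn(
                f"zero-variance seed within state {gi + 1}; leakage "
                "correction skipped for that state",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        sc = s - s.mean()
        Tt = test[:, idx]
        beta = (Tt - Tt.mean(axis=1, keepdims=True)) @ sc / (sc @ sc)
        fit = beta[:, None] * s[None, :]
        resid = Tt - fit
        # OLS with intercept: remove the fitted intercept too
        resid -= resid.mean(axis=1, keepdims=True)
        out[:, idx] = resid
    return out[0] if single else out


def glm_tstat(
    Y: np.ndarray, X: DesignMatrix, contrast: np.ndarray
) -> StatMap:
    """Mass-univariate OLS t-statistic map.

    ``t = c' beta / (sigma * sqrt(c' (X'X)^-1 c))`` with
    ``dof = T_out - P``.  Voxels with vanishing residual variance are capped
    at +/-T_CAP and flagged.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    Xm = X.matrix
    T_out, P = Xm.shape
    if Y.shape[1] != T_out:
        raise ValueError("Y and design matrix row counts differ")
    if T_out <= P:
        raise ValueError("need T_out > P for residual degrees of freedom")
    c = np.asarray(contrast, float).ravel()
    if c.size != P:
        raise ValueError("contrast length must equal the number of regressors")
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    betas = Y @ Xm @ XtX_inv.T                      # (V, P)
    resid = Y - betas @ Xm.T
    dof = T_out - P
    sigma2 = (resid**2).sum(axis=1) / dof
    denom_c = float(c @ XtX_inv @ c)
    eff = betas @ c
    scale = np.sqrt(np.maximum(sigma2 * denom_c, 0.0))
    flags = scale <= np.abs(eff) / T_CAP
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(flags, np.sign(eff) * T_CAP, eff / np.where(scale > 0, scale, 1.0))
    t = np.where((scale == 0) & (eff == 0), 0.0, t)
    return StatMap(values=t, dof=dof, flags=flags, betas=betas)


def seed_map(seed_pow: np.ndarray, voxel_pows: np.ndarray) -> StatMap:
    """Simple-regression t map of the seed power regressor (with intercept).

    Voxels with a constant time series get t = 0 with a warning.
    """
    seed = np.asarray(seed_pow, float).ravel()
    Y = np.atleast_2d(np.asarray(voxel_pows, float))
    if Y.shape[1] != seed.size:
        raise ValueError("seed and voxel series must have equal length")
    X = DesignMatrix(
        matrix=np.column_stack([np.ones(seed.size), seed]),
        names=["intercept", "seed"],
    )
    const = Y.var(axis=1) == 0
    sm = glm_tstat(Y, X, contrast=[0.0, 1.0])
    if const.any():
        warnings.warn(
            f"{int(const.sum())} voxel(s) have constant series; t set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        sm.values[const] = 0.0
        sm.flags = sm.flags | const if sm.flags is not None else const
    return sm


def fixed_effects(
    betas: np.ndarray,
    variances: np.ndarray,
    dofs: np.ndarray | None = None,
) -> StatMap:
    """Inverse-variance weighted fixed-effects combination over states.

    ``beta_bar = (sum beta_k / v_k) / (sum 1/v_k)``,
    ``var = 1 / (sum 1/v_k)``, ``t = beta_bar / sqrt(var)``,
    ``dof = sum dof_k`` (one dof per state when not given).
    """
    betas = np.atleast_2d(np.asarray(betas, float))       # (K, V)
    variances = np.atleast_2d(np.asarray(variances, float))
    if betas.shape != variances.shape:
        raise ValueError("betas and variances must have the same shape")
    if np.any(variances <= 0):
        raise ValueError("all variances must be positive")
    w = 1.0 / variances
    beta_bar = (betas * w).sum(axis=0) / w.sum(axis=0)
    var = 1.0 / w.sum(axis=0)
    t = beta_bar / np.sqrt(var)
    dof = float(np.sum(dofs)) if dofs is not None else float(betas.shape[0])
    return StatMap(values=t, dof=dof, betas=beta_bar, variances=var)


def percentile_threshold(stat_map: StatMap, pct: float) -> StatMap:
    """Keep voxels at or above the pct-th percentile of in-mask values.

    The percentile is rank-based: with n in-mask voxels the lowest
    ``floor(n * pct / 100)`` are marked null, so a vanishing percentile
    retains every voxel.  The in-brain mask is never changed by
    thresholding, so applying the same threshold twice gives the same
    result.  Sub-threshold voxels are NaN in ``masked_values``.
    """
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    mask = stat_map.mask
    if mask is None or not mask.any():
        raise ValueError("empty mask")
    vals = np.sort(stat_map.values[mask])
    k = int(np.floor(vals.size * pct / 100.0))
    tau = vals[min(k, vals.size - 1)]
    display = mask & (stat_map.values >= tau)
    return StatMap(
        values=stat_map.values,
        dof=stat_map.dof,
        grid=stat_map.grid,
        mask=mask,
        display_mask=display,
        flags=stat_map.flags,
    )
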