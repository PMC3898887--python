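"""Summary statistics of state sequences and covariance dissimilarity.

Fractional occupancy is the fraction of samples assigned to each state; the
mean life-time is the average contiguous dwell per visit; occurrences are
counted as rising edges of the binary state indicator (a run starting at the
first sample counts as an occurrence, and runs truncated by the end of the
sequence count too).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky

from .datasets import StateSequence

__all__ = [
    "StateSummary",
    "summarize_states",
    "symmetrised_kl",
    "state_indicator_spectrum",
]


@dataclass
class StateSummary:
    fractional_occupancy: np.ndarray  # (K,), sums to 1
    mean_lifetime_s: np.ndarray       # (K,), seconds (0 for unvisited states)
    n_occurrences: np.ndarray         # (K,), integer counts
    occupancy_s: np.ndarray           # (K,), seconds
    occupancy_samples: np.ndarray     # (K,), integer sample counts


def summarize_states(u: StateSequence) -> StateSummary:
    """Per-state occupancy, visit counts and mean life-times."""
    labels = u.labels
    T = labels.size
    K = u.K
    counts = np.bincount(labels - 1, minlength=K)
    fo = counts / T
    # rising edges of each state's indicator; first sample counts if active
    prev = np.concatenate(([0], labels[:-1]))
    starts = labels != prev
    n_occ = np.zeros(K, dtype=int)
    for k in range(K):
        n_occ[k] = int(np.count_nonzero(starts & (labels == k + 1)))
    occupancy_s = counts / u.fs
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_lt = np.where(n_occ > 0, occupancy_s / np.maximum(n_occ, 1), 0.0)
    return StateSummary(
        fractional_occupancy=fo,
        mean_lifetime_s=mean_lt,
        n_occurrences=n_occ,
        occupancy_s=occupancy_s,
        occupancy_samples=counts,
    )


def _check_spd(S: np.ndarray, name: str) -> np.ndarray:
    S = np.asarray(S, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError(f"{name} is not positive definite")
    return S


def symmetrised_kl(Sigma_a: np.ndarray, Sigma_b: np.ndarray) -> float:
    """Symmetrised KL divergence between zero-mean Gaussians.

    Returns ``0.25*[tr(Sb^-1 Sa) + tr(Sa^-1 Sb)] - N/2``: symmetric in its
    arguments, zero iff the two covariances are equal.
    """
    Sa = _check_spd(Sigma_a, "Sigma_a")
    Sb = _check_spd(Sigma_b, "Sigma_b")
    if Sa.shape != Sb.shape:
        raise ValueError("covariances must have the same dimension")
    N = Sa.shape[0]
    La = cholesky(Sa, lower=True)
    Lb = cholesky(Sb, lower=True)
    tr_ab = np.trace(cho_solve((Lb, True), Sa))  # tr(Sb^-1 Sa)
    tr_ba = np.trace(cho_solve((La, True), Sb))
    return float(0.25 * (tr_ab + tr_ba) - N / 2.0)


def state_indicator_spectrum(
    u: StateSequence, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of the mean-removed binary indicator of state ``k``.

    Uses the convention ``P(f) = |X(f)|^2 / T`` with one-sided doubling of
    the non-DC/non-Nyquist bins, so that the summed power equals the
    indicator variance times T (Parseval).
    """
    ind = u.indicator(k)
    if ind.sum() == 0:
        warnings.warn(
            f"state {k} never visited; spectrum is identically zero",
            RuntimeWarning,
            stacklevel=2,
        )
    x = ind - ind.mean()
    T = x.size
    X = np.fft.rfft(x)
    power = np.abs(X) ** 2 / T
    # one-sided doubling (DC and, for even T, Nyquist appear once)
    if T % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(T, d=1.0 / u.fs)
    return freqs, power
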