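"""Gaussian-observation hidden Markov model with variational Bayes inference.

The sensor data ``y_t`` (an N-vector per sample) is modelled as being emitted
from one of K hidden states; state k emits from a multivariate Normal
N(mu_k, Sigma_k) and the state sequence follows a first-order Markov chain
with a K x K row-stochastic transition matrix.  Inference is variational
Bayes with conjugate priors: Dirichlet on the initial-state vector and on
each transition row, Normal-Wishart on each state's (mean, precision).

The evidence lower bound is referred to throughout as the *free energy* with
the sign convention that larger is better (it is the negative of the
variational free energy in the physics convention); the trace is
non-decreasing over iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.ndimage import uniform_filter1d
from scipy.special import digamma, gammaln, multigammaln

from .datasets import SensorDataset, StateSequence

logger = logging.getLogger(__name__)

__all__ = [
    "HMMConfig",
    "HMMPosterior",
    "fit_hmm",
    "viterbi_decode",
    "sample_hmm",
    "select_model_order",
    "merge_rare_states",
]


@dataclass
class HMMConfig:
    """Configuration of the variational HMM fit.

    ``prior_strength`` scales the weakly informative conjugate priors
    (Dirichlet pseudo-counts and Normal-Wishart beta0); the Wishart scale is
    matched to the data covariance so that the prior expected state
    covariance equals the global sample covariance.
    """

    K: int = 7
    max_iter: int = 200
    tol: float = 1e-6
    n_restarts: int = 2
    prior_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.prior_strength < 0:
            raise ValueError("prior_strength must be nonnegative")


@dataclass
class HMMPosterior:
    """Fitted state parameters and the posterior state probabilities.

    ``covariances`` are the responsibility-weighted empirical state
    covariances (unbiased denominator), so that with a single state they
    coincide exactly with the sample covariance of the data.  ``transition``
    and ``initial`` are posterior-mean Dirichlet probabilities.
    """

    means: np.ndarray            # (K, N)
    covariances: np.ndarray      # (K, N, N)
    transition: np.ndarray       # (K, K), rows sum to 1
    initial: np.ndarray          # (K,)
    free_energy_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    gamma: np.ndarray | None = None   # (T, K)

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.initial = np.atleast_1d(np.asarray(self.initial, dtype=float))
        rows = self.transition.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]

    @property
    def free_energy(self) -> float:
        return float(self.free_energy_trace[-1])


# ---------------------------------------------------------------------------
# helpers


def _check_data(data: SensorDataset, K: int) -> np.ndarray:
    Y = data.data
    N, T = Y.shape
    var = Y.var(axis=1)
    # a constant channel may carry O(eps^2) rounding variance
    tol = (1e-12 * np.maximum(1.0, np.abs(Y).max(axis=1))) ** 2
    dead = np.flatnonzero(var <= tol)
    if dead.size:
        raise ValueError(
            f"channel(s) {dead.tolist()} have zero variance; remove or jitter "
            "degenerate channels before fitting"
        )
    if T <= K * (N + 1):
        raise ValueError(
            f"need more than K*(N+1)={K * (N + 1)} samples to fit K={K} states "
            f"on N={N} channels; got T={T}"
        )
    return Y


def _e_log_det_lambda(cho_Winv: np.ndarray, nu: float, d: int) -> float:
    """E_q[ln |Lambda|] for a Wishart q with scale W = Winv^{-1} and dof nu."""
    logdet_Winv = 2.0 * np.log(np.diag(cho_Winv)).sum()
    return (
        digamma(0.5 * (nu - np.arange(d))).sum() + d * np.log(2.0) - logdet_Winv
    )


def _kl_dirichlet(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a.sum()
    return float(
        gammaln(a0)
        - gammaln(a).sum()
        - gammaln(b.sum())
        + gammaln(b).sum()
        + ((a - b) * (digamma(a) - digamma(a0))).sum()
    )


def _log_wishart_B(logdet_Winv: float, nu: float, d: int) -> float:
    return 0.5 * nu * logdet_Winv - 0.5 * nu * d * np.log(2.0) - multigammaln(
        0.5 * nu, d
    )


class _NWPrior:
    """Shared Normal-Wishart + Dirichlet hyperprior, scaled to the data."""

    def __init__(self, Y: np.ndarray, prior_strength: float):
        N, T = Y.shape
        eps = 1e-8
        self.d = N
        self.m0 = Y.mean(axis=1)
        self.beta0 = max(prior_strength, eps)
        self.nu0 = N + 2.0
        S = np.cov(Y)
        S = np.atleast_2d(S)
        # prior expected covariance = data covariance
        self.W0inv = S * self.nu0
        self.W0inv += np.eye(N) * (1e-10 * np.trace(self.W0inv) / N + 1e-300)
        self.cho_W0inv = cholesky(self.W0inv, lower=True)
        self.logdet_W0inv = 2.0 * np.log(np.diag(self.cho_W0inv)).sum()
        self.alpha0 = max(prior_strength, eps)


class _VBState:
    """Variational posterior hyperparameters for one fit."""

    def __init__(self, prior: _NWPrior, K: int):
        self.prior = prior
        self.K = K
        d = prior.d
        self.beta = np.full(K, prior.beta0)
        self.nu = np.full(K, prior.nu0)
        self.m = np.tile(prior.m0, (K, 1))
        self.Winv = np.tile(prior.W0inv, (K, 1, 1))
        self.alpha_init = np.full(K, prior.alpha0)
        self.alpha_trans = np.full((K, K), prior.alpha0)
        self._refresh()

    def _refresh(self) -> None:
        d = self.prior.d
        self.cho_Winv = np.empty_like(self.Winv)
        self.e_logdet = np.empty(self.K)
        for k in range(self.K):
            jitter = 0.0
            base = self.Winv[k]
            scale = np.trace(base) / d
            while True:
                try:
                    L = cholesky(base + jitter * np.eye(d), lower=True)
                    break
                except np.linalg.LinAlgError:
                    jitter = max(jitter * 10.0, 1e-12 * scale)
                    warnings.warn(
                        f"singular within-state covariance for state {k + 1}; "
                        f"adding diagonal jitter {jitter:.3e}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
            if jitter:
                self.Winv[k] = base + jitter * np.eye(d)
            self.cho_Winv[k] = L
            self.e_logdet[k] = _e_log_det_lambda(L, self.nu[k], d)
        self.e_log_init = digamma(self.alpha_init) - digamma(self.alpha_init.sum())
        self.e_log_trans = digamma(self.alpha_trans) - digamma(
            self.alpha_trans.sum(axis=1, keepdims=True)
        )

    # -- E step quantities -------------------------------------------------
    def expected_loglik(self, Y: np.ndarray) -> np.ndarray:
        """T x K matrix of E_q[ln p(y_t | s_t = k)]."""
        d, T = Y.shape
        ll = np.empty((T, self.K))
        for k in range(self.K):
            diff = Y - self.m[k][:, None]
            # (y-m)^T W (y-m) with W = Winv^{-1}
            X = solve_triangular(self.cho_Winv[k], diff, lower=True)
            quad = self.nu[k] * (X * X).sum(axis=0)
            ll[:, k] = 0.5 * (
                self.e_logdet[k]
                - d * np.log(2.0 * np.pi)
                - d / self.beta[k]
                - quad
            )
        return ll

    def m_step(self, Y: np.ndarray, gamma: np.ndarray, xi: np.ndarray) -> None:
        p = self.prior
        d = p.d
        Nk = gamma.sum(axis=0)
        self.alpha_init = p.alpha0 + gamma[0]
        self.alpha_trans = p.alpha0 + xi
        self.beta = p.beta0 + Nk
        self.nu = p.nu0 + Nk
        for k in range(self.K):
            g = gamma[:, k]
            if Nk[k] > 0:
                xbar = (Y * g).sum(axis=1) / Nk[k]
                diff = Y - xbar[:, None]
                Sk = (diff * g) @ diff.T
            else:
                xbar = p.m0
                Sk = np.zeros((d, d))
            self.m[k] = (p.beta0 * p.m0 + Nk[k] * xbar) / self.beta[k]
            dm = xbar - p.m0
            self.Winv[k] = (
                p.W0inv
                + Sk
                + (p.beta0 * Nk[k] / (p.beta0 + Nk[k])) * np.outer(dm, dm)
            )
        self._refresh()

    def kl_parameters(self) -> float:
        """KL(q || prior) over all parameter factors."""
        p = self.prior
        d = p.d
        kl = _kl_dirichlet(self.alpha_init, np.full(self.K, p.alpha0))
        for j in range(self.K):
            kl += _kl_dirichlet(self.alpha_trans[j], np.full(self.K, p.alpha0))
        for k in range(self.K):
            L = self.cho_Winv[k]
            logdet_Winv = 2.0 * np.log(np.diag(L)).sum()
            elog = self.e_logdet[k]
            nu, beta = self.nu[k], self.beta[k]
            dm = self.m[k] - p.m0
            x = solve_triangular(L, dm, lower=True)
            quad = float(x @ x)  # dm^T W dm
            kl_normal = 0.5 * (
                d * np.log(beta / p.beta0)
                + d * (p.beta0 / beta - 1.0)
                + p.beta0 * nu * quad
            )
            # tr(W0inv W) = tr(solve(Winv, W0inv))
            tr = np.trace(cho_solve((L, True), p.W0inv))
            kl_wishart = (
                _log_wishart_B(logdet_Winv, nu, d)
                - _log_wishart_B(p.logdet_W0inv, p.nu0, d)
                + 0.5 * (nu - p.nu0) * elog
                - 0.5 * nu * d
                + 0.5 * nu * tr
            )
            kl += kl_normal + kl_wishart
        return float(kl)


def _forward_backward(
    log_init: np.ndarray,
    log_trans: np.ndarray,
    loglik: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward.

    Returns (gamma, xi, log_normaliser) where xi is the summed K x K matrix
    of expected transition counts.
    """
    T, K = loglik.shape
    # the surrogate probabilities exp(E[ln pi]) are used unnormalised; the
    # scaling constants absorb them and log_norm is then the exact ELBO term
    A = np.exp(log_trans)
    pi0 = np.exp(log_init)
    m = loglik.max(axis=1)
    B = np.exp(loglik - m[:, None])

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi0 * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    AT = A.T
    for t in range(1, T):
        a = (AT @ alpha[t - 1]) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = A @ (B[t + 1] * beta[t + 1]) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # xi_jk summed over t: alpha_{t-1,j} A_jk B_tk beta_tk / c_t
    w = B[1:] * beta[1:] / c[1:, None]
    xi = A * (alpha[:-1].T @ w)
    log_norm = float(np.log(c).sum() + m.sum())
    return gamma, xi, log_norm


def _init_gamma_kmeans(Y: np.ndarray, K: int, fs_window: int, seed: int) -> np.ndarray:
    """Initial responsibilities from k-means on log moving-variance features."""
    from sklearn.cluster import KMeans

    power = uniform_filter1d(Y**2, size=max(3, fs_window), axis=1, mode="nearest")
    feat = np.log(power + 1e-12).T
    km = KMeans(n_clusters=K, n_init=3, random_state=seed % (2**31))
    lab = km.fit_predict(feat)
    T = Y.shape[1]
    gamma = np.full((T, K), 0.05 / K)
    gamma[np.arange(T), lab] += 0.95
    return gamma


def _init_gamma_random(T: int, K: int, rng: np.random.Generator) -> np.ndarray:
    gamma = rng.dirichlet(np.ones(K), size=T)
    return gamma


def _empirical_covariances(
    Y: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Responsibility-weighted means and unbiased empirical covariances."""
    d, T = Y.shape
    K = gamma.shape[1]
    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    full_cov = np.atleast_2d(np.cov(Y))
    for k in range(K):
        g = gamma[:, k]
        Nk = g.sum()
        if Nk < 2.0:
            warnings.warn(
                f"state {k + 1} has effective occupancy {Nk:.2f} < 2; "
                "falling back to the global covariance",
                RuntimeWarning,
                stacklevel=2,
            )
            means[k] = Y.mean(axis=1)
            covs[k] = full_cov
            continue
        xbar = (Y * g).sum(axis=1) / Nk
        diff = Y - xbar[:, None]
        covs[k] = (diff * g) @ diff.T / (Nk - 1.0)
        means[k] = xbar
        # SPD guard
        try:
            cholesky(covs[k], lower=True)
        except np.linalg.LinAlgError:
            jit = 1e-10 * np.trace(covs[k]) / d + 1e-300
            covs[k] += jit * np.eye(d)
            warnings.warn(
                f"state {k + 1} empirical covariance regularised with "
                f"jitter {jit:.3e}",
                RuntimeWarning,
                stacklevel=2,
            )
    return means, covs


# ---------------------------------------------------------------------------
# public API


def fit_hmm(data: SensorDataset, cfg: HMMConfig) -> HMMPosterior:
    """Fit a K-state Gaussian-observation HMM by variational Bayes.

    Runs ``cfg.n_restarts`` fits (one k-means-seeded, the rest from random
    responsibilities) and returns the restart with the highest final free
    energy.  The free-energy trace (one entry per iteration) is monotone
    non-decreasing up to numerical tolerance.
    """
    Y = _check_data(data, cfg.K)
    K = cfg.K
    prior = _NWPrior(Y, cfg.prior_strength)
    T = Y.shape[1]
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_restarts)

    best: tuple[float, _VBState, np.ndarray, np.ndarray] | None = None
    for r in range(cfg.n_restarts):
        rng = np.random.default_rng(children[r])
        if r == 0:
            gamma = _init_gamma_kmeans(
                Y, K, int(round(0.2 * data.fs)), int(rng.integers(2**31))
            )
        else:
            gamma = _init_gamma_random(T, K, rng)
        xi = gamma[:-1].T @ gamma[1:]
        vb = _VBState(prior, K)
        trace: list[float] = []
        F_prev = -np.inf
        for _ in range(cfg.max_iter):
            vb.m_step(Y, gamma, xi)
            ll = vb.expected_loglik(Y)
            gamma, xi, log_norm = _forward_backward(
                vb.e_log_init, vb.e_log_trans, ll
            )
            F = log_norm - vb.kl_parameters()
            trace.append(F)
            if np.isfinite(F_prev) and abs(F - F_prev) < cfg.tol * abs(F):
                break
            F_prev = F
        logger.info(
            "restart %d: free energy %.6g after %d iterations", r, trace[-1], len(trace)
        )
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], vb, gamma, np.asarray(trace))

    assert best is not None
    _, vb, gamma, trace = best
    means, covs = _empirical_covariances(Y, gamma)
    transition = vb.alpha_trans / vb.alpha_trans.sum(axis=1, keepdims=True)
    initial = vb.alpha_init / vb.alpha_init.sum()
    return HMMPosterior(
        means=means,
        covariances=covs,
        transition=transition,
        initial=initial,
        free_energy_trace=trace,
        gamma=gamma,
    )


def _gaussian_loglik(post: HMMPosterior, Y: np.ndarray) -> np.ndarray:
    """T x K log-likelihood under the posterior means/covariances."""
    d, T = Y.shape
    ll = np.empty((T, post.K))
    for k in range(post.K):
        L = cholesky(post.covariances[k], lower=True)
        diff = Y - post.means[k][:, None]
        X = solve_triangular(L, diff, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        ll[:, k] = -0.5 * (
            (X * X).sum(axis=0) + logdet + d * np.log(2.0 * np.pi)
        )
    return ll


def viterbi_decode(post: HMMPosterior, data: SensorDataset) -> StateSequence:
    """Most probable joint state path (MAP sequence) given the fitted model.

    Deterministic; exact likelihood ties resolve to the lowest state index.
    """
    Y = data.data
    if Y.shape[0] != post.n_channels:
        raise ValueError(
            f"channel dimension mismatch: posterior has {post.n_channels}, "
            f"data has {Y.shape[0]}"
        )
    ll = _gaussian_loglik(post, Y)
    T, K = ll.shape
    with np.errstate(divide="ignore"):
        logA = np.log(post.transition)
        log_init = np.log(post.initial)
    delta = log_init + ll[0]
    back = np.empty((T, K), dtype=np.int32)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)  # ties -> lowest index
        delta = cand[back[t], np.arange(K)] + ll[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return StateSequence(labels=path + 1, K=K, fs=data.fs)


def sample_hmm(
    params: HMMPosterior,
    T: int,
    seed: int,
    fs: float = 1.0,
) -> tuple[StateSequence, np.ndarray]:
    """Sample a state path and observations from generating HMM parameters.

    Returns ``(states, data)`` with ``data`` of shape (N, T).  Reproducible
    for a given seed.
    """
    trans = np.asarray(params.transition, float)
    if trans.ndim != 2 or trans.shape[0] != trans.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(trans < 0) or not np.allclose(trans.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix must be row-stochastic")
    K = trans.shape[0]
    init = np.asarray(params.initial, float)
    init = init / init.sum()
    rng = np.random.default_rng(seed)
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(K, p=init)
    cum = trans.cumsum(axis=1)
    u = rng.random(T - 1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    N = params.means.shape[1]
    chols = [cholesky(params.covariances[k], lower=True) for k in range(K)]
    Z = rng.standard_normal((N, T))
    Y = np.empty((N, T))
    for k in range(K):
        idx = states == k
        Y[:, idx] = params.means[k][:, None] + chols[k] @ Z[:, idx]
    return StateSequence(labels=states + 1, K=K, fs=fs), Y


def merge_rare_states(u: StateSequence, min_samples: int) -> StateSequence:
    """Absorb states with fewer than ``min_samples`` samples into their
    temporal context and renumber the remaining labels compactly.

    Samples of a rare (or absent) state are forward-filled with the previous
    surviving state's label (backward-filled at the start).  Needed before
    state-pooled covariance estimation, which requires every state to hold
    more samples than the data dimension.  Merges are logged.
    """
    labels = u.labels.copy()
    counts = np.bincount(labels - 1, minlength=u.K)
    rare = np.flatnonzero(counts < min_samples) + 1
    keep = np.flatnonzero(counts >= min_samples) + 1
    if keep.size == 0:
        raise ValueError("no state reaches the minimum occupancy")
    if rare.size:
        logger.info(
            "merging %d under-occupied state(s) %s (min_samples=%d)",
            rare.size,
            rare.tolist(),
            min_samples,
        )
        bad = np.isin(labels, rare)
        idx = np.where(~bad, np.arange(labels.size), -1)
        np.maximum.accumulate(idx, out=idx)
        first_good = int(np.argmax(~bad))
        labels = np.where(idx >= 0, labels[np.maximum(idx, 0)], labels[first_good])
    remap = {int(old): i + 1 for i, old in enumerate(np.unique(labels))}
    labels = np.vectorize(remap.get)(labels)
    return StateSequence(labels=labels, K=len(remap), fs=u.fs)


def select_model_order(
    data: SensorDataset,
    K_candidates: list[int],
    min_occupancy_s: float,
    cfg: HMMConfig,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Choose the state count by the minimum-occupancy rule.

    Fits each candidate K, decodes the MAP path, and keeps the largest K
    whose least-occupied state still accumulates at least ``min_occupancy_s``
    seconds.  Returns ``(chosen_K, free_energies, min_occupancies_s)`` with
    the arrays ordered like ``K_candidates``.  If no candidate qualifies the
    candidate with the largest minimum occupancy is returned with a warning.
    """
    from .state_stats import summarize_states

    if not K_candidates:
        raise ValueError("K_candidates must be nonempty")
    if any(K < 1 for K in K_candidates):
        raise ValueError("all K candidates must be >= 1")
    free_energies = np.empty(len(K_candidates))
    min_occ = np.empty(len(K_candidates))
    for i, K in enumerate(K_candidates):
        cfg_k = HMMConfig(
            K=K,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            n_restarts=cfg.n_restarts,
            prior_strength=cfg.prior_strength,
            seed=cfg.seed,
        )
        post = fit_hmm(data, cfg_k)
        u = viterbi_decode(post, data)
        summ = summarize_states(u)
        free_energies[i] = post.free_energy
        min_occ[i] = summ.occupancy_s.min()
    ok = [i for i in range(len(K_candidates)) if min_occ[i] >= min_occupancy_s]
    if ok:
        chosen = max(ok, key=lambda i: K_candidates[i])
    else:
        chosen = int(np.argmax(min_occ))
        warnings.warn(
            f"no candidate K reaches min occupancy {min_occupancy_s} s; "
            f"returning K={K_candidates[chosen]} with the largest minimum "
            f"occupancy {min_occ[chosen]:.3g} s",
            RuntimeWarning,
            stacklevel=2,
        )
    return K_candidates[chosen], free_energies, min_occ
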