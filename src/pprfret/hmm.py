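"""Bayesian hidden-Markov state finding on FRET trajectories.

Variational-Bayes inference for a Gaussian-emission HMM with Dirichlet
priors on the initial/transition probabilities and a Normal-Gamma prior on
each state's (mean, precision). The number of states is selected by the
variational evidence (ELBO) over a candidate range with multiple restarts,
which lets genuinely one-state trajectories stay one-state instead of
absorbing noise into spurious extra states.

The emission-prior hyperparameters follow the convention of the vbFRET-style
analysis: the prior mean is fixed at 0.5 FRET, ``mu`` is the pseudo-count
strength with which state means are pulled toward it, and ``beta`` scales
the Gamma rate of the precision prior (larger values favour broader states,
both discouraging over-fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from ._hmmcore import forward_backward, viterbi
from .io import FRETTrajectory

__all__ = ["HMMPriors", "HMMFit", "fit_hmm", "decode_posteriors"]

_LN2PI = np.log(2.0 * np.pi)


@dataclass
class HMMPriors:
    """Hyperparameters of the variational HMM.

    mu   : pseudo-count strength of the emission prior mean (Normal-Gamma
           beta0); default 1.5
    beta : precision-prior scale multiplier; default 0.5
    transition_concentration : Dirichlet concentration of transition rows
    k_range  : candidate state counts
    restarts : independent initializations per state count
    prior_mean : emission prior mean (FRET)
    precision_shape : Gamma shape a0 of the precision prior
    noise_scale : FRET noise scale sigma0 anchoring the precision prior
                  (Gamma rate b0 = beta * a0 * sigma0^2)
    """

    mu: float = 1.5
    beta: float = 0.5
    transition_concentration: float = 1.0
    k_range: tuple = (1, 2, 3, 4)
    restarts: int = 5
    prior_mean: float = 0.5
    precision_shape: float = 2.5
    noise_scale: float = 0.1
    max_iter: int = 300
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.mu <= 0:
            raise ValueError("mu and beta must be > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if len(self.k_range) == 0:
            raise ValueError("k_range must be non-empty")

    @property
    def beta0(self) -> float:
        return self.mu

    @property
    def a0(self) -> float:
        return self.precision_shape

    @property
    def b0(self) -> float:
        return self.beta * self.precision_shape * self.noise_scale**2


@dataclass
class _Posterior:
    """Variational posterior parameters (one Gaussian state per row)."""

    w_pi: np.ndarray  # Dirichlet over initial state
    w_a: np.ndarray  # Dirichlet rows over transitions
    m: np.ndarray  # Normal-Gamma mean
    beta_k: np.ndarray  # Normal-Gamma pseudo-counts
    a: np.ndarray  # Gamma shape
    b: np.ndarray  # Gamma rate

    def permuted(self, order: np.ndarray) -> "_Posterior":
        return _Posterior(
            w_pi=self.w_pi[order],
            w_a=self.w_a[np.ix_(order, order)],
            m=self.m[order],
            beta_k=self.beta_k[order],
            a=self.a[order],
            b=self.b[order],
        )


@dataclass
class HMMFit:
    """Selected model: state count, emission moments, transitions, path."""

    k: int
    state_means: np.ndarray
    state_sds: np.ndarray
    transition_matrix: np.ndarray  # posterior-mean per-frame probabilities
    path: np.ndarray
    evidence: float
    molecule_id: str = ""
    frame_interval: float = float("nan")
    imaging_lifetime: float = float("nan")
    censored: bool = False
    converged: bool = True
    elbo_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    posterior: _Posterior | None = None

    @property
    def idealized(self) -> np.ndarray:
        return self.state_means[self.path]

    def __len__(self) -> int:
        return len(self.path)


def _expected_log_params(post: _Posterior, y: np.ndarray):
    """Subnormalized parameters for the E-step / decoding."""
    elog_pi = digamma(post.w_pi) - digamma(post.w_pi.sum())
    elog_a = digamma(post.w_a) - digamma(post.w_a.sum(axis=1))[:, None]
    elog_b = 0.5 * (
        digamma(post.a)
        - np.log(post.b)
        - _LN2PI
        - 1.0 / post.beta_k
        - (post.a / post.b) * (y[:, None] - post.m[None, :]) ** 2
    )
    return np.exp(elog_pi), np.exp(elog_a), elog_b


def _kl_dirichlet(w: np.ndarray, u: np.ndarray) -> float:
    w = np.atleast_1d(w)
    u = np.atleast_1d(u)
    sw = w.sum()
    return float(
        gammaln(sw)
        - gammaln(w).sum()
        - gammaln(u.sum())
        + gammaln(u).sum()
        + ((w - u) * (digamma(w) - digamma(sw))).sum()
    )


def _kl_normal_gamma(post: _Posterior, pri: HMMPriors) -> float:
    m0, b0k, a0, b0 = pri.prior_mean, pri.beta0, pri.a0, pri.b0
    m, bk, a, b = post.m, post.beta_k, post.a, post.b
    kl_gamma = (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )
    kl_norm = 0.5 * (np.log(bk / b0k) + b0k / bk - 1.0 + b0k * (a / b) * (m - m0) ** 2)
    return float((kl_gamma + kl_norm).sum())


def _kl_total(post: _Posterior, pri: HMMPriors, k: int) -> float:
    u_pi = np.ones(k)
    u_a = np.full((k, k), pri.transition_concentration)
    kl = _kl_dirichlet(post.w_pi, u_pi)
    for j in range(k):
        kl += _kl_dirichlet(post.w_a[j], u_a[j])
    return kl + _kl_normal_gamma(post, pri)


def _init_posterior(y: np.ndarray, k: int, pri: HMMPriors, rng) -> _Posterior:
    n = len(y)
    qs = np.quantile(y, (np.arange(k) + 0.5) / k)
    spread = max(float(y.max() - y.min()), 1e-3)
    jitter = rng.normal(0.0, 0.05 * spread, k) if rng is not None else np.zeros(k)
    m = np.sort(qs + jitter)
    var0 = max(float(np.var(y)) / max(k, 1), 1e-6)
    a = np.full(k, pri.a0 + n / (2.0 * k))
    b = a * var0
    beta_k = np.full(k, pri.beta0 + n / k)
    w_pi = np.ones(k)
    w_a = np.full((k, k), pri.transition_concentration) + (n / k) * (
        0.8 * np.eye(k) + 0.2 / k
    )
    return _Posterior(w_pi=w_pi, w_a=w_a, m=m, beta_k=beta_k, a=a, b=b)


def _vb_iterate(y: np.ndarray, post: _Posterior, pri: HMMPriors, k: int):
    """Run VBEM to convergence; returns (posterior, elbo_trace, converged)."""
    u_pi = np.ones(k)
    u_a = np.full((k, k), pri.transition_concentration)
    elbos = []
    converged = False
    for _ in range(pri.max_iter):
        tpi, ta, logb = _expected_log_params(post, y)
        gamma, xi_sum, lnz = forward_backward(tpi, ta, logb)
        elbo = lnz - _kl_total(post, pri, k)
        elbos.append(elbo)
        if len(elbos) > 1 and abs(elbos[-1] - elbos[-2]) < pri.tol * (1 + abs(elbos[-1])):
            converged = True
            break
        nk = gamma.sum(axis=0)
        safe = np.maximum(nk, 1e-12)
        ybar = (gamma * y[:, None]).sum(axis=0) / safe
        sk = (gamma * (y[:, None] - ybar[None, :]) ** 2).sum(axis=0)
        post = _Posterior(
            w_pi=u_pi + gamma[0],
            w_a=u_a + xi_sum,
            m=(pri.beta0 * pri.prior_mean + nk * ybar) / (pri.beta0 + nk),
            beta_k=pri.beta0 + nk,
            a=pri.a0 + nk / 2.0,
            b=pri.b0
            + 0.5 * sk
            + 0.5 * pri.beta0 * nk * (ybar - pri.prior_mean) ** 2 / (pri.beta0 + nk),
        )
    return post, np.array(elbos), converged


def _prepare_series(traj) -> np.ndarray:
    y = traj.fret if isinstance(traj, FRETTrajectory) else np.asarray(traj, dtype=float)
    y = np.asarray(y, dtype=float).copy()
    bad = ~np.isfinite(y)
    if bad.all():
        raise ValueError("no finite FRET values to fit")
    if bad.any():
        y[bad] = np.median(y[~bad])  # rare flagged frames; keep path aligned
    return y


def fit_hmm(traj, priors: HMMPriors | None = None, seed: int = 0) -> HMMFit:
    """Fit the variational HMM and select the state count by evidence.

    For each k in ``k_range`` and each restart, VBEM runs from a
    deterministic initialization derived from (seed, k, restart); the fit
    with the highest ELBO wins, ties broken toward smaller k. States are
    reported sorted by ascending FRET mean and the path is the most probable
    (Viterbi) decoding under the expected-log parameters.
    """
    priors = priors or HMMPriors()
    y = _prepare_series(traj)
    if len(y) < 10:
        raise ValueError("trajectory too short to fit (need >= 10 frames)")

    best = None
    for k in sorted(priors.k_range):
        for r in range(priors.restarts):
            rng = (
                None
                if r == 0
                else np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, k, r]))
            )
            post0 = _init_posterior(y, k, priors, rng)
            post, elbos, conv = _vb_iterate(y, post0, priors, k)
            if best is None or elbos[-1] > best[1][-1] + 1e-9:
                best = (k, elbos, post, conv)

    k, elbos, post, conv = best
    order = np.argsort(post.m)
    post = post.permuted(order)
    tpi, ta, logb = _expected_log_params(post, y)
    path = np.asarray(viterbi(tpi, ta, logb))
    means = post.m.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        sds = np.sqrt(post.b / np.maximum(post.a - 1.0, 1e-9))
    trans = post.w_a / post.w_a.sum(axis=1, keepdims=True)

    mol = getattr(traj, "molecule_id", "")
    dt = getattr(traj, "frame_interval", float("nan"))
    lifetime = getattr(traj, "imaging_lifetime", float("nan"))
    censored = getattr(traj, "censored", False)
    return HMMFit(
        k=int(k),
        state_means=means,
        state_sds=sds,
        transition_matrix=trans,
        path=path,
        evidence=float(elbos[-1]),
        molecule_id=mol,
        frame_interval=dt,
        imaging_lifetime=lifetime,
        censored=censored,
        converged=bool(conv),
        elbo_trace=elbos,
        posterior=post,
    )


def decode_posteriors(fit: HMMFit, traj) -> np.ndarray:
    """Per-frame state probabilities (forward-backward) under the fit.

    Rows sum to 1 within 1e-9; the trajectory must be the one the fit was
    produced from (lengths must match).
    """
    y = _prepare_series(traj)
    if len(y) != len(fit.path):
        raise ValueError("trajectory length does not match the fit")
    if fit.posterior is None:
        raise ValueError("fit carries no posterior parameters")
    tpi, ta, logb = _expected_log_params(fit.posterior, y)
    gamma, _, _ = forward_backward(tpi, ta, logb)
    return np.asarray(gamma)
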