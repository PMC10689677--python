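"""Bayesian sampling: adaptive Metropolis and parallel tempering.

The base kernel is random-walk Metropolis whose proposal covariance tracks
the chain's empirical covariance (stochastic-approximation update with decay
``(t+1)^-delta``) and whose global scale is tuned toward a target acceptance
rate of 0.234. Parallel tempering runs coupled chains at inverse
temperatures ``1 = beta_1 > ... > beta_K > 0`` targeting ``exp(-beta *
Lambda)`` with ``Lambda`` the negative log posterior; adjacent chains
exchange states on a fixed alternating even/odd schedule, and the
temperature ladder can adapt in log-gap space to equalize swap acceptance
rates. Burn-in (Geweke z-scores) and autocorrelation-based effective sample
size diagnostics are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from statsmodels.tsa.stattools import acovf

from .problem import Problem

DEFAULT_SAMPLE_OPTIONS = {
    "alpha_target": 0.234,   # target acceptance rate
    "decay": 0.51,           # adaptation decay exponent, in (0.5, 1]
    "eps": 1e-10,            # covariance regularization
    "adapt_until": None,     # freeze adaptation after this iteration
}

DEFAULT_PT_OPTIONS = {
    **DEFAULT_SAMPLE_OPTIONS,
    "swap_every": 10,
    "beta_ratio": 0.25,      # geometric initial ladder
    "adapt_ladder": True,
    "ladder_kappa0": 1.0,
    "ladder_t0": 1000.0,
    "ladder_ewma": 0.95,     # memory of the per-pair acceptance estimate
}


@dataclass
class McmcTrace:
    """Single-chain history with final adaptation state."""

    states: np.ndarray             # (n_iter, dim)
    neg_log_posterior: np.ndarray  # (n_iter,)
    acceptance: np.ndarray         # (n_iter,) bool
    mu: np.ndarray
    Sigma: np.ndarray
    log_scale: float
    seed: int
    beta: float = 1.0
    parameter_ids: list = field(default_factory=list)

    @property
    def n_iter(self) -> int:
        return len(self.neg_log_posterior)

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.acceptance))


@dataclass
class PTTrace:
    """Per-temperature traces; the beta=1 chain (index 0) is the posterior
    sample."""

    traces: list
    betas: np.ndarray
    betas_init: np.ndarray
    swap_accept_counts: np.ndarray
    swap_attempt_counts: np.ndarray
    seed: int

    @property
    def posterior(self) -> McmcTrace:
        return self.traces[0]

    @property
    def swap_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.swap_accept_counts / np.maximum(
                self.swap_attempt_counts, 1
            )


def _nlp_callable(target) -> Callable:
    """Accept a plain callable, an objective, or a Problem."""
    if isinstance(target, Problem):
        problem = target
        return lambda x: problem.objective_free(x).fval
    if hasattr(target, "capabilities"):
        return lambda x: target(x).fval
    return target


def metropolis_step(x, nlp_x, proposal_cov, scale, target, rng,
                    lb=None, ub=None, beta: float = 1.0):
    """One random-walk Metropolis step: propose ``x + scale * L z`` with
    ``L`` the Cholesky factor of the proposal covariance, accept with
    probability ``min(1, exp(beta * (nlp_x - nlp_proposal)))``. Proposals
    outside bounds and non-finite values are rejected. Returns
    ``(x', nlp', accepted, acceptance_probability)``."""
    nlp_fn = _nlp_callable(target)
    x = np.asarray(x, dtype=float)
    L = np.linalg.cholesky(proposal_cov)
    z = rng.standard_normal(x.size)
    y = x + scale * (L @ z)
    u = rng.uniform()
    in_bounds = (lb is None or np.all(y >= lb)) and (
        ub is None or np.all(y <= ub)
    )
    if not in_bounds:
        return x, nlp_x, False, 0.0
    nlp_y = float(nlp_fn(y))
    if not np.isfinite(nlp_y):
        return x, nlp_x, False, 0.0
    alpha = float(min(1.0, np.exp(min(0.0, beta * (nlp_x - nlp_y)))))
    if u < alpha:
        return y, nlp_y, True, alpha
    return x, nlp_x, False, alpha


def adapt(mu, Sigma, log_scale, x_t, accepted_prob, t, options=None):
    """Stochastic-approximation update of the proposal: with
    ``gamma_t = (t+1)^-decay``, shift the running mean toward ``x_t``, the
    running covariance toward the recentred outer product (plus ``eps * I``
    regularization), and the log scale by ``gamma_t * (alpha -
    alpha_target)``."""
    opts = {**DEFAULT_SAMPLE_OPTIONS, **(options or {})}
    gamma = (t + 1.0) ** (-opts["decay"])
    mu = np.asarray(mu, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    mu_new = mu + gamma * (x_t - mu)
    dx = (x_t - mu_new)[:, None]
    Sigma_new = Sigma + gamma * (dx @ dx.T - Sigma) + opts["eps"] * np.eye(
        mu.size
    )
    log_scale_new = log_scale + gamma * (accepted_prob - opts["alpha_target"])
    return mu_new, Sigma_new, float(log_scale_new)


class _ChainState:
    """Mutable per-chain sampler state (position + adaptation)."""

    __slots__ = ("x", "lam", "mu", "Sigma", "log_scale")

    def __init__(self, x, lam, mu, Sigma, log_scale):
        self.x = x
        self.lam = lam          # unscaled negative log posterior Lambda
        self.mu = mu
        self.Sigma = Sigma
        self.log_scale = log_scale


def _init_sigma(lb, ub) -> np.ndarray:
    rng_width = np.where(
        np.isfinite(ub - lb), ub - lb, 20.0
    )
    return np.diag((rng_width / 20.0) ** 2)


def _chain_iteration(state: _ChainState, beta, nlp_fn, lb, ub, rng, opts, t):
    """One Metropolis + adaptation update; returns acceptance flag."""
    x_new, lam_new, accepted, alpha = metropolis_step(
        state.x, state.lam, state.Sigma, np.exp(state.log_scale),
        nlp_fn, rng, lb=lb, ub=ub, beta=beta,
    )
    state.x, state.lam = x_new, lam_new
    adapt_until = opts["adapt_until"]
    if adapt_until is None or t < adapt_until:
        state.mu, state.Sigma, state.log_scale = adapt(
            state.mu, state.Sigma, state.log_scale, x_new, alpha, t, opts
        )
    return accepted


def sample_adaptive_metropolis(problem: Problem, x0=None, n_iter: int = 1000,
                               options: Optional[dict] = None,
                               seed: int = 0) -> McmcTrace:
    """Adaptive Metropolis on the free parameter space (estimation scale).
    Deterministic given ``seed``; adaptation can be frozen via the
    ``adapt_until`` option."""
    opts = {**DEFAULT_SAMPLE_OPTIONS, **(options or {})}
    lb, ub = problem.lb_free, problem.ub_free
    if x0 is None:
        x0 = np.clip(problem.nominal_est_free(), lb, ub)
    x0 = np.asarray(x0, dtype=float)
    nlp_fn = _nlp_callable(problem)
    lam0 = float(nlp_fn(x0))
    if not np.isfinite(lam0):
        raise ValueError("objective non-finite at the sampler start point")
    rng = np.random.default_rng(seed)
    state = _ChainState(
        x=x0.copy(), lam=lam0, mu=x0.copy(), Sigma=_init_sigma(lb, ub),
        log_scale=0.0,
    )
    d = x0.size
    states = np.empty((n_iter, d))
    nlps = np.empty(n_iter)
    accepts = np.empty(n_iter, dtype=bool)
    for t in range(n_iter):
        accepts[t] = _chain_iteration(
            state, 1.0, nlp_fn, lb, ub, rng, opts, t
        )
        states[t] = state.x
        nlps[t] = state.lam
    return McmcTrace(
        states=states, neg_log_posterior=nlps, acceptance=accepts,
        mu=state.mu, Sigma=state.Sigma, log_scale=state.log_scale,
        seed=seed, parameter_ids=problem.free_ids,
    )


def geometric_ladder(n_chains: int, beta_ratio: float = 0.25) -> np.ndarray:
    """Initial inverse-temperature ladder ``beta_k = ratio**(k-1)``; the
    coldest chain is pinned at beta=1 and all chains stay informative
    (beta > 0)."""
    return beta_ratio ** np.arange(n_chains, dtype=float)


def swap_step(states: Sequence, nlps: Sequence, betas, rng, parity: int = 0):
    """Attempt exchanges between adjacent pairs ``(i, i+1)`` with
    ``i % 2 == parity``, accepting with probability
    ``min(1, exp((beta_i - beta_{i+1}) * (Lambda_i - Lambda_{i+1})))``.
    Returns updated states/nlps and per-pair (accepted, attempted) flags."""
    betas = np.asarray(betas, dtype=float)
    K = len(betas)
    states = list(states)
    nlps = list(nlps)
    accepted = np.zeros(K - 1, dtype=bool)
    attempted = np.zeros(K - 1, dtype=bool)
    for i in range(parity % 2, K - 1, 2):
        attempted[i] = True
        u = rng.uniform()
        log_p = (betas[i] - betas[i + 1]) * (nlps[i] - nlps[i + 1])
        if np.log(u) < min(0.0, log_p):
            states[i], states[i + 1] = states[i + 1], states[i]
            nlps[i], nlps[i + 1] = nlps[i + 1], nlps[i]
            accepted[i] = True
    return states, nlps, accepted, attempted


def swap_acceptance_probability(beta_i, beta_j, lam_i, lam_j) -> float:
    """Closed-form adjacent-pair swap acceptance probability."""
    return float(min(1.0, np.exp((beta_i - beta_j) * (lam_i - lam_j))))


def adapt_ladder(betas, swap_accept_rates, t, options=None) -> np.ndarray:
    """Adapt the temperature ladder in log-gap space: with
    ``S_i = log(1/beta_{i+1} - 1/beta_i)`` and decaying gain
    ``kappa(t) = kappa0 / (t/t0 + 1)``, update
    ``S_i += kappa(t) * (A_i - A_{i+1})`` so neighboring swap rates
    equalize; beta_1 stays pinned at 1 and monotonicity is preserved by
    construction."""
    opts = {**DEFAULT_PT_OPTIONS, **(options or {})}
    betas = np.asarray(betas, dtype=float)
    K = betas.size
    if K < 3:
        raise ValueError("ladder adaptation needs K >= 3 chains")
    A = np.asarray(swap_accept_rates, dtype=float)
    T = 1.0 / betas
    S = np.log(np.diff(T))
    kappa = opts["ladder_kappa0"] / (t / opts["ladder_t0"] + 1.0)
    for i in range(K - 2):
        S[i] += kappa * (A[i] - A[i + 1])
    T_new = np.concatenate([[1.0], 1.0 + np.cumsum(np.exp(S))])
    return 1.0 / T_new


def sample_parallel_tempering(problem: Problem, x0=None, n_chains: int = 5,
                              n_iter: int = 1000,
                              options: Optional[dict] = None,
                              seed: int = 0) -> PTTrace:
    """Parallel tempering: per-temperature adaptive-Metropolis updates plus
    adjacent-pair swaps every ``swap_every`` iterations on an alternating
    even/odd schedule. With a single chain this reduces exactly to adaptive
    Metropolis (same seed, same trace)."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    opts = {**DEFAULT_PT_OPTIONS, **(options or {})}
    lb, ub = problem.lb_free, problem.ub_free
    if x0 is None:
        x0 = np.clip(problem.nominal_est_free(), lb, ub)
    x0 = np.asarray(x0, dtype=float)
    nlp_fn = _nlp_callable(problem)
    lam0 = float(nlp_fn(x0))
    if not np.isfinite(lam0):
        raise ValueError("objective non-finite at the sampler start point")
    rng = np.random.default_rng(seed)
    betas = geometric_ladder(n_chains, opts["beta_ratio"])
    betas_init = betas.copy()
    chains = [
        _ChainState(x=x0.copy(), lam=lam0, mu=x0.copy(),
                    Sigma=_init_sigma(lb, ub), log_scale=0.0)
        for _ in range(n_chains)
    ]
    d = x0.size
    states = np.empty((n_chains, n_iter, d))
    nlps = np.empty((n_chains, n_iter))
    accepts = np.empty((n_chains, n_iter), dtype=bool)
    swap_accept = np.zeros(max(n_chains - 1, 0), dtype=int)
    swap_attempt = np.zeros(max(n_chains - 1, 0), dtype=int)
    pair_rate = np.zeros(max(n_chains - 1, 0))
    swap_every = int(opts["swap_every"])
    ewma = opts["ladder_ewma"]
    swap_round = 0
    for t in range(n_iter):
        for k in range(n_chains):
            accepts[k, t] = _chain_iteration(
                chains[k], betas[k], nlp_fn, lb, ub, rng, opts, t
            )
        if n_chains > 1 and (t + 1) % swap_every == 0:
            xs = [c.x for c in chains]
            ls = [c.lam for c in chains]
            xs, ls, acc, att = swap_step(xs, ls, betas, rng,
                                         parity=swap_round % 2)
            for k, c in enumerate(chains):
                c.x, c.lam = xs[k], ls[k]
            swap_accept += acc.astype(int)
            swap_attempt += att.astype(int)
            pair_rate[att] = ewma * pair_rate[att] + (1 - ewma) * acc[att]
            if opts["adapt_ladder"] and n_chains >= 3:
                betas = adapt_ladder(betas, pair_rate, swap_round, opts)
            swap_round += 1
        for k in range(n_chains):
            states[k, t] = chains[k].x
            nlps[k, t] = chains[k].lam
    traces = [
        McmcTrace(
            states=states[k], neg_log_posterior=nlps[k],
            acceptance=accepts[k], mu=chains[k].mu, Sigma=chains[k].Sigma,
            log_scale=chains[k].log_scale, seed=seed, beta=float(betas[k]),
            parameter_ids=problem.free_ids,
        )
        for k in range(n_chains)
    ]
    return PTTrace(
        traces=traces, betas=betas, betas_init=betas_init,
        swap_accept_counts=swap_accept, swap_attempt_counts=swap_attempt,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _states(trace) -> np.ndarray:
    x = trace.states if isinstance(trace, McmcTrace) else np.asarray(trace)
    return x[:, None] if x.ndim == 1 else x


def _spectral0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via the initial positive sequence
    of autocovariances."""
    c = acovf(x, fft=True, demean=True)
    s = c[0]
    for k in range(1, len(c)):
        if c[k] <= 0:
            break
        s += 2 * c[k]
    return float(max(s, 0.0))


def geweke_z_scores(x: np.ndarray, first: float = 0.1,
                    last: float = 0.5) -> np.ndarray:
    """Per-parameter Geweke z-scores comparing the means of the first and
    last chain segments with spectral variance estimates."""
    x = _states(x)
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    z = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        va = _spectral0(a[:, j]) / len(a)
        vb = _spectral0(b[:, j]) / len(b)
        denom = np.sqrt(va + vb)
        diff = a[:, j].mean() - b[:, j].mean()
        z[j] = 0.0 if denom == 0 else diff / denom
    return z


BURN_IN_FRACTIONS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def geweke_burn_in(trace, return_diagnostics: bool = False):
    """Smallest checkpoint (fractions 0, 0.1, ..., 0.5 of the chain
    discarded) at which all per-parameter Geweke z-scores of the retained
    chain fall below 2; the full length if none qualifies. A zero-variance
    chain is degenerate and reports burn-in 0."""
    x = _states(trace)
    n = len(x)
    if n < 100:
        raise ValueError("burn-in diagnostic needs at least 100 iterations")
    if np.all(x.std(axis=0) == 0):
        result, diag = 0, {"degenerate": True, "z": np.zeros(x.shape[1])}
        return (result, diag) if return_diagnostics else result
    for frac in BURN_IN_FRACTIONS:
        start = int(frac * n)
        z = geweke_z_scores(x[start:])
        if np.all(np.abs(z) < 2.0):
            diag = {"degenerate": False, "z": z, "fraction": frac}
            return (start, diag) if return_diagnostics else start
    diag = {"degenerate": False, "z": z, "fraction": None}
    return (n, diag) if return_diagnostics else n


def effective_sample_size(trace, burn_in: int = 0) -> float:
    """Autocorrelation-discounted sample count ``n / (1 + 2 sum rho_k)``
    with the initial-positive-sequence truncation, per parameter; the
    minimum over parameters is reported."""
    x = _states(trace)[burn_in:]
    n = len(x)
    if n < 10:
        raise ValueError("effective sample size needs at least 10 samples")
    ess = []
    for j in range(x.shape[1]):
        c = acovf(x[:, j], fft=True, demean=True)
        if c[0] == 0:
            ess.append(float(n))
            continue
        tau = 1.0
        for k in range(1, len(c)):
            rho = c[k] / c[0]
            if rho <= 0:
                break
            tau += 2 * rho
        ess.append(n / tau)
    return float(min(ess))
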