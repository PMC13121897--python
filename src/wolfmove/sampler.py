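"""Hamiltonian Monte Carlo with dual-averaging step-size adaptation.

A compact, dependency-free sampler for the smooth, moderate-dimension
posteriors of this package's hierarchical regressions (a few hundred
parameters once random-effect levels are counted, with non-centered
parameterization).  Warmup adapts the leapfrog step size to a target
acceptance rate and estimates a diagonal mass matrix from an adaptation
window; sampling uses a jittered number of leapfrog steps to avoid resonance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    step_size: float
    n_divergent: int


def _find_initial_step(logp_grad: LogpGrad, theta: np.ndarray, inv_mass: np.ndarray, rng) -> float:
    """Heuristic initial step size: double/halve until the one-step
    acceptance probability crosses 0.5 (Hoffman & Gelman's heuristic)."""
    eps = 0.1
    lp0, g0 = logp_grad(theta)
    p0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)

    def one_step(e):
        p = p0 + 0.5 * e * g0
        th = theta + e * inv_mass * p
        lp, g = logp_grad(th)
        p = p + 0.5 * e * g
        h0 = lp0 - 0.5 * np.sum(inv_mass * p0**2)
        h1 = lp - 0.5 * np.sum(inv_mass * p**2)
        return h1 - h0

    dh = one_step(eps)
    if not np.isfinite(dh):
        dh = -np.inf
    direction = 1.0 if dh > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        dh = one_step(eps)
        if not np.isfinite(dh):
            dh = -np.inf
        if direction == 1.0 and dh <= np.log(0.5):
            break
        if direction == -1.0 and dh >= np.log(0.5):
            break
    return eps


def hmc_chain(
    logp_grad: LogpGrad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.85,
    max_leapfrog: int = 64,
    integration_time: float = 1.8,
) -> HMCResult:
    """Run one HMC chain; returns post-warmup draws."""
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    inv_mass = np.ones(dim)

    np_err = np.seterr(over="ignore", invalid="ignore", divide="ignore")
    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass adaptation window inside warmup
    win_lo, win_hi = int(0.25 * n_warmup), int(0.8 * n_warmup)
    window_draws: list[np.ndarray] = []

    lp, grad = logp_grad(theta)
    draws = np.empty((n_draws, dim))
    n_accept = 0
    n_div = 0
    total = n_warmup + n_draws
    adapt_count = 0
    for it in range(total):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p**2)
        n_leap = max(1, min(max_leapfrog, int(np.ceil(integration_time / max(eps, 1e-6)))))
        n_leap = int(rng.integers(max(1, n_leap // 2), n_leap + 1))
        th_new, p_new, lp_new, g_new = theta, p.copy(), lp, grad
        diverged = False
        p_new = p_new + 0.5 * eps * g_new
        for step in range(n_leap):
            th_new = th_new + eps * inv_mass * p_new
            lp_new, g_new = logp_grad(th_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            if step < n_leap - 1:
                p_new = p_new + eps * g_new
        if not diverged:
            p_new = p_new + 0.5 * eps * g_new
            h1 = lp_new - 0.5 * np.sum(inv_mass * p_new**2)
            delta_h = h1 - h0
            if delta_h < -1000.0:
                diverged = True
        if diverged:
            accept_prob = 0.0
            n_div += it >= n_warmup
        else:
            accept_prob = min(1.0, np.exp(min(0.0, delta_h)))
            if rng.random() < accept_prob:
                theta, lp, grad = th_new, lp_new, g_new
        if it < n_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if win_lo <= it < win_hi:
                window_draws.append(theta.copy())
            if it == win_hi and len(window_draws) > 10:
                var = np.var(np.asarray(window_draws), axis=0)
                # regularized estimate (shrunk toward unit scale) so a
                # poorly mixed window cannot produce a degenerate metric
                n_w = len(window_draws)
                w = n_w / (n_w + 5.0)
                var = w * var + (1.0 - w) * np.ones(dim)
                inv_mass = np.clip(var, 1e-4, 1e4)
                # restart step-size adaptation for the new metric
                eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = theta
            n_accept += accept_prob
    np.seterr(**np_err)
    return HMCResult(
        draws=draws,
        accept_rate=n_accept / max(1, n_draws),
        step_size=eps,
        n_divergent=n_div,
    )


def sample_posterior(
    logp_grad: LogpGrad,
    init: np.ndarray,
    n_chains: int = 2,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    target_accept: float = 0.85,
    jitter: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Run several chains from jittered inits; returns draws of shape
    (n_chains, n_draws, dim) plus sampler info."""
    rng = np.random.default_rng(seed)
    dim = init.size
    all_draws = np.empty((n_chains, n_draws, dim))
    info = {"accept_rates": [], "step_sizes": [], "n_divergent": 0}
    for c in range(n_chains):
        # a chain whose sampling-phase acceptance collapses (failed
        # adaptation) is discarded and rerun from a fresh start
        for attempt in range(3):
            theta0 = init + jitter * rng.standard_normal(dim)
            res = hmc_chain(
                logp_grad,
                theta0,
                n_warmup=n_warmup,
                n_draws=n_draws,
                seed=int(rng.integers(0, 2**31 - 1)),
                target_accept=target_accept,
            )
            if res.accept_rate >= 0.5:
                break
        all_draws[c] = res.draws
        info["accept_rates"].append(res.accept_rate)
        info["step_sizes"].append(res.step_size)
        info["n_divergent"] += res.n_divergent
    return all_draws, info
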