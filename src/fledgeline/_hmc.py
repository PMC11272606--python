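"""A compact Hamiltonian Monte Carlo sampler.

Leapfrog integration with dual-averaging step-size adaptation, one
diagonal mass-matrix adaptation window, and jittered trajectory lengths.
Warmup is the first half of each chain and is discarded; the second half
is retained, so ``chains`` x ``iterations`` yields exactly
``chains * iterations / 2`` posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCResult", "sample_hmc"]

_ACCEPT_TARGET = 0.8
_MAX_LEAPFROG = 64
_DIVERGENCE_ENERGY = 1000.0


@dataclass
class HMCResult:
    """Retained draws and sampler health counters for a set of chains."""

    draws: np.ndarray          # (chains, kept, dim)
    accept_rate: np.ndarray    # per chain, post-warmup
    divergences: np.ndarray    # per chain, post-warmup
    step_size: np.ndarray      # per chain, final adapted value


def _leapfrog(theta, p, grad, eps, n_steps, logp_grad, inv_mass):
    """Integrate Hamilton's equations; returns end state and end log-prob."""
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        theta = theta + eps * inv_mass * p
        lp, grad = logp_grad(theta)
        if not np.isfinite(lp):
            return theta, p, lp, grad
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return theta, p, lp, grad


def sample_hmc(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    iterations: int,
    rng: np.random.Generator,
    trajectory_length: float = 1.2,
) -> tuple[np.ndarray, dict]:
    """Run one HMC chain of ``iterations`` transitions; keep the second half.

    ``logp_grad`` returns the joint log density (up to a constant) and its
    gradient on the unconstrained scale.  The mass matrix is diagonal,
    re-estimated once from the middle of warmup; the step size is tuned by
    dual averaging to an 80% average acceptance.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    warmup = iterations // 2
    kept = iterations - warmup
    draws = np.empty((kept, dim))

    inv_mass = np.ones(dim)
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite log probability at the initial point")

    # dual averaging state (Hoffman & Gelman's schedule)
    eps = 0.1
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    # one mass window in the middle of warmup
    win_lo, win_hi = warmup // 4, (3 * warmup) // 4
    window: list[np.ndarray] = []

    n_accept = 0
    n_div = 0
    for it in range(iterations):
        sd = 1.0 / np.sqrt(inv_mass)
        p0 = rng.normal(size=dim) * sd
        h0 = -lp + 0.5 * np.sum(inv_mass * p0 * p0)

        jitter = rng.uniform(0.5, 1.5)
        n_steps = int(np.clip(np.ceil(trajectory_length * jitter / eps), 1, _MAX_LEAPFROG))
        theta_new, p_new, lp_new, grad_new = _leapfrog(
            theta, p0, grad, eps, n_steps, logp_grad, inv_mass
        )

        if np.isfinite(lp_new):
            h_new = -lp_new + 0.5 * np.sum(inv_mass * p_new * p_new)
            delta_h = h0 - h_new
            diverged = (not np.isfinite(delta_h)) or (-delta_h > _DIVERGENCE_ENERGY)
            accept_prob = 0.0 if diverged else float(np.exp(min(delta_h, 0.0)))
        else:
            diverged = True
            accept_prob = 0.0

        accepted = (not diverged) and (rng.uniform() < accept_prob)
        if accepted:
            theta, lp, grad = theta_new, lp_new, grad_new

        if it < warmup:
            # dual averaging update
            adapt_iter += 1
            eta = 1.0 / (adapt_iter + t0)
            h_bar = (1.0 - eta) * h_bar + eta * (_ACCEPT_TARGET - accept_prob)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            power = adapt_iter ** (-kappa)
            log_eps_bar = power * log_eps + (1.0 - power) * log_eps_bar
            eps = float(np.exp(log_eps))

            if win_lo <= it < win_hi:
                window.append(theta.copy())
            if it == win_hi - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                # regularize towards unit scale as Stan does
                n_w = len(window)
                inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-8)
                # restart step-size adaptation for the new metric
                eps = float(np.exp(log_eps_bar))
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            n_accept += accepted
            n_div += diverged
            draws[it - warmup] = theta

    info = {
        "accept_rate": n_accept / max(kept, 1),
        "divergences": int(n_div),
        "step_size": eps,
    }
    return draws, info


def sample_chains(
    logp_grad,
    init: Callable[[np.random.Generator], np.ndarray],
    chains: int,
    iterations: int,
    seed,
) -> HMCResult:
    """Run independent HMC chains from jittered starts; stack retained halves."""
    seqs = np.random.SeedSequence(seed).spawn(chains)
    all_draws, acc, div, steps = [], [], [], []
    for c in range(chains):
        rng = np.random.default_rng(seqs[c])
        draws, info = sample_hmc(logp_grad, init(rng), iterations, rng)
        all_draws.append(draws)
        acc.append(info["accept_rate"])
        div.append(info["divergences"])
        steps.append(info["step_size"])
    return HMCResult(
        draws=np.asarray(all_draws),
        accept_rate=np.asarray(acc),
        divergences=np.asarray(div),
        step_size=np.asarray(steps),
    )
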