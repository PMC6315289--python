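"""Minimal Hamiltonian Monte Carlo with dual-averaging step-size adaptation.

Self-contained gradient-based sampler used by the pseudotime model: static
(jittered-length) leapfrog trajectories, diagonal mass matrix estimated
during warmup, Nesterov dual averaging targeting a fixed acceptance rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCStats:
    accept_rate: float
    divergences: int
    step_size: float
    n_draws: int


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    eps: float,
    n_steps: int,
    inv_mass: np.ndarray,
    grad: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    p = p + 0.5 * eps * grad
    for i in range(n_steps):
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, -np.inf, grad
        p = p + (eps if i < n_steps - 1 else 0.5 * eps) * grad
    return x, p, lp, grad


def hmc_sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    base_leapfrog: int = 12,
    init_step_size: float = 0.1,
    divergence_threshold: float = 1000.0,
) -> tuple[np.ndarray, HMCStats]:
    """Draw from the target density; returns (draws, stats).

    Warmup schedule: dual averaging of the step size throughout; the diagonal
    mass matrix is re-estimated once from the middle warmup window, after
    which step-size adaptation restarts.
    """
    dim = x0.size
    x = np.array(x0, dtype=float)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    eps = float(init_step_size)
    # dual-averaging state (Hoffman & Gelman constants)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    mass_lo, mass_hi = int(0.4 * n_warmup), int(0.9 * n_warmup)
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_accept = 0
    divergences = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * np.sum(inv_mass * p0 * p0)
        n_steps = int(rng.integers(1, 2 * base_leapfrog + 1))
        x_new, p_new, lp_new, grad_new = _leapfrog(logp_grad, x, p0, eps, n_steps, inv_mass, grad)
        if np.isfinite(lp_new):
            h_new = -lp_new + 0.5 * np.sum(inv_mass * p_new * p_new)
            delta_h = h0 - h_new
        else:
            delta_h = -np.inf
        if delta_h < -divergence_threshold:
            if not warming:
                divergences += 1
            accept_prob = 0.0
        else:
            accept_prob = min(1.0, float(np.exp(min(delta_h, 0.0))))
        if rng.random() < accept_prob:
            x, lp, grad = x_new, lp_new, grad_new
            if not warming:
                n_accept += 1

        if warming:
            adapt_iter += 1
            h_bar = (1 - 1 / (adapt_iter + t0)) * h_bar + (target_accept - accept_prob) / (adapt_iter + t0)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            w = adapt_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if mass_lo <= it < mass_hi:
                window.append(x.copy())
            if it == mass_hi - 1 and len(window) >= 10:
                var = np.var(np.stack(window), axis=0)
                inv_mass = np.maximum(var, 1e-8)
                # restart step-size adaptation around the current value
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if adapt_iter > 0 else eps
        else:
            draws[it - n_warmup] = x

    stats = HMCStats(
        accept_rate=n_accept / max(n_draws, 1),
        divergences=divergences,
        step_size=eps,
        n_draws=n_draws,
    )
    return draws, stats


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a 1-D chain via Geyer's initial positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    # sum consecutive pairs while they stay positive
    s = 0.0
    for k in range(1, (n - 1) // 2):
        pair = acf[2 * k - 1] + acf[2 * k]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))
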