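"""Capture-time-anchored Gaussian-process pseudotime model.

Each cell's latent time tau_c gets a Normal(k_c, sigma_tau^2) prior around
its capture time k_c. Each (centered) gene expression vector is modelled as
a draw from a GP over tau with a shared squared-exponential length-scale l,
gene-specific amplitude psi_g and white noise omega_g:

    cov(y_gc, y_gc') = psi_g * exp(-(tau_c - tau_c')^2 / (2 l^2)) + omega_g * 1[c = c']

The joint posterior over (tau, psi, omega) is sampled by Hamiltonian Monte
Carlo. tau is non-centered (tau = k + sigma_tau * z) so the sigma_tau -> 0
limit degenerates cleanly to the capture times. Likelihood and gradients
are evaluated in the eigenbasis of the correlation matrix, making the cost
per gradient one N x N eigendecomposition plus O(G N^2) work.

The inferred ordering is validated by a permutation roughness test: the
root-mean-square successive difference of each gene's profile along the
ordering, averaged over genes, compared with uniformly random orderings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hmc import hmc_sample, effective_sample_size
from .datatypes import CellRecord, CountMatrix, RunConfig

log = logging.getLogger("trajkl.pseudotime")

_HYPER_BOUND = 30.0  # reject |log psi|, |log omega| beyond this (overflow guard)


@dataclass
class PseudotimeFit:
    cell_ids: list[str]
    capture_times: np.ndarray
    tau_draws: np.ndarray  # (n_total_draws, n_cells)
    tau_hat: pd.Series  # posterior mean per cell
    psi: pd.Series  # posterior mean amplitude per gene
    omega: pd.Series  # posterior mean noise variance per gene
    diagnostics: dict = field(default_factory=dict)


@dataclass
class RoughnessTestResult:
    observed: float
    p_value: float
    null: np.ndarray
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# model density


class _ModelDensity:
    """Log posterior and gradient for x = [z (N), log psi (G), log omega (G)]."""

    def __init__(self, y: np.ndarray, capture: np.ndarray, sigma_tau: float, length_scale: float):
        self.y = y - y.mean(axis=1, keepdims=True)  # per-gene centering
        self.k = capture
        self.sigma_tau = sigma_tau
        self.l2 = length_scale**2
        self.n_genes, self.n_cells = self.y.shape
        var_g = np.maximum(self.y.var(axis=1), 1e-6)
        self.mu_lpsi = np.log(var_g)
        self.mu_lomega = np.log(var_g / 2.0)
        self.hyper_sd = 1.0

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n, g = self.n_cells, self.n_genes
        return x[:n], x[n : n + g], x[n + g :]

    def initial_point(self) -> np.ndarray:
        return np.concatenate([np.zeros(self.n_cells), self.mu_lpsi, self.mu_lomega])

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        z, lpsi, lomega = self.unpack(x)
        if np.max(np.abs(lpsi)) > _HYPER_BOUND or np.max(np.abs(lomega)) > _HYPER_BOUND:
            return -np.inf, np.zeros_like(x)
        psi, omega = np.exp(lpsi), np.exp(lomega)
        tau = self.k + self.sigma_tau * z

        diff = tau[None, :] - tau[:, None]  # E_ij = tau_j - tau_i
        corr = np.exp(-(diff**2) / (2.0 * self.l2))
        lam, q = np.linalg.eigh(corr)
        lam = np.maximum(lam, 0.0)

        yt = self.y @ q  # (G, N) rotated data
        d = psi[:, None] * lam[None, :] + omega[:, None]  # (G, N) eigenvalues of K_g
        yt2_over_d = yt**2 / d
        loglik = -0.5 * float(np.sum(yt2_over_d) + np.sum(np.log(d)))

        # priors
        lp_prior = -0.5 * float(z @ z)
        lp_prior += -0.5 * float(np.sum(((lpsi - self.mu_lpsi) / self.hyper_sd) ** 2))
        lp_prior += -0.5 * float(np.sum(((lomega - self.mu_lomega) / self.hyper_sd) ** 2))

        # gradients of the likelihood
        inv_d = 1.0 / d
        quad = yt2_over_d / d  # yt^2 / d^2
        g_lpsi = -0.5 * psi * ((inv_d - quad) @ lam)
        g_lomega = -0.5 * omega * np.sum(inv_d - quad, axis=1)

        # M = sum_g psi_g (K_g^{-1} - alpha_g alpha_g^T), in the eigenbasis
        w = (psi[:, None] * inv_d).sum(axis=0)  # (N,)
        u = yt * inv_d  # (G, N), rows are Q^T alpha_g
        inner = (q * w[None, :]) @ q.T - (q @ (u.T * psi[None, :])) @ (u @ q.T)
        g_tau = -(inner * corr * diff).sum(axis=1) / self.l2
        g_z = self.sigma_tau * g_tau - z

        grad = np.concatenate(
            [
                g_z,
                g_lpsi - (lpsi - self.mu_lpsi) / self.hyper_sd**2,
                g_lomega - (lomega - self.mu_lomega) / self.hyper_sd**2,
            ]
        )
        return loglik + lp_prior, grad


def fit_pseudotime(matrix: CountMatrix, cells: list[CellRecord], config: RunConfig) -> PseudotimeFit:
    """Sample the joint pseudotime posterior by HMC.

    ``matrix`` should be the working matrix restricted to the analysis
    genes. Cells enter the model sorted by cell id so results do not depend
    on input file order; the returned fit uses that sorted order.
    """
    by_id = {c.cell_id: c for c in cells}
    missing = [c for c in matrix.cells if c not in by_id]
    if missing:
        raise ValueError(f"cells missing metadata: {missing}")
    order = sorted(matrix.cells)
    matrix = matrix.subset_cells(order)
    capture = np.array([by_id[c].capture_time_h for c in order], dtype=float)
    if len(set(capture)) < 2:
        raise ValueError("need >= 2 capture groups to fit pseudotime")

    density = _ModelDensity(matrix.values, capture, config.sigma_tau_h, config.length_scale_h)
    n, g = density.n_cells, density.n_genes

    seeds = np.random.SeedSequence(config.seed).spawn(config.mcmc_chains)
    all_draws = []
    chain_stats = []
    for chain, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        x0 = density.initial_point()
        x0[:n] = 0.1 * rng.standard_normal(n)
        draws, stats = hmc_sample(
            density,
            x0,
            n_warmup=config.mcmc_warmup,
            n_draws=config.mcmc_draws,
            rng=rng,
        )
        all_draws.append(draws)
        chain_stats.append(stats)
        log.info(
            "chain %d: accept=%.2f divergences=%d step=%.3g",
            chain,
            stats.accept_rate,
            stats.divergences,
            stats.step_size,
        )

    draws = np.concatenate(all_draws, axis=0)
    z_draws = draws[:, :n]
    tau_draws = capture[None, :] + config.sigma_tau_h * z_draws
    tau_hat = pd.Series(tau_draws.mean(axis=0), index=order, name="tau_hat")
    psi_hat = pd.Series(np.exp(draws[:, n : n + g]).mean(axis=0), index=matrix.genes, name="psi")
    omega_hat = pd.Series(np.exp(draws[:, n + g :]).mean(axis=0), index=matrix.genes, name="omega")

    ess = np.array(
        [sum(effective_sample_size(d[:, j]) for d in (c[:, :n] for c in all_draws)) for j in range(n)]
    )
    total_div = sum(s.divergences for s in chain_stats)
    total_draws = config.mcmc_chains * config.mcmc_draws
    diagnostics = {
        "accept_rate": float(np.mean([s.accept_rate for s in chain_stats])),
        "divergences": int(total_div),
        "divergence_rate": total_div / max(total_draws, 1),
        "ess_tau_min": float(ess.min()),
        "ess_tau_median": float(np.median(ess)),
        "chains": config.mcmc_chains,
        "warmup": config.mcmc_warmup,
        "draws_per_chain": config.mcmc_draws,
        "seed": config.seed,
    }
    if diagnostics["divergence_rate"] > 0.1:
        diagnostics["divergence_warning"] = True
        log.warning("divergence rate %.1f%% exceeds 10%%", 100 * diagnostics["divergence_rate"])
    return PseudotimeFit(
        cell_ids=order,
        capture_times=capture,
        tau_draws=tau_draws,
        tau_hat=tau_hat,
        psi=psi_hat,
        omega=omega_hat,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# roughness permutation test


def roughness(profile: np.ndarray, ordering: np.ndarray) -> float:
    """Root-mean-square successive difference of ``profile`` along ``ordering``."""
    profile = np.asarray(profile, dtype=float)
    ordering = np.asarray(ordering)
    if profile.size != ordering.size or profile.size < 2:
        raise ValueError("profile and ordering must have equal length >= 2")
    x = profile[ordering]
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def _mean_roughness(values: np.ndarray, ordering: np.ndarray) -> float:
    x = values[:, ordering]
    return float(np.mean(np.sqrt(np.mean(np.diff(x, axis=1) ** 2, axis=1))))


def roughness_permutation_test(
    matrix: CountMatrix | np.ndarray,
    tau_hat: pd.Series | np.ndarray,
    n_permutations: int,
    seed: int,
) -> RoughnessTestResult:
    """Compare the inferred ordering's mean roughness with random orderings.

    Observed statistic: per-gene roughness under the ordering of cells by
    ``tau_hat``, averaged (unweighted) over genes. Null: the same statistic
    under uniformly random orderings. One-sided, smooth-is-small:
    p = (1 + #{null <= observed}) / (n_permutations + 1); ties count
    against the alternative.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if isinstance(matrix, CountMatrix):
        if isinstance(tau_hat, pd.Series):
            tau = tau_hat.reindex(matrix.cells).to_numpy()
            if np.any(np.isnan(tau)):
                raise ValueError("tau_hat missing for some matrix cells")
        else:
            tau = np.asarray(tau_hat, dtype=float)
        values = matrix.values
    else:
        values = np.asarray(matrix, dtype=float)
        tau = np.asarray(tau_hat, dtype=float)
    n_cells = values.shape[1]
    if n_cells < 3:
        raise ValueError("need >= 3 cells for the roughness test")
    if tau.size != n_cells:
        raise ValueError("tau_hat length does not match number of cells")

    observed = _mean_roughness(values, np.argsort(tau, kind="stable"))
    rng = np.random.default_rng(seed)
    null = np.array(
        [_mean_roughness(values, rng.permutation(n_cells)) for _ in range(n_permutations)]
    )
    p = (1 + int(np.sum(null <= observed))) / (n_permutations + 1)
    return RoughnessTestResult(
        observed=observed, p_value=p, null=null, n_permutations=n_permutations, seed=seed
    )
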