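"""Per-gene GP expression trajectories and KL-divergence ranking.

For each transcript a Gaussian-process regression over the inferred
pseudotimes (squared-exponential kernel, fixed length-scale, amplitude and
noise fitted by marginal likelihood) yields a posterior mean mu_g(t) and sd
s_g(t) of the latent expression curve. The change statistic is the KL
divergence between the Gaussian trajectory posteriors evaluated at
representative start and end pseudotimes (group medians); transcripts are
ranked by it, largest first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .datatypes import CellRecord, CountMatrix, RunConfig
from .pseudotime import PseudotimeFit

log = logging.getLogger("trajkl.trajectory")

_JITTER = 1e-10


@dataclass
class GeneTrajectory:
    """Fitted GP posterior for one transcript."""

    gene: str
    tau_train: np.ndarray
    psi: float
    omega: float
    mean_offset: float
    length_scale: float

    def __post_init__(self) -> None:
        if self.psi < 0 or self.omega < 0:
            raise ValueError(f"{self.gene}: psi and omega must be >= 0")
        tau = np.asarray(self.tau_train, dtype=float)
        self.tau_train = tau
        n = tau.size
        d2 = (tau[:, None] - tau[None, :]) ** 2
        k = self.psi * np.exp(-d2 / (2 * self.length_scale**2))
        k[np.diag_indices(n)] += self.omega + _JITTER * max(self.psi, 1.0)
        self._chol = scipy.linalg.cho_factor(k, lower=True)
        self._y: np.ndarray | None = None
        self._alpha: np.ndarray | None = None

    def set_data(self, y: np.ndarray) -> "GeneTrajectory":
        """Attach (uncentered) training observations; required before mu()."""
        y = np.asarray(y, dtype=float)
        if y.size != self.tau_train.size:
            raise ValueError(f"{self.gene}: data length mismatch")
        self._y = y
        self._alpha = scipy.linalg.cho_solve(self._chol, y - self.mean_offset)
        return self

    def _kstar(self, t: np.ndarray) -> np.ndarray:
        d2 = (np.atleast_1d(t)[:, None] - self.tau_train[None, :]) ** 2
        return self.psi * np.exp(-d2 / (2 * self.length_scale**2))

    def mu(self, t: float | np.ndarray) -> np.ndarray | float:
        """Posterior mean of the latent trajectory at time(s) t."""
        if self._alpha is None:
            raise RuntimeError(f"{self.gene}: call set_data() before evaluating")
        out = self.mean_offset + self._kstar(t) @ self._alpha
        return float(out[0]) if np.isscalar(t) else out

    def sd(self, t: float | np.ndarray, predictive: bool = False) -> np.ndarray | float:
        """Posterior sd of the latent trajectory (add omega if predictive)."""
        ks = self._kstar(t)
        v = self.psi - np.sum(ks * scipy.linalg.cho_solve(self._chol, ks.T).T, axis=1)
        v = np.maximum(v, 1e-300)
        if predictive:
            v = v + self.omega
        out = np.sqrt(v)
        return float(out[0]) if np.isscalar(t) else out


def _neg_marginal_loglik(
    params: np.ndarray, lam: np.ndarray, yt2: np.ndarray
) -> tuple[float, np.ndarray]:
    lpsi, lomega = params
    psi, omega = np.exp(lpsi), np.exp(lomega)
    d = psi * lam + omega
    nll = 0.5 * float(np.sum(yt2 / d) + np.sum(np.log(d)))
    inv_d = 1.0 / d
    quad = yt2 * inv_d * inv_d
    g_psi = 0.5 * psi * float((inv_d - quad) @ lam)
    g_omega = 0.5 * omega * float(np.sum(inv_d - quad))
    return nll, np.array([g_psi, g_omega])


def fit_gene_trajectory(
    expr: np.ndarray,
    tau_hat: np.ndarray,
    length_scale: float,
    hyper_strategy: str = "mle",
    psi0: float | None = None,
    omega0: float | None = None,
    gene: str = "",
    _eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> GeneTrajectory:
    """Fit one transcript's GP trajectory over fixed pseudotimes.

    ``hyper_strategy='mle'`` maximizes the marginal likelihood over
    amplitude/noise (deterministic multistart L-BFGS); ``'carry'`` uses the
    supplied ``psi0``/``omega0`` (e.g. pseudotime-stage posteriors) as-is.
    ``_eig`` optionally carries a precomputed eigendecomposition of the
    correlation matrix, shared across genes with identical pseudotimes.
    """
    expr = np.asarray(expr, dtype=float)
    tau_hat = np.asarray(tau_hat, dtype=float)
    if expr.size != tau_hat.size or expr.size < 3:
        raise ValueError(f"{gene or 'gene'}: need matching expr/tau of length >= 3")
    offset = float(expr.mean())
    y = expr - offset

    if hyper_strategy == "carry":
        if psi0 is None or omega0 is None:
            raise ValueError("hyper_strategy='carry' requires psi0 and omega0")
        psi, omega = float(psi0), float(omega0)
    elif hyper_strategy == "mle":
        if _eig is None:
            d2 = (tau_hat[:, None] - tau_hat[None, :]) ** 2
            corr = np.exp(-d2 / (2 * length_scale**2))
            lam, q = np.linalg.eigh(corr)
            lam = np.maximum(lam, 0.0)
        else:
            lam, q = _eig
        yt2 = (y @ q) ** 2
        var = max(float(y.var()), 1e-12)
        lv = np.log(var)
        best = None
        for f_psi, f_omega in ((0.9, 0.1), (0.5, 0.5), (0.1, 0.9)):
            res = scipy.optimize.minimize(
                _neg_marginal_loglik,
                x0=np.array([lv + np.log(f_psi), lv + np.log(f_omega)]),
                args=(lam, yt2),
                jac=True,
                method="L-BFGS-B",
                bounds=[(lv - 18.0, lv + 18.0)] * 2,
            )
            if not np.isfinite(res.fun):
                raise ValueError(f"non-finite marginal likelihood for gene {gene!r}")
            if best is None or res.fun < best.fun:
                best = res
        psi, omega = (float(x) for x in np.exp(best.x))
    else:
        raise ValueError(f"unknown hyper_strategy {hyper_strategy!r}")

    traj = GeneTrajectory(
        gene=gene,
        tau_train=tau_hat,
        psi=psi,
        omega=omega,
        mean_offset=offset,
        length_scale=length_scale,
    )
    return traj.set_data(expr)


# ---------------------------------------------------------------------------
# KL statistic


def gaussian_kl(mu1: float, s1: float, mu2: float, s2: float) -> float:
    """KL(N(mu1, s1^2) || N(mu2, s2^2)) in nats."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    return float(np.log(s2 / s1) + (s1**2 + (mu1 - mu2) ** 2) / (2 * s2**2) - 0.5)


def kl_expression_change(
    traj: GeneTrajectory,
    t_start: float,
    t_end: float,
    direction: str = "symmetrized",
    predictive: bool = False,
) -> float:
    """KL divergence between the trajectory posteriors at t_start and t_end."""
    mu_s, sd_s = traj.mu(t_start), traj.sd(t_start, predictive=predictive)
    mu_e, sd_e = traj.mu(t_end), traj.sd(t_end, predictive=predictive)
    if direction == "start_to_end":
        return gaussian_kl(mu_s, sd_s, mu_e, sd_e)
    if direction == "end_to_start":
        return gaussian_kl(mu_e, sd_e, mu_s, sd_s)
    if direction == "symmetrized":
        return 0.5 * (gaussian_kl(mu_s, sd_s, mu_e, sd_e) + gaussian_kl(mu_e, sd_e, mu_s, sd_s))
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class KLRecord:
    gene: str
    t_start: float
    t_end: float
    mu_start: float
    sd_start: float
    mu_end: float
    sd_end: float
    divergence: float
    rank: int | None = None


def representative_pseudotimes(
    fit: PseudotimeFit | pd.Series,
    cells: list[CellRecord],
    start_h: float = 0.0,
    end_h: float = 48.0,
) -> tuple[float, float]:
    """Median inferred pseudotime of the start and end capture groups."""
    tau_hat = fit.tau_hat if isinstance(fit, PseudotimeFit) else fit
    by_id = {c.cell_id: c for c in cells}
    out = []
    for group in (start_h, end_h):
        vals = [
            tau_hat[cid]
            for cid in tau_hat.index
            if cid in by_id and by_id[cid].capture_time_h == group
        ]
        if not vals:
            raise ValueError(f"no cells in capture group {group} h")
        out.append(float(np.median(vals)))
    return out[0], out[1]


def rank_transcripts(records: list[KLRecord]) -> pd.DataFrame:
    """Descending divergence; ties break by ascending gene id; rank 1 = largest."""
    rows = sorted(records, key=lambda r: (-r.divergence, r.gene))
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "divergence": [r.divergence for r in rows],
            "rank": np.arange(1, len(rows) + 1),
            "t_start": [r.t_start for r in rows],
            "t_end": [r.t_end for r in rows],
            "mu_start": [r.mu_start for r in rows],
            "sd_start": [r.sd_start for r in rows],
            "mu_end": [r.mu_end for r in rows],
            "sd_end": [r.sd_end for r in rows],
        }
    )
    for r, new_rank in zip(rows, df["rank"]):
        r.rank = int(new_rank)
    return df


def kl_rank_genes(
    working: CountMatrix,
    fit: PseudotimeFit,
    cells: list[CellRecord],
    config: RunConfig,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Fit trajectories and rank all (or the given) genes by KL divergence."""
    config.validate()
    genes = list(genes) if genes is not None else list(working.genes)
    sub = working.subset_genes(genes).subset_cells(fit.cell_ids)
    tau = fit.tau_hat.reindex(fit.cell_ids).to_numpy()
    t_start, t_end = representative_pseudotimes(fit, cells)

    d2 = (tau[:, None] - tau[None, :]) ** 2
    corr = np.exp(-d2 / (2 * config.length_scale_h**2))
    lam, q = np.linalg.eigh(corr)
    eig = (np.maximum(lam, 0.0), q)

    records = []
    for i, gene in enumerate(genes):
        kwargs: dict = {}
        if config.trajectory_hyper_strategy == "carry":
            if gene not in fit.psi.index:
                raise ValueError(f"gene {gene!r} has no pseudotime-stage hyperparameters to carry")
            kwargs = {"psi0": float(fit.psi[gene]), "omega0": float(fit.omega[gene])}
        traj = fit_gene_trajectory(
            sub.values[i],
            tau,
            config.length_scale_h,
            hyper_strategy=config.trajectory_hyper_strategy,
            gene=gene,
            _eig=eig,
            **kwargs,
        )
        records.append(
            KLRecord(
                gene=gene,
                t_start=t_start,
                t_end=t_end,
                mu_start=float(traj.mu(t_start)),
                sd_start=float(traj.sd(t_start, predictive=config.kl_predictive)),
                mu_end=float(traj.mu(t_end)),
                sd_end=float(traj.sd(t_end, predictive=config.kl_predictive)),
                divergence=kl_expression_change(
                    traj, t_start, t_end, direction=config.kl_direction, predictive=config.kl_predictive
                ),
            )
        )
    return rank_transcripts(records)
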