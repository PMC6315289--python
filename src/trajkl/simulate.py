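"""Synthetic datasets with known ground truth for every pipeline stage.

Expression: cells are drawn around their capture times
(tau* ~ Normal(k_c, sigma_tau_true^2)); down/up genes follow strictly
monotone sigmoid mean curves of tau* on the log10 scale, flat genes are
constant; counts are produced by exponentiating the noisy log-scale signal,
applying a per-cell size factor, subtracting 1 and rounding (floored at 0).
Gaussian noise on the log scale makes the counts overdispersed relative to
Poisson and matches the pipeline's log10(count + 1) working scale.

Binding: toy TSS tables and factor/dataset interval sets where planted
occupied genes satisfy the all-factors-in->=2-datasets rule and planted
unoccupied genes violate it in controlled ways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellRecord, CountMatrix
from .occupancy import GenomicInterval, TSSRecord

_DYE = {0.0: "hoechst", 24.0: "cellmask", 48.0: "calcein"}

# Known markers whose direction along the transition is established; the
# leading simulated genes of each class are named after them so the curated
# gene list and the marker-exclusion rule exercise realistic ids.
_DOWN_MARKERS = ("Tfcp2l1", "Esrrb", "Cox7a1", "Cpt1a")
_UP_MARKERS = ("Fgf5", "Lin28b", "Pdk1", "Pdk3", "Slc2a1", "Stk11")


@dataclass
class SimConfig:
    seed: int
    n_cells_per_group: int = 20
    capture_set: tuple[float, ...] = (0.0, 24.0, 48.0)
    sigma_tau_true: float = 8.0
    n_down: int = 40
    n_up: int = 40
    n_flat: int = 40
    amplitude: float = 1.5  # sigmoid rise on the log10 scale
    noise_sd: float = 0.15  # log10-scale dispersion
    sf_log_sd: float = 0.2
    min_mapped_reads: int = 6_000_000
    n_qc_failures: int = 0  # cells given mapped_reads below the threshold
    use_marker_names: bool = True  # name leading down/up genes after known markers

    def validate(self) -> None:
        if self.n_cells_per_group < 1 or len(self.capture_set) < 1:
            raise ValueError("need >= 1 cell per group and a non-empty capture set")
        if self.n_down + self.n_up + self.n_flat < 1:
            raise ValueError("need >= 1 gene")
        if self.sigma_tau_true < 0 or self.noise_sd < 0 or self.sf_log_sd < 0:
            raise ValueError("spread parameters must be >= 0")


@dataclass
class SimulationTruth:
    tau_true: pd.Series | None = None
    size_factors: pd.Series | None = None
    gene_class: pd.Series | None = None  # down / up / flat
    gene_params: pd.DataFrame | None = None
    dispersion: float | None = None
    occupancy: pd.Series | None = None
    field_notes: dict = field(default_factory=dict)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gene_means(rng: np.random.Generator, cls: str, amplitude: float) -> dict:
    base = rng.uniform(0.6, 1.2)
    mid = rng.uniform(14.0, 34.0)
    slope = rng.uniform(6.0, 12.0)
    return {"class": cls, "base": base, "amplitude": amplitude, "midpoint": mid, "slope": slope}


def _mean_curve(params: dict, tau: np.ndarray) -> np.ndarray:
    cls = params["class"]
    if cls == "flat":
        return np.full_like(tau, params["base"] + params["amplitude"] / 2.0)
    s = _sigmoid((tau - params["midpoint"]) / params["slope"])
    if cls == "down":
        s = 1.0 - s
    return params["base"] + params["amplitude"] * s


def simulate_expression(config: SimConfig) -> tuple[CountMatrix, list[CellRecord], SimulationTruth]:
    """Generate a pseudotime-structured count matrix with full truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    cell_ids, times, labels = [], [], []
    for t in config.capture_set:
        for i in range(config.n_cells_per_group):
            cell_ids.append(f"c{int(round(t)):02d}h_{i:03d}")
            times.append(float(t))
            labels.append(_DYE.get(float(t), f"group{t}"))
    times_arr = np.array(times)
    tau_true = times_arr + config.sigma_tau_true * rng.standard_normal(len(times_arr))
    size_factors = np.exp(config.sf_log_sd * rng.standard_normal(len(times_arr)))

    gene_rows = []
    markers = {"down": _DOWN_MARKERS, "up": _UP_MARKERS, "flat": ()}
    for cls, n in (("down", config.n_down), ("up", config.n_up), ("flat", config.n_flat)):
        named = markers[cls] if config.use_marker_names else ()
        for i in range(n):
            p = _gene_means(rng, cls, config.amplitude)
            p["gene"] = named[i] if i < len(named) else f"{cls}_{i:03d}"
            gene_rows.append(p)
    genes = [p["gene"] for p in gene_rows]

    log_mu = np.stack([_mean_curve(p, tau_true) for p in gene_rows])
    noisy = log_mu + config.noise_sd * rng.standard_normal(log_mu.shape)
    counts = np.maximum(0, np.round(size_factors[None, :] * 10.0**noisy - 1.0))
    matrix = CountMatrix(genes, cell_ids, counts)

    mapped = config.min_mapped_reads + rng.integers(0, 4_000_000, size=len(cell_ids))
    for j in range(min(config.n_qc_failures, len(cell_ids))):
        mapped[j] = rng.integers(1_000_000, config.min_mapped_reads)
    cells = [
        CellRecord(cell_id=c, capture_time_h=t, mapped_reads=int(m), label=lab)
        for c, t, m, lab in zip(cell_ids, times, mapped, labels)
    ]

    truth = SimulationTruth(
        tau_true=pd.Series(tau_true, index=cell_ids, name="tau_true"),
        size_factors=pd.Series(size_factors, index=cell_ids, name="size_factor"),
        gene_class=pd.Series([p["class"] for p in gene_rows], index=genes, name="class"),
        gene_params=pd.DataFrame(gene_rows).set_index("gene"),
        dispersion=config.noise_sd,
    )
    return matrix, cells, truth


def simulate_null_expression(config: SimConfig) -> tuple[CountMatrix, list[CellRecord]]:
    """All-flat dataset: no pseudotime structure by construction."""
    cfg = SimConfig(
        seed=config.seed,
        n_cells_per_group=config.n_cells_per_group,
        capture_set=config.capture_set,
        sigma_tau_true=config.sigma_tau_true,
        n_down=0,
        n_up=0,
        n_flat=config.n_down + config.n_up + config.n_flat,
        amplitude=config.amplitude,
        noise_sd=config.noise_sd,
        sf_log_sd=config.sf_log_sd,
        min_mapped_reads=config.min_mapped_reads,
        n_qc_failures=config.n_qc_failures,
        use_marker_names=False,
    )
    matrix, cells, _ = simulate_expression(cfg)
    return matrix, cells


# ---------------------------------------------------------------------------
# binding landscapes

_UNOCCUPIED_MODES = ("one_dataset", "missing_factor", "empty")


@dataclass
class BindingSimConfig:
    seed: int
    n_genes: int = 12
    occupied_fraction: float = 0.5
    factors: tuple[str, ...] = ("OCT4", "SOX2", "NANOG")
    datasets: tuple[str, ...] = ("ds1", "ds2", "ds3")
    up_bp: int = 20_000
    down_bp: int = 4_000
    chrom: str = "chrS"
    spacing_bp: int = 200_000
    peak_width_bp: int = 400

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need >= 1 gene")
        if len(self.factors) != 3 or len(self.datasets) != 3:
            raise ValueError("binding simulation expects exactly 3 factors and 3 datasets")
        if self.up_bp <= 0 or self.down_bp <= 0:
            raise ValueError("window parameters missing or non-positive")


def simulate_binding_landscape(
    config: BindingSimConfig,
) -> tuple[list[TSSRecord], dict[tuple[str, str], list[GenomicInterval]], SimulationTruth]:
    """Plant occupied / unoccupied genes with recorded truth.

    Occupied genes get all three factors overlapping their window in 2 or 3
    datasets. Unoccupied genes cycle through controlled violations: all
    factors in exactly one dataset; two datasets but one factor missing in
    one of them (leaving a single qualifying dataset); or no intervals.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_occ = int(round(config.occupied_fraction * config.n_genes))

    tss: list[TSSRecord] = []
    truth_flags = {}
    binding: dict[tuple[str, str], list[GenomicInterval]] = {
        (f, d): [] for f in config.factors for d in config.datasets
    }

    for i in range(config.n_genes):
        gene = f"g{i:03d}"
        strand = "+" if i % 2 == 0 else "-"
        pos = config.up_bp + 10_000 + i * config.spacing_bp
        tss.append(TSSRecord(gene=gene, chrom=config.chrom, position=pos, strand=strand))
        occupied = i < n_occ
        truth_flags[gene] = occupied

        if strand == "+":
            lo, hi = pos - config.up_bp, pos + config.down_bp
        else:
            lo, hi = pos - config.down_bp, pos + config.up_bp

        def peak() -> GenomicInterval:
            start = int(rng.integers(lo, hi - config.peak_width_bp))
            return GenomicInterval(chrom=config.chrom, start=start, end=start + config.peak_width_bp)

        if occupied:
            n_ds = int(rng.integers(2, 4))  # 2 or 3 qualifying datasets
            which = rng.permutation(len(config.datasets))[:n_ds]
            for d_idx in which:
                for f in config.factors:
                    binding[(f, config.datasets[d_idx])].append(peak())
        else:
            mode = _UNOCCUPIED_MODES[i % len(_UNOCCUPIED_MODES)]
            if mode == "one_dataset":
                d = config.datasets[int(rng.integers(0, 3))]
                for f in config.factors:
                    binding[(f, d)].append(peak())
            elif mode == "missing_factor":
                d_full, d_partial = (config.datasets[j] for j in rng.permutation(3)[:2])
                for f in config.factors:
                    binding[(f, d_full)].append(peak())
                for f in list(config.factors)[:-1]:  # drop one factor
                    binding[(f, d_partial)].append(peak())
            # "empty": no intervals at all

    truth = SimulationTruth(
        occupancy=pd.Series(truth_flags, name="occupied"),
        field_notes={"factors": list(config.factors), "datasets": list(config.datasets)},
    )
    return tss, binding, truth
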