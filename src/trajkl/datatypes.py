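"""Core data containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

#: Genes named in the main-text trajectory figures; used as the default
#: curated seed of the analysis-gene list (the remainder is filled by the
#: capture-time variance-ratio score).
DEFAULT_CURATED_GENES = (
    "Esrrb",
    "Tfcp2l1",
    "Fgf5",
    "Lin28b",
    "Pdk1",
    "Pdk3",
    "Slc2a1",
    "Stk11",
    "Cox7a1",
    "Cpt1a",
)

KL_DIRECTIONS = ("start_to_end", "end_to_start", "symmetrized")


@dataclass(frozen=True)
class CellRecord:
    """One profiled cell: identity, harvest time and mapping depth."""

    cell_id: str
    capture_time_h: float
    mapped_reads: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.mapped_reads < 0:
            raise ValueError(f"cell {self.cell_id!r}: mapped_reads must be >= 0")


class CountMatrix:
    """Genes x cells expression matrix.

    Holds raw integer counts before transformation and reals afterwards.
    Gene and cell identifiers are unique and ordered; ``values[i, j]`` is
    gene ``genes[i]`` in cell ``cells[j]``.
    """

    def __init__(self, genes: Sequence[str], cells: Sequence[str], values: np.ndarray):
        genes = list(genes)
        cells = list(cells)
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"values shape {values.shape} does not match {len(genes)} genes x {len(cells)} cells"
            )
        for name, ids in (("gene", genes), ("cell", cells)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise ValueError(f"duplicate {name} id: {x!r}")
                seen.add(x)
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite values")
        self.genes = genes
        self.cells = cells
        self.values = values

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def subset_genes(self, keep: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in keep]
        return CountMatrix(list(keep), list(self.cells), self.values[rows])

    def subset_cells(self, keep: Sequence[str]) -> "CountMatrix":
        idx = {c: j for j, c in enumerate(self.cells)}
        cols = [idx[c] for c in keep]
        return CountMatrix(list(self.genes), list(keep), self.values[:, cols])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.genes == other.genes
            and self.cells == other.cells
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"CountMatrix({len(self.genes)} genes x {len(self.cells)} cells)"


@dataclass
class RunConfig:
    """Declarative configuration for the full pipeline.

    ``kl_direction`` has no default on purpose: the direction of the KL
    statistic must be chosen explicitly (use ``"symmetrized"`` unless you
    have a reason not to) and is validated before any computation runs.
    """

    # cell / gene QC
    min_mapped_reads: int = 6_000_000
    marker_gene: str = "Tfcp2l1"
    marker_threshold: float = 1.5  # on the log10(count+1) scale
    marker_group_h: float = 48.0
    capture_set: tuple[float, ...] = (0.0, 24.0, 48.0)
    # analysis-gene selection
    n_analysis_genes: int = 135
    curated_genes: tuple[str, ...] = DEFAULT_CURATED_GENES
    # pseudotime model
    sigma_tau_h: float = 8.0
    length_scale_h: float = 48.0
    mcmc_chains: int = 2
    mcmc_warmup: int = 300
    mcmc_draws: int = 300
    seed: int = 0
    # roughness test
    n_permutations: int = 999
    # KL stage
    kl_direction: str | None = None
    kl_predictive: bool = False
    trajectory_hyper_strategy: str = "mle"  # or "carry"
    # stage-order switch for the marker exclusion (see preprocess docs)
    marker_on_normalized: bool = False
    # occupancy
    osn_stranded: bool = True
    osn_rule: str = "all_factors_per_dataset"  # or "each_factor_min_datasets"
    osn_up_bp: int = 20_000
    osn_down_bp: int = 4_000
    osn_min_datasets: int = 2

    def validate(self) -> None:
        if self.min_mapped_reads <= 0:
            raise ValueError("min_mapped_reads must be positive")
        if self.marker_threshold <= 0:
            raise ValueError("marker_threshold must be positive")
        if self.n_analysis_genes <= 0:
            raise ValueError("n_analysis_genes must be positive")
        if self.sigma_tau_h <= 0:
            raise ValueError("sigma_tau_h must be positive")
        if self.length_scale_h <= 0:
            raise ValueError("length_scale_h must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.kl_direction is None:
            raise ValueError("kl_direction must be set explicitly (e.g. 'symmetrized')")
        if self.kl_direction not in KL_DIRECTIONS:
            raise ValueError(f"kl_direction must be one of {KL_DIRECTIONS}, got {self.kl_direction!r}")
        if self.trajectory_hyper_strategy not in ("mle", "carry"):
            raise ValueError("trajectory_hyper_strategy must be 'mle' or 'carry'")
        if self.osn_rule not in ("all_factors_per_dataset", "each_factor_min_datasets"):
            raise ValueError(f"unknown osn_rule {self.osn_rule!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["capture_set"] = list(self.capture_set)
        d["curated_genes"] = list(self.curated_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "capture_set" in d:
            d["capture_set"] = tuple(float(x) for x in d["capture_set"])
        if "curated_genes" in d:
            d["curated_genes"] = tuple(d["curated_genes"])
        return cls(**d)


def check_cells_aligned(matrix: CountMatrix, records: Sequence[CellRecord]) -> None:
    """Verify every matrix cell has a metadata record (hard error otherwise)."""
    have = {r.cell_id for r in records}
    missing = [c for c in matrix.cells if c not in have]
    if missing:
        raise ValueError(f"cells missing from metadata: {missing}")
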