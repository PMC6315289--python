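"""Cell/gene QC, transform, normalization and analysis-gene selection.

Fixed stage order::

    mapped-read filter -> invariant-gene removal -> log10(count+1) transform
    -> marker exclusion -> size factors (raw counts, surviving cells)
    -> normalize + transform -> variance-ratio gene selection

The marker exclusion threshold is applied to the *unnormalized*
log10(count+1) value by default; set ``marker_on_normalized=True`` in the
config to threshold the size-factor-normalized value instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellRecord, CountMatrix, RunConfig, check_cells_aligned

log = logging.getLogger("trajkl.preprocess")


@dataclass
class PreprocessReport:
    cells_in: int
    cells_after_read_filter: int
    cells_after_marker_filter: int
    genes_in: int
    genes_after_invariant_filter: int
    size_factors: pd.Series = field(repr=False)
    analysis_genes: pd.Series = field(repr=False)  # gene -> variance-ratio score, selection order

    def to_dict(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_after_read_filter": self.cells_after_read_filter,
            "cells_after_marker_filter": self.cells_after_marker_filter,
            "genes_in": self.genes_in,
            "genes_after_invariant_filter": self.genes_after_invariant_filter,
            "size_factors": {c: float(v) for c, v in self.size_factors.items()},
            "analysis_genes": {g: float(v) for g, v in self.analysis_genes.items()},
        }


def filter_cells_by_mapped_reads(cells: list[CellRecord], min_reads: int) -> list[str]:
    """Cell ids with mapped_reads >= min_reads (inclusive boundary)."""
    return [c.cell_id for c in cells if c.mapped_reads >= min_reads]


def log_transform_counts(matrix: CountMatrix) -> CountMatrix:
    """Replace each value x by log10(x + 1)."""
    if np.any(matrix.values < 0):
        raise ValueError("negative counts cannot be log-transformed")
    return CountMatrix(matrix.genes, matrix.cells, np.log10(matrix.values + 1.0))


def remove_invariant_transcripts(matrix: CountMatrix) -> CountMatrix:
    """Drop genes whose value is identical across all cells."""
    v = matrix.values
    varying = ~np.all(v == v[:, :1], axis=1) if v.shape[1] else np.zeros(v.shape[0], bool)
    keep = [g for g, k in zip(matrix.genes, varying) if k]
    return matrix.subset_genes(keep)


def exclude_high_marker_cells(
    transformed: CountMatrix,
    cells: list[CellRecord],
    marker: str,
    threshold: float,
    group_h: float,
) -> list[str]:
    """Exclude cells of capture group ``group_h`` whose transformed marker
    expression strictly exceeds ``threshold``; other groups are untouched."""
    if marker not in transformed.genes:
        raise ValueError(f"marker gene {marker!r} absent from matrix")
    row = transformed.gene_row(marker)
    value = dict(zip(transformed.cells, row))
    by_id = {c.cell_id: c for c in cells}
    kept = []
    for cell_id in transformed.cells:
        rec = by_id[cell_id]
        if rec.capture_time_h == group_h and value[cell_id] > threshold:
            continue
        kept.append(cell_id)
    return kept


def median_of_ratios_size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors from raw counts.

    The reference for gene g is its geometric mean across cells, computed
    only over genes with strictly positive counts in every cell; the size
    factor of cell c is the median over those genes of count_gc / ref_g.
    """
    v = matrix.values
    all_positive = np.all(v > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no gene has strictly positive counts in all cells; relax the "
            "reference-gene rule or pre-filter cells/genes"
        )
    pos = v[all_positive]
    ref = np.exp(np.log(pos).mean(axis=1))  # per-gene geometric mean
    sf = np.median(pos / ref[:, None], axis=0)
    return pd.Series(sf, index=matrix.cells, name="size_factor")


def normalize_and_transform(matrix: CountMatrix, size_factors: pd.Series) -> CountMatrix:
    """Working value = log10(count / sf + 1)."""
    sf = size_factors.reindex(matrix.cells)
    if sf.isna().any():
        raise ValueError(f"size factors missing for cells: {list(sf.index[sf.isna()])}")
    if len(size_factors) != len(matrix.cells):
        raise ValueError(
            f"size-factor vector length {len(size_factors)} != {len(matrix.cells)} cells"
        )
    if np.any(sf.to_numpy() <= 0):
        raise ValueError("size factors must be positive")
    return CountMatrix(
        matrix.genes, matrix.cells, np.log10(matrix.values / sf.to_numpy()[None, :] + 1.0)
    )


def capture_variance_ratio(matrix: CountMatrix, cells: list[CellRecord]) -> pd.Series:
    """Per-gene between-capture-group variance over within-group variance.

    Var_between is the sample variance of the per-group means; Var_within is
    the unweighted mean of the per-group sample variances. A gene with zero
    within-group variance but positive between-group variance scores +inf;
    0/0 scores 0. Every group must contain >= 2 cells.
    """
    by_id = {c.cell_id: c for c in cells}
    times = np.array([by_id[c].capture_time_h for c in matrix.cells])
    groups = sorted(set(times))
    if len(groups) < 2:
        raise ValueError("need >= 2 capture groups")
    masks = [times == g for g in groups]
    for g, m in zip(groups, masks):
        if m.sum() < 2:
            raise ValueError(f"capture group {g} h has fewer than 2 cells")
    means = np.stack([matrix.values[:, m].mean(axis=1) for m in masks], axis=1)
    wvars = np.stack([matrix.values[:, m].var(axis=1, ddof=1) for m in masks], axis=1)
    between = means.var(axis=1, ddof=1)
    within = wvars.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = between / within
    score[(within == 0) & (between > 0)] = np.inf
    score[(within == 0) & (between == 0)] = 0.0
    return pd.Series(score, index=matrix.genes, name="variance_ratio")


def select_analysis_genes(scores: pd.Series, curated: list[str], n_total: int) -> list[str]:
    """Curated genes first, then top variance-ratio genes until ``n_total``.

    Curated genes absent from the score index are logged and skipped.
    Score ties break by ascending gene id. Raises if the curated list alone
    exceeds ``n_total``.
    """
    present = [g for g in curated if g in scores.index]
    for g in curated:
        if g not in scores.index:
            log.warning("curated gene %r not in matrix; skipped", g)
    if n_total < len(present):
        raise ValueError(f"n_total={n_total} smaller than curated list ({len(present)} genes)")
    chosen = list(dict.fromkeys(present))
    taken = set(chosen)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    for gene, _ in ranked:
        if len(chosen) >= n_total:
            break
        if gene not in taken:
            chosen.append(gene)
            taken.add(gene)
    return chosen


def preprocess(
    matrix: CountMatrix, cells: list[CellRecord], config: RunConfig
) -> tuple[CountMatrix, list[CellRecord], PreprocessReport]:
    """Run the full QC/normalization/selection chain.

    Returns the working matrix (normalized log scale, all surviving genes),
    the surviving cell records, and a report. The analysis-gene list lives
    in the report; subset the working matrix with it for the pseudotime fit.
    """
    check_cells_aligned(matrix, cells)
    cells_in, genes_in = len(matrix.cells), len(matrix.genes)

    kept = filter_cells_by_mapped_reads([c for c in cells if c.cell_id in set(matrix.cells)],
                                        config.min_mapped_reads)
    matrix = matrix.subset_cells([c for c in matrix.cells if c in set(kept)])
    n_after_reads = len(matrix.cells)
    log.info("read filter: %d -> %d cells", cells_in, n_after_reads)

    matrix = remove_invariant_transcripts(matrix)
    n_genes_after = len(matrix.genes)
    log.info("invariant-gene removal: %d -> %d genes", genes_in, n_genes_after)
    if n_genes_after == 0:
        raise ValueError("no varying genes remain after invariant-gene removal")

    transformed = log_transform_counts(matrix)
    cell_list = [c for c in cells if c.cell_id in set(matrix.cells)]
    if config.marker_on_normalized:
        sf0 = median_of_ratios_size_factors(matrix)
        marker_basis = normalize_and_transform(matrix, sf0)
    else:
        marker_basis = transformed
    kept = exclude_high_marker_cells(
        marker_basis, cell_list, config.marker_gene, config.marker_threshold, config.marker_group_h
    )
    matrix = matrix.subset_cells(kept)
    n_after_marker = len(matrix.cells)
    log.info("marker exclusion: %d -> %d cells", n_after_reads, n_after_marker)

    size_factors = median_of_ratios_size_factors(matrix)
    working = normalize_and_transform(matrix, size_factors)

    surviving = [c for c in cells if c.cell_id in set(matrix.cells)]
    scores = capture_variance_ratio(working, surviving)
    n_total = min(config.n_analysis_genes, len(scores))
    analysis = select_analysis_genes(scores, list(config.curated_genes), n_total)
    report = PreprocessReport(
        cells_in=cells_in,
        cells_after_read_filter=n_after_reads,
        cells_after_marker_filter=n_after_marker,
        genes_in=genes_in,
        genes_after_invariant_filter=n_genes_after,
        size_factors=size_factors,
        analysis_genes=scores.reindex(analysis),
    )
    return working, surviving, report
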