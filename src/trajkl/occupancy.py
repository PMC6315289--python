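"""Promoter-window transcription-factor occupancy calls.

A gene is called occupied when all configured factors have at least one
binding interval overlapping its regulatory window in at least
``min_datasets`` of the datasets. Coordinates are 0-based, half-open
throughout; windows are oriented by gene strand by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_UPSTREAM_BP = 20_000
DEFAULT_DOWNSTREAM_BP = 4_000


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) on {self.chrom}")


@dataclass(frozen=True)
class TSSRecord:
    gene: str
    chrom: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"TSS position must be >= 0 for {self.gene}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-' for {self.gene}")


@dataclass(frozen=True)
class OccupancyCall:
    gene: str
    per_dataset: dict[str, bool]
    qualifying_datasets: int
    occupied: bool


def regulatory_window(
    tss: TSSRecord,
    up_bp: int = DEFAULT_UPSTREAM_BP,
    down_bp: int = DEFAULT_DOWNSTREAM_BP,
    stranded: bool = True,
) -> GenomicInterval:
    """Window from ``up_bp`` upstream to ``down_bp`` downstream of the TSS.

    Upstream/downstream are strand-aware unless ``stranded=False``, in which
    case the + geometry is applied regardless of strand. The window start is
    clamped at 0.
    """
    if tss.strand == "+" or not stranded:
        start, end = tss.position - up_bp, tss.position + down_bp
    else:
        start, end = tss.position - down_bp, tss.position + up_bp
    return GenomicInterval(chrom=tss.chrom, start=max(0, start), end=end)


def binds_region(intervals: Sequence[GenomicInterval], region: GenomicInterval) -> bool:
    """True iff any interval overlaps the region by >= 1 bp (same chromosome)."""
    same = [iv for iv in intervals if iv.chrom == region.chrom]
    if not same:
        return False
    starts = np.fromiter((iv.start for iv in same), dtype=np.int64)
    ends = np.fromiter((iv.end for iv in same), dtype=np.int64)
    return bool(np.any((starts < region.end) & (region.start < ends)))


def call_osn_occupancy(
    gene: str,
    tss_table: Mapping[str, TSSRecord] | Sequence[TSSRecord],
    binding: Mapping[tuple[str, str], Sequence[GenomicInterval]],
    factors: Sequence[str] = ("OCT4", "SOX2", "NANOG"),
    datasets: Sequence[str] = ("ds1", "ds2", "ds3"),
    up_bp: int = DEFAULT_UPSTREAM_BP,
    down_bp: int = DEFAULT_DOWNSTREAM_BP,
    min_datasets: int = 2,
    stranded: bool = True,
    rule: str = "all_factors_per_dataset",
) -> OccupancyCall:
    """Call occupancy for one gene against factor/dataset interval sets.

    ``binding`` maps ``(factor, dataset)`` to its intervals; a missing key
    means no intervals for that pair. Under the default rule a dataset
    qualifies iff *all* factors overlap the window in it, and the gene is
    occupied iff at least ``min_datasets`` datasets qualify. The alternative
    rule ``"each_factor_min_datasets"`` instead requires every factor
    individually to overlap in >= ``min_datasets`` datasets.
    """
    if isinstance(tss_table, Mapping):
        tss = tss_table.get(gene)
    else:
        tss = next((r for r in tss_table if r.gene == gene), None)
    if tss is None:
        raise KeyError(f"gene {gene!r} absent from TSS table")
    region = regulatory_window(tss, up_bp=up_bp, down_bp=down_bp, stranded=stranded)

    hits = {
        (f, d): binds_region(binding.get((f, d), ()), region)
        for f in factors
        for d in datasets
    }
    per_dataset = {d: all(hits[(f, d)] for f in factors) for d in datasets}
    qualifying = sum(per_dataset.values())
    if rule == "all_factors_per_dataset":
        occupied = qualifying >= min_datasets
    elif rule == "each_factor_min_datasets":
        occupied = all(sum(hits[(f, d)] for d in datasets) >= min_datasets for f in factors)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return OccupancyCall(gene=gene, per_dataset=per_dataset, qualifying_datasets=qualifying, occupied=occupied)


def call_all_genes(
    tss_records: Sequence[TSSRecord],
    binding: Mapping[tuple[str, str], Sequence[GenomicInterval]],
    **kwargs,
) -> pd.DataFrame:
    """Occupancy calls for every gene in the TSS table, as a tidy table."""
    table = {r.gene: r for r in tss_records}
    rows = []
    for gene in table:
        call = call_osn_occupancy(gene, table, binding, **kwargs)
        row: dict[str, object] = {"gene": gene}
        for d, ok in call.per_dataset.items():
            row[f"dataset_{d}"] = ok
        row["qualifying_datasets"] = call.qualifying_datasets
        row["occupied"] = call.occupied
        rows.append(row)
    return pd.DataFrame(rows)
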