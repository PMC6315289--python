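"""End-to-end pipeline runner: preprocess -> pseudotime -> KL ranking
(-> optional occupancy), with a JSON manifest of every stage output."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import io as tio
from .datatypes import CellRecord, CountMatrix, RunConfig, check_cells_aligned
from .preprocess import preprocess
from .pseudotime import fit_pseudotime, roughness_permutation_test
from .trajectory import kl_rank_genes

log = logging.getLogger("trajkl.pipeline")


class PipelineError(RuntimeError):
    """Raised when a stage fails; message carries the stage name and cause."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return wrapper

    return deco


def analyze(
    matrix: CountMatrix, cells: list[CellRecord], config: RunConfig, kl_genes: list[str] | None = None
) -> dict:
    """Run the in-memory analysis chain; returns a dict of stage results."""
    config.validate()
    check_cells_aligned(matrix, cells)

    working, surviving, report = _stage("preprocess")(preprocess)(matrix, cells, config)
    analysis_genes = list(report.analysis_genes.index)
    fit = _stage("pseudotime")(fit_pseudotime)(working.subset_genes(analysis_genes), surviving, config)
    rough = _stage("roughness_test")(roughness_permutation_test)(
        working.subset_genes(analysis_genes).subset_cells(fit.cell_ids),
        fit.tau_hat,
        config.n_permutations,
        config.seed,
    )
    kl_table = _stage("klrank")(kl_rank_genes)(working, fit, surviving, config, genes=kl_genes)
    return {
        "working": working,
        "cells": surviving,
        "report": report,
        "fit": fit,
        "roughness": rough,
        "kl_table": kl_table,
    }


def run_pipeline(
    config: RunConfig,
    counts_path: str | Path,
    metadata_path: str | Path,
    outdir: str | Path,
    counts_format: str | None = None,
    tss_path: str | Path | None = None,
    binding_paths: dict[tuple[str, str], str | Path] | None = None,
    kl_genes: list[str] | None = None,
) -> dict:
    """Read inputs, run all stages, write outputs and a manifest JSON.

    Returns the manifest dict. Reruns with identical config and seeds are
    bit-for-bit reproducible (the MCMC is seeded through the config).
    """
    config.validate()  # fail before any computation or I/O
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = _stage("read_counts")(tio.read_count_matrix)(counts_path, counts_format)
    cells = _stage("read_metadata")(tio.read_cell_metadata)(metadata_path, config.capture_set)
    _stage("read_metadata")(check_cells_aligned)(matrix, cells)

    res = analyze(matrix, cells, config, kl_genes=kl_genes)
    report = res["report"]
    fit = res["fit"]

    outputs: list[dict] = []

    def emit(name: str, path: Path, n_rows: int) -> None:
        outputs.append({"name": name, "path": path.name, "rows": int(n_rows)})

    p = outdir / "working_matrix.tsv"
    tio.write_count_matrix(res["working"], p)
    emit("working_matrix", p, len(res["working"].genes))

    p = outdir / "size_factors.tsv"
    report.size_factors.rename_axis("cell_id").to_frame().to_csv(p, sep="\t")
    emit("size_factors", p, len(report.size_factors))

    p = outdir / "analysis_genes.tsv"
    report.analysis_genes.rename_axis("gene").rename("variance_ratio").to_frame().to_csv(p, sep="\t")
    emit("analysis_genes", p, len(report.analysis_genes))

    p = outdir / "pseudotime.tsv"
    q = np.quantile(fit.tau_draws, [0.025, 0.5, 0.975], axis=0)
    pd.DataFrame(
        {
            "cell_id": fit.cell_ids,
            "capture_time_h": fit.capture_times,
            "tau_hat": fit.tau_hat.to_numpy(),
            "tau_q025": q[0],
            "tau_q500": q[1],
            "tau_q975": q[2],
        }
    ).to_csv(p, sep="\t", index=False)
    emit("pseudotime", p, len(fit.cell_ids))

    p = outdir / "roughness_test.json"
    p.write_text(json.dumps(res["roughness"].to_dict(), indent=2) + "\n")
    emit("roughness_test", p, 1)

    p = outdir / "kl_ranked.tsv"
    res["kl_table"].to_csv(p, sep="\t", index=False)
    emit("kl_ranked", p, len(res["kl_table"]))

    if tss_path is not None and binding_paths:
        from .occupancy import call_all_genes

        tss = _stage("osn")(tio.read_tss_bed)(tss_path)
        binding = {
            key: tio.read_bed_intervals(path) for key, path in binding_paths.items()
        }
        factors = sorted({f for f, _ in binding})
        datasets = sorted({d for _, d in binding})
        calls = _stage("osn")(call_all_genes)(
            tss,
            binding,
            factors=factors,
            datasets=datasets,
            up_bp=config.osn_up_bp,
            down_bp=config.osn_down_bp,
            min_datasets=config.osn_min_datasets,
            stranded=config.osn_stranded,
            rule=config.osn_rule,
        )
        p = outdir / "osn_occupancy.tsv"
        calls.to_csv(p, sep="\t", index=False)
        emit("osn_occupancy", p, len(calls))

    manifest = {
        "config": config.to_dict(),
        "preprocess_report": {
            k: v for k, v in report.to_dict().items() if not isinstance(v, dict)
        },
        "pseudotime_diagnostics": fit.diagnostics,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("wrote %d stage outputs to %s", len(outputs), outdir)
    return manifest
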