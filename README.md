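# trajkl

Capture-time-anchored pseudotime inference and KL-divergence trajectory
ranking for single-cell RNA-seq time courses, with transcription-factor
promoter-occupancy calling and a ground-truth synthetic data generator.

## What it does

Given a genes × cells count matrix and per-cell metadata (capture time in
hours, uniquely mapped read count), the pipeline:

1. **preprocess** — drops cells below a mapped-read threshold (default
   ≥ 6,000,000, inclusive), removes zero-variance transcripts, transforms
   counts as `log10(count + 1)`, excludes late-time-point cells whose
   transformed marker expression (default *Tfcp2l1*) strictly exceeds a
   threshold (default 1.5), computes median-of-ratios size factors on the
   raw counts of surviving cells, normalizes, and selects analysis genes
   (default 135) as a curated list plus the top genes by the ratio of
   between-capture-group to within-capture-group variance.
2. **pseudotime** — fits a Bayesian latent-time model: each cell's
   pseudotime has a `Normal(capture_time, sigma_tau^2)` prior (default
   σ_τ = 8 h) and each gene's expression is a GP over pseudotime with a
   shared squared-exponential length-scale (default l = 48 h), gene-specific
   amplitude and noise. The joint posterior is sampled with a built-in
   Hamiltonian Monte Carlo sampler (seeded, reproducible). The inferred
   ordering is validated with a permutation roughness test
   (root-mean-square successive differences vs random orderings).
3. **klrank** — fits a per-gene GP trajectory over the inferred pseudotimes
   (amplitude/noise by marginal-likelihood), evaluates the posterior at the
   median pseudotimes of the first and last capture groups, and ranks
   transcripts by the KL divergence between those two Gaussian posteriors
   (symmetrized by default; both one-sided directions available).
4. **osn** — calls per-gene OCT4/SOX2/NANOG occupancy: a stranded window
   from 20 kb upstream to 4 kb downstream of the TSS, occupied iff all
   three factors overlap the window in at least 2 of 3 binding datasets
   (BED intervals, 0-based half-open).

`trajkl.simulate` generates pseudotime-structured overdispersed counts
(down/up/flat gene classes with recorded truth), structure-free null
datasets, and toy binding landscapes with planted occupancy, so every stage
is testable without external data.

## CLI

```sh
# make a synthetic dataset (counts, metadata, truth, TSS + binding BEDs)
trajkl simulate --seed 1 --outdir data/

# full pipeline; writes stage TSV/JSON outputs plus manifest.json
trajkl run --counts data/counts.tsv --metadata data/metadata.tsv \
    --tss data/tss.bed --binding-dir data/ --outdir out/ \
    --kl-direction symmetrized --seed 1

# individual stages
trajkl preprocess --counts data/counts.tsv --metadata data/metadata.tsv --outdir pre/
trajkl pseudotime --working pre/working_matrix.tsv --metadata data/metadata.tsv --out tau.tsv
trajkl klrank --working pre/working_matrix.tsv --metadata data/metadata.tsv \
    --pseudotime tau.tsv --out ranked.tsv
trajkl osn --tss data/tss.bed --binding-dir data/ --out osn.tsv
```

`--config file.yaml` supplies any `RunConfig` field; explicit flags
override the file. All randomness flows from the configured seed; two runs
with the same config produce identical outputs.

## Layout

- `src/trajkl/datatypes.py` — `CellRecord`, `CountMatrix`, `RunConfig`
- `src/trajkl/io.py` — TSV/MatrixMarket/BED readers and writers
- `src/trajkl/preprocess.py` — QC, transform, size factors, gene selection
- `src/trajkl/pseudotime.py` — latent-time model, HMC fit, roughness test
- `src/trajkl/_hmc.py` — minimal HMC sampler (dual-averaging step size)
- `src/trajkl/trajectory.py` — per-gene GP trajectories, KL ranking
- `src/trajkl/occupancy.py` — TSS windows and occupancy calls
- `src/trajkl/simulate.py` — synthetic expression and binding landscapes
- `src/trajkl/pipeline.py` — end-to-end runner and manifest
- `src/trajkl/cli.py` — `trajkl` command
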