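# microcda

Compositional discriminant analysis of microbiome count tables: a tested,
reusable pipeline that discriminates two sample groups from 16S ASV (or
genus) abundance tables and calls differentially abundant taxa.

The pipeline has two independent branches plus a shared preparation layer:

- **tables** — TSV I/O and validation for count tables, QIIME2-style
  taxonomy maps, and two-group sample metadata; prevalence filtering
  (inclusive ≥50% per group), pseudocounts, genus collapsing (per-sample
  totals conserved exactly), hypergeometric rarefaction, and a PCA-based
  outlier screen.
- **diversity** — observed richness, Shannon (bits), Pielou evenness with
  Kruskal–Wallis tests; Bray–Curtis and Jaccard distances with PERMANOVA
  and PERMDISP (a significant dispersion test voids the location verdict).
- **compositional** — additive log-ratio (ALR) transformation with
  lowest-CV reference selection and Procrustes verification against the
  CLR geometry.
- **plsda** — two-class PLS-DA by NIPALS on auto-scaled predictors,
  Mahalanobis nearest-centroid prediction, balanced-error-rate (BER)
  cross-validation with a one-SD component rule, VIP scores, iterative
  VIP&nbsp;&gt;&nbsp;1 variable selection, aggregated confusion matrices, and a
  label-permutation test.
- **bayes** — per-variable Bayesian two-group linear model with flat
  priors solved by Gibbs sampling (vectorized across variables and
  chains), split-chain R-hat diagnostics, P0/PEP summaries, shortest 95%
  posterior intervals, and cumulative-PEP (q-value-like) relevance calls
  with a configurable effect-size reporting floor.
- **synth** — a logistic-normal/multinomial generator that mimics the
  study design (two groups, sparse features collapsible to genera, a
  dominant phylum, realistic read depths) and injects group effects
  directly in ALR-SD units, with a recorded ground truth per feature.
- **workflow** — YAML-config-driven orchestration of both branches with
  seeded, byte-reproducible report bundles, plus a genus-level rerun that
  cross-references ASV- and genus-level selections.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form unit
checks, a Gibbs-vs-Student-t oracle, null calibrations, parameter-recovery
simulations, structural invariants, and qualitative end-to-end analogs).
One acceptance test is deliberately left failing:
`test_null_run_yields_no_relevant_taxa` documents that selecting variables
on the full data and then validating only the selected subset is
anticonservative under the global null — the surviving variables are the
extremes of hundreds of null association statistics, so some are always
called relevant.  See `notes` in the project history for the full analysis.

## Command line

```bash
# generate a synthetic dataset
microcda simulate --spec spec.yaml --out-dir data/

# full two-branch comparison (optionally also collapsed to genus level)
microcda run --config cfg.yaml --genus

# individual stages
microcda diversity --counts data/counts.tsv --metadata data/metadata.tsv \
    --depth 10000 --out out/diversity.json
microcda plsda --counts data/counts.tsv --metadata data/metadata.tsv \
    --out-dir out/
microcda bayes --alr out/alr.tsv --metadata data/metadata.tsv \
    --out out/da.tsv
```

A minimal `cfg.yaml`:

```yaml
comparison: lines
counts_path: data/counts.tsv
taxonomy_path: data/taxonomy.tsv
metadata_path: data/metadata.tsv
rarefaction_depth: 10000
seed: 1
out_dir: out/lines
```

Replace the input paths with a `synthetic:` block (any `SyntheticSpec`
field, plus `n_diff`) to run on generated data.

## Reproducibility

Every stochastic step takes an explicit seed; report bundles embed the
config hash and seed, and re-running a fixed config reproduces all output
files byte for byte.
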