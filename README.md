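# pairedwgcna

Weighted gene co-expression network analysis (WGCNA) for **paired-design**
expression data (e.g. tumour / matched-normal samples from the same
subjects).

The classical WGCNA pipeline assumes independent samples. This package
implements the paired-design variant:

* **Similarity** `s_ij = |cor(x_i, x_j)|` over all pooled samples. Pooled
  Pearson correlation remains valid under a two-component (control/case)
  mixture — the closed-form mixture correlation and a Monte-Carlo verifier
  are provided (`mixture_correlation`).
* **Soft thresholding** `a_ij = s_ij^beta`, with `beta` chosen as the first
  peak of the signed scale-free fit index (log10 frequency vs log10
  connectivity regression over binned connectivity).
* **Modules** via average-linkage clustering on `dissTOM = 1 − TOM`
  (unsigned topological overlap), tree cut with a minimum module size,
  unassigned genes in the reserved `grey` module, module eigengenes (first
  principal component) and module membership `MM = cor(gene, ME)`.
* **Paired association** — the key modification: a random-intercept linear
  mixed-effects model per response (module eigengene or single gene),
  `y_ij = b_i + beta1·condition + covariates + e_ij`, fitted by exact
  closed-form REML for the balanced paired layout. Without covariates the
  condition test is numerically identical to the classical paired t-test
  (df = n_pairs − 1). Gene significance `GS = |t|`, module significance
  `MS = mean GS`.
* **Hubs** — module edge lists after dichotomizing the weighted network,
  degrees, deterministic hub selection, Cytoscape-loadable SIF/TSV export.
* **Sample QC** — PCA overview, dendrogram-based outlier flagging, and
  pair-consistent exclusion (a flagged sample removes its matched partner
  too, keeping the design fully paired).
* **Synthetic data** — paired two-condition generator with planted
  co-expression modules, per-pair random intercepts and condition shifts,
  plus recovery scoring (ARI, shift bias, hub hits).

## CLI

```sh
# generate paired data with planted modules
pairedwgcna simulate --seed 1 --n-pairs 38 \
    --modules 250:0.8:1.0,190:0.8:0.5,80:0.8:0.0 --out-dir sim

# full pipeline: QC -> network -> modules -> association -> hubs
pairedwgcna run --expr sim/expression.tsv --design sim/design.tsv \
    --covariates age,stage --out-dir results

# individual stages
pairedwgcna qc --expr e.tsv --design d.tsv
pairedwgcna network --expr e.tsv --beta-grid 1:20
pairedwgcna modules --expr e.tsv --design d.tsv --min-module-size 30
pairedwgcna associate --expr e.tsv --design d.tsv --modules modules.tsv
pairedwgcna hubs --expr e.tsv --modules modules.tsv --module turquoise
```

`run` also accepts a TOML config (`--config run.toml`); every flag overrides
its config key. Outputs are TSV/SIF/Newick plus a `summary.json` whose hash
is reproducible for identical inputs and configuration.

Input formats: expression TSV/CSV (genes in rows, first column gene id,
header sample ids; orientation is explicit, never guessed), design TSV with
columns `sample_id`, `pair_id`, `condition` (0=control, 1=case) and optional
subject-level covariates, and GEO series-matrix text files (`--geo`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: mixture-identity
vs Monte Carlo, paired-t equivalence of the mixed model, type-I error
calibration, TOM brute-force oracle, planted-module recovery, and the
scale-free scan. The real-data replication test is skipped unless the GEO
dataset has been downloaded (see below).

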