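# vaxbiome

Analysis pipeline linking baseline gut-metagenome composition to
vaccine-induced immune reactivity:

- **synthetic** — multi-cohort synthetic data generator (zero-inflated
  compositional abundance profiles with planted cluster-associated taxa,
  cohort batch effects, cytokine panels with planted responders,
  negative-binomial gene-family counts) with full ground truth.
- **io** — MetaPhlAn-style merged abundance tables, gene-family /
  cytokine / metadata TSVs, analysis configuration and hashes.
- **reactivity** — immunoassay positivity rules (multiplex delta/ratio,
  whole-blood ratio, fixed IFN-γ threshold), low-frequency analyte
  filtering, binary-distance + Ward.D2 responder clustering, median
  splits and booster-response calls.
- **ecology** — richness / Shannon / inverse-Simpson, Bray–Curtis
  dissimilarities, classical MDS, seeded PERMANOVA, intra- vs
  inter-individual distance comparison (Kruskal–Wallis + Dunn).
- **diffab** — per-taxon gamma GLM (log link) and per-gene
  negative-binomial GLM with covariate adjustment and
  Benjamini–Yekutieli FDR.
- **meta** — inverse-variance random-effects meta-analysis with
  Paule–Mandel heterogeneity estimation and the minimum-two-cohorts
  pooling rule.
- **ml** — random-forest benchmarks: repeated stratified CV,
  leakage-free training-fold top-k feature selection, LODO, X-LODO and
  cross-prediction matrices.
- **toposcore** — SIG1 / Grey / SIG2 classification from configured
  species lists plus category-frequency comparisons (Fisher /
  chi-squared).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form
and brute-force oracles, simulation calibrations, end-to-end parameter
recovery); the remaining files are per-module unit and property tests.

## CLI

All functionality is exposed through the `vaxbiome` entry point
(`vaxbiome --help` lists global flags `--config`, `--seed`,
`--log-level`):

```sh
vaxbiome simulate --out-dir data/ --seed 1            # synthetic cohorts
vaxbiome reactivity --cytokines data/cohort01_cytokines.tsv \
    --rule multiplex --out-dir out/rx
vaxbiome diversity --abundance data/cohort01_abundance.tsv \
    --clusters out/rx/clusters.tsv --out-dir out/div
vaxbiome diffab --abundance data/cohort01_abundance.tsv \
    --metadata data/cohort01_metadata.tsv \
    --clusters out/rx/clusters.tsv --cohort cohort01 --out out/assoc1.tsv
vaxbiome meta --associations out/assoc1.tsv --associations out/assoc2.tsv \
    --out out/meta.tsv
vaxbiome ml --abundance data/cohort01_abundance.tsv \
    --clusters out/rx/clusters.tsv --folds 5 --reps 2 --trees 100 \
    --seed 1 --out-dir out/ml
vaxbiome toposcore --abundance data/cohort01_abundance.tsv \
    --sig-config sig.json --out-dir out/topo
vaxbiome report --in-dir out/ --out summary.json
```

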