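# evomark

Evolution-informed biomarker selection and outcome prediction for binary
clinical endpoints.

Evolutionary conservation — estimated from protein multiple sequence
alignments on a time-calibrated species tree — is converted into per-feature
weights that, together with outcome-association weights, steer sparse
logistic-regression stability selection. The selected biomarkers feed a
class-balanced random-forest ensemble that predicts outcomes with confidence
scores.

## Method overview

1. **Conservation** (`evomark.phylo`): for each alignment column, the tree is
   pruned to the taxa carrying a residue; the column's time span `t` is the
   pruned tree's total branch length (Myr), the substitution count `s` is the
   number of distinct residues (or minimum-change parsimony in `fitch` mode),
   and the absolute rate is `r = 1000·s/t` (subst/Byr). The gene rate `R` is
   the mean `r` over countable columns; the evolutionary weight is `WE = 1/R`.
2. **Weighting** (`evomark.weighting`): statistical weight
   `WS = -log10(p)` from a two-sample t-test per feature; composite
   `W = WE + WS`. Clinical covariates, having no conservation score, receive
   the maximum molecular `WE`. Features are z-scored (sample sd), then
   multiplied by `W` before selection — equivalent to a per-feature l1
   penalty of `λ/W`.
3. **Selection** (`evomark.selection`): l1-penalized logistic regression
   (FISTA + soft-thresholding, unpenalized intercept) fitted along a
   descending λ grid over class-stratified bootstraps; features kept when
   selected in strictly more than 50% of runs.
4. **Ensemble** (`evomark.ensemble`): 100 balanced undersamples (90% of the
   minority class from each class), one stability selection + 50-tree random
   forest per subset, trained on *unweighted* values of the selected
   features. Confidence = fraction of submodels voting positive; the label
   requires a strict majority.
5. **Evaluation** (`evomark.metrics`): balanced accuracy and rank-based
   AUROC, with repeated stratified train/test splits fitting all
   data-dependent parameters on the training side only.
6. **Fixtures** (`evomark.simulate`): ultrametric trees, Poisson-process
   protein alignments with known site rates, and cohorts with planted
   informative features whose conservation is coupled to informativeness.

## CLI

```sh
# per-gene evolutionary rates from aligned FASTAs + a Newick time tree (Myr)
evomark rates --alignments aln_dir/ --tree tree.nwk --reference human \
    --mode distinct --out rates.tsv

# composite weights from a labeled feature table + metadata + rates
evomark weights --features data.tsv --meta meta.tsv --rates rates.tsv \
    --label-col outcome --out weights.tsv

# train / predict / evaluate
evomark train --features data.tsv --meta meta.tsv --rates rates.tsv \
    --config run.yaml --seed 1 --out model/
evomark predict --model model/ --features new.tsv --out predictions.tsv
evomark evaluate --model model/ --features test.tsv --labels-col outcome \
    --out report.json

# synthetic fixture set (tree, alignments, cohort, truth)
evomark simulate --seed 1 --out-dir fixtures/

# four-way weighted/unweighted comparison with matched splits
evomark compare --features data.tsv --meta meta.tsv --rates rates.tsv \
    --modes es,e,s,0 --out comparison.json
```

Feature tables are CSV/TSV with a sample-id first column and a binary label
column (`0/1` or `good/poor`); metadata tables carry `feature_id`, `kind`
(`molecular`/`clinical`) and `gene_id`. Config is YAML with the fields of
`evomark.config.RunConfig` (defaults: 100 submodels, 100 inner bootstraps,
stability threshold 0.5, 50 trees, 90% undersampling).

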