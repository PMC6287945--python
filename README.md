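# methage

Build, apply, and compare DNA-methylation age predictors ("clocks") on
RRBS-style data: coverage-based QC filters, tissue-stratified elastic-net
training with cross-validation, linear clock models over CpG percent
methylation, a statistical battery for clock comparison and intervention
effects, clock-site robustness resampling, and a synthetic methylome
simulator so the whole pipeline is testable without external data.

## Package layout

| module | contents |
|---|---|
| `methage.types` | `CpGSite`, `SampleMethylome`, `MethylationMatrix`, `ClockDefinition`, `TransformSpec`, `AgePrediction` |
| `methage.io` | bismark coverage / cytosine-report parsing, strand merging, matrix assembly, clock + metadata TSV round-trips |
| `methage.qc` | sample site-count filter, soft coverage cutoff, common-site intersection, tissue-stratified split, optional PCA outlier flag |
| `methage.enet` | in-repo elastic net: standardization, lambda path, cyclic coordinate descent, stratified K-fold CV (MSE-min or 1-SE selection) |
| `methage.build` | `train_clock`, `evaluate_clock`, `resample_clocks`, `robustness_stats` |
| `methage.predict` | `predict_age` with explicit missing-site policies, coverage accounting, age transforms |
| `methage.stats` | exact / tie-corrected Mann-Whitney U, Yates chi-square, Bartlett, Benjamini-Hochberg |
| `methage.compare` | pairwise clock error comparison, residual-slope test, group regression comparison, intervention delta-age tests, correlation matrices, weight-distribution tests |
| `methage.sites` | clock-site overlaps, gene-overlap chi-square, CpG island / shore / shelf / open-sea annotation, chromosome representation |
| `methage.simulate` | age-structured synthetic RRBS cohorts (methylation drift toward intermediate states, negative-binomial depth, binomial counts, dropout, tissue/batch effects) |
| `methage.cli` | `methage` command with subcommands and per-run manifests |

## CLI

Every subcommand writes a `manifest.json` (resolved config, seeds, input
digests, version) next to its outputs.

```bash
# synthetic cohort (S1 preset: 200 samples x 2000 sites, 40 age-informative)
methage simulate --preset S1 --out cohort/

# QC chain: sample filter -> union matrix -> soft coverage cutoff -> common sites
methage qc --coverage-dir cohort/ --metadata cohort/metadata.tsv \
           --min-common 0 --out qc/

# train a clock (80/20 tissue-stratified split, 10-fold CV elastic net)
methage train --matrix-dir qc/ --l1-ratio 1.0 --lambda-selection 1se \
              --seed 7 --out clock/

# apply any clock definition
methage predict --clock clock/clock.tsv --matrix-dir qc/ --out preds/

# compare >= 2 clocks on shared samples (MAE + pairwise MWU + correlations)
methage compare --predictions preds/predictions.tsv \
                --predictions other/predictions.tsv \
                --metadata cohort/metadata.tsv --out cmp/

# robustness: retrain under resampled splits, count site appearances
methage robustness --matrix-dir qc/ --n-resamples 100 --base-seed 0 --out rob/

# site-set analyses
methage overlap --clock-a clock/clock.tsv --clock-b other.tsv --out ov/
methage annotate --clock clock/clock.tsv --islands islands.bed --out ann/
```

Notes on training configuration: the defaults (`--l1-ratio 0.5`,
`--lambda-selection min`) minimize cross-validated prediction MSE and tend
to produce dense, heavily shrunk models. For support recovery (selecting the
truly age-informative sites) use the sparse configuration
`--l1-ratio 1.0 --lambda-selection 1se`.

## Clock definition format

Plain TSV with `#key=value` headers:

```
#name=my_clock
#intercept=234.64
#transform=identity
#min_site_fraction=0.9
#strand_policy=forward_only
chrom	pos_1based	weight	train_mean
chr1	3100007	0.8124	45.2
...
```

Transforms: `identity`, `exp_linear;a=..;b=..` (age = exp(a*score + b), for
clocks trained on log age), `logistic;a=..;b=..;c=..`. Weights are days per
percent methylation; methylation inputs are always percent (0-100).
Coordinates are 1-based (genome-browser style); BED I/O converts at the
boundary.

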