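# hofcnet

Estimation and evaluation of high-order functional connectivity networks
(HoFCNs) from ROI time series.

A low-order connectivity network links brain regions whose signals co-vary.
A *high-order* network instead captures how the connectivity pattern itself
co-varies over time: low-order networks are estimated in sliding windows,
treated as samples from a matrix-variate normal distribution, and the shared
row/column covariance is recovered by a damped maximum-likelihood fixed
point.  That initial estimate is then refined by a proximal algorithm toward
a nearby network that is sparse (l1 prior) or sparse and low-rank
(l1 + trace-norm prior, which induces modular block structure).  A nested
leave-one-out cross-validation harness evaluates the resulting edge-weight
features with t-test selection and a linear SVM.

## Layout

| module | contents |
| --- | --- |
| `hofcnet.lowfcn` | column standardization, full-correlation and sparse-representation networks, sliding windows, magnitude thresholding |
| `hofcnet.hofcn_mle` | matrix-normal MLE fixed point for the initial high-order network |
| `hofcnet.hofcn_prox` | soft-thresholding, singular-value thresholding, sparse / modular refinement |
| `hofcnet.classify` | edge features, t-test selection, linear SVM, nested LOOCV, ACC/SEN/SPE |
| `hofcnet.synthetic` | seeded generators: modular-covariance BOLD series, matrix-normal samples, two-class cohorts with planted edge effects |
| `hofcnet.io_cli` | delimited text formats, run configuration, CLI entry points |

## CLI

All data are plain tab-delimited text (time series V x P, networks P x P with
label header row and column, manifests with `subject_id  path  label`).
Every command writes a JSON record of its resolved configuration; identical
configuration + seed yields byte-identical outputs.

```sh
# synthetic two-class cohort: 10 subjects, 20 ROIs, 60 volumes
hofcnet simulate --out cohort/ --subjects 10 --rois 20 --volumes 60 --seed 7 \
    --n-affected-edges 5 --effect-size 0.5

# one network file per subject (pc | sr | hofcn_mle | s_hofcn | m_hofcn)
hofcnet estimate --manifest cohort/manifest.tsv --out nets/ --method pc

# nested LOOCV evaluation with per-fold and summary rows
hofcnet classify --manifest cohort/manifest.tsv --out eval.tsv --method m_hofcn \
    --window-width 30 --window-step 10

# repeat the evaluation over several (window width, step) settings
hofcnet sweep --manifest cohort/manifest.tsv --out sweep.tsv --method s_hofcn \
    --windows 50:1,70:1,70:2
```

Defaults follow the evaluated protocol: regularizer grid `2^-5 ... 2^5`,
eleven sparsity levels `1%, 10%, ..., 100%` for the un-regularized
estimators, pooled two-sample t-test at p = 0.05, linear SVM with C = 1.
A flat `key = value` config file (`--config`) can override any setting.

## Notes

* The raw MLE fixed-point map can oscillate; the iteration is damped
  (default 0.5), which preserves its fixed points.  Near-singular iterates
  are handled by an escalating diagonal jitter before inversion.
* With the default proximal step size alpha = 1/2 the refinement collapses
  to the sequential proximal maps `SVT_mu2(soft_mu1(omega0))`; alpha is
  configurable, and an `ista_scaling` switch applies step-size-scaled
  thresholds instead of the literal ones.
* Inside every cross-validation fold the selected features are z-scored
  with training-side statistics before the SVM, making the fixed C
  meaningful regardless of the estimator's weight scale.
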