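# lsfactor

Interpretable overlapping latent-factor regression for cluster-wise
pseudobulk single-cell transcriptomes, with Gaussian-knockoff FDR control,
permutation-tested cross-validation, cross-cohort transfer, and
correlation-network reporting.

## The problem

Case/control single-cell skin studies — here modeled on a localized
scleroderma (morphea) cohort of 44 biopsies (27 cases, 17 controls, with
adult and pediatric substructure) — need more than predictive biomarkers:
the goal is to find *coexpression modules* (sets of cluster-specific gene
features that rise and fall together across samples) that are statistically
tied to a clinical response, whether a binary disease label, an adult/
pediatric contrast, or a continuous severity score such as the mLoSSI.

`lsfactor` implements that analysis as a tested, reusable pipeline:

1. **Pseudobulk features.** Cells pass strict QC (detected genes strictly
   between 200 and 5,500; mitochondrial fraction < 25%; ribosomal fraction
   < 55%), are depth-normalized and log1p-transformed, and are aggregated
   per (sample, cluster) into mean expression. Within each cluster the 50
   genes with the highest across-sample variance are kept; 31 clusters
   yield 1,550 `cluster:gene` features.
2. **Overlapping latent factors.** The standardized matrix X (n samples ×
   p features) is decomposed under the model X = Z Aᵀ + E, where A is a
   sparse, possibly overlapping weight matrix anchored by *pure variables*
   — features loading on exactly one factor. Pure-variable clusters are
   detected from the feature correlation matrix; remaining features are
   allocated by per-feature lasso on the pure-factor scores, so overlap
   arises wherever two or more loadings survive the penalty. Sample scores
   are the least-squares projection Ẑ = X A (AᵀA)⁻¹.
3. **Significance with FDR control.** Second-order Gaussian knockoffs Z̃
   (equicorrelated construction, Ledoit–Wolf-regularized covariance) feed a
   knockoff filter on the lasso signed-max statistic at target FDR
   q = 0.05, for marginal factors and — hierarchically — factor×factor
   interactions.
4. **Validation.** Repeated stratified k-fold cross-validation with the
   entire pipeline refit inside every training fold, label-permutation
   nulls compared by one-sided rank-sum test, grouped anatomical-site
   holdout (train on trunk, test on extremity, and vice versa), and
   cross-cohort prediction: a frozen weight matrix and coefficients applied
   to a feature-matched external cohort, with factor preservation measured
   by matched cosine similarity.
5. **Reporting.** Per significant factor: top genes by loading and by
   univariate predictiveness, direction of association, and a signed
   Pearson correlation network over those features thresholded at
   |r| > 0.25 (purple = positive, green = negative), exported as GraphML
   and TSV.

A fully seeded synthetic-cohort generator (negative-binomial cells with
cluster structure and QC violators; pseudobulk with planted overlapping
factors and known response coefficients) makes every stage testable without
any data download.

## Worked example

```python
import numpy as np
import lsfactor as lf

cfg = lf.CohortConfig(n_clusters=10, genes_per_cluster_pool=30, seed=3)
pb, y, truth = lf.plant_pseudobulk(cfg, K=10, snr=5.0)
print(f"cohort: {pb.n_samples} samples x {pb.n_features} features "
      f"({int(y.sum())} case / {int((1 - y).sum())} control)")

bundle = lf.fit_pipeline(pb, y.to_numpy(), lf.PipelineSpec(task="binary"), seed=0)
print(f"estimated factors: K={bundle.model.K}")
print(f"knockoff-selected at q=0.05: {bundle.selection.selected_marginal}")

report = lf.permutation_null(pb, y.to_numpy(), k=5, n_repeats=10, n_perms=20,
                             spec=lf.PipelineSpec(task="binary"), seed=0)
print(f"held-out AUC: {np.mean(report.metrics):.3f} "
      f"(permuted-label null {np.mean(report.null_metrics):.3f}, "
      f"rank-sum p = {report.p_value:.2e})")

Xs = lf.standardize(pb)
factor = bundle.selection.selected_marginal[0]
nodes = lf.top_genes(bundle.model, factor, Xs, y.to_numpy())
net = lf.correlation_network(nodes, Xs)
print(f"{factor}: {len(nodes)} top features, "
      f"{net.graph.number_of_edges()} network edges with |r| > 0.25")
```

prints exactly:

```
cohort: 44 samples x 300 features (16 case / 28 control)
estimated factors: K=13
knockoff-selected at q=0.05: ['LF6', 'LF9', 'LF11']
held-out AUC: 0.973 (permuted-label null 0.490, rank-sum p = 5.88e-06)
LF6: 16 top features, 120 network edges with |r| > 0.25
```

The pipeline estimated 13 candidate modules from 300 features on 44
samples, the knockoff filter kept 3 of them at q = 0.05, and repeated
5-fold cross-validation separated cases from controls with mean held-out
AUC 0.973 against a permutation null centered at chance — i.e. the selected
modules carry genuine signal, not correlation-structure artifacts.

A command-line interface mirrors the library:

```bash
lsfactor simulate --seed 1 --out runs/sim          # cohort + pseudobulk to disk
lsfactor preprocess --cells runs/sim/cells --out runs/pb
lsfactor run --config run.yaml --out runs/case_control
```

`run.yaml` names one of the four study designs (`case_control`,
`adult_only`, `age_contrast`, `severity` — the last residualizes sex from
the severity score before regression) plus all hyperparameters; every run
writes a manifest sufficient to reproduce its outputs byte for byte.

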