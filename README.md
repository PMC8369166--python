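# tmelearn

Systems-level signatures of the tumor microenvironment (TME) and multi-task
models of immune response from bulk RNA-seq.

From a genes × samples TPM matrix plus prior-knowledge files, the package
derives five feature matrices ("views"):

| view       | features | derivation |
|------------|----------|------------|
| `cellfrac` | 11       | immune cell fractions by non-negative least-squares deconvolution on a cell-type signature matrix (10 immune types + unclassified remainder; the CD4 column reports non-regulatory CD4 + Treg, Treg kept separately) |
| `pathways` | 14       | pathway activities as weighted sums of z-scored perturbation-response signature genes |
| `tfs`      | per regulon set | TF activities as normalized enrichment scores over rank-transformed target expression (confidence A/B regulons, ≥5 present targets) |
| `lrpairs`  | per database | ligand-receptor pair weights, min log2(TPM+1) over the pair's genes; identical columns grouped |
| `ccpairs`  | 169      | cell-cell interaction scores over ordered pairs of 13 aggregated cell types: sum of inverse reference-cohort frequencies of the active LR pairs assigned to each sender→receiver pair |

These views feed two multi-task learners trained against transcriptome-based
immune-response proxy scores (cytolytic activity, weighted/rank-normalized
gene-signature means, gene-pair logic scores, sign-anchored PC1 scores):

* **RMTLR** — regularized multi-task linear regression with a grouped
  elastic-net penalty (feature rows are selected for all tasks or none),
  fitted by block coordinate descent, hyperparameters by 5-fold CV.
* **BEMKL** — Bayesian efficient multiple-kernel learning: variational
  regression over Gaussian view-kernels with kernel weights shared across
  tasks and task-specific sample weights.

Training repeats 100× with randomized 80/20 splits (test standardized with
training statistics). RMTLR ensembles yield a robust-biomarker table (median
weight across runs then tasks, Wilcoxon tests against zero, low-consistency
flags); predictions on new cohorts average the 100 models per view, and the
ensemble score averages the single-view predictions. Tumor mutational burden
can be blended in via a tertile penalty (`P + c·γ`) or a weighted average of
0–1-scaled scores (`(1−η)·P + η·TMB`).

A seeded synthetic module generates priors, Dirichlet cell mixtures with
spiked pathway/TF/LR structure, and responder labels driven by a latent
immune-activity factor, so the whole pipeline is testable offline.

## CLI

```bash
tmelearn simulate --out sim/ --seed 3 --n-samples 200
tmelearn views    --expr sim/expression.tsv --priors sim/priors.yaml --out views/
tmelearn scores   --expr sim/expression.tsv --priors sim/priors.yaml --out tasks.tsv
tmelearn train    --views views/ --view cellfrac --tasks tasks.tsv \
                  --n-runs 100 --seed 1 --out model.json
tmelearn biomarkers --model model.json --out biomarkers.tsv
tmelearn predict  --model model.json --expr sim/expression.tsv \
                  --priors sim/priors.yaml --labels sim/labels.tsv --out pred.tsv
```

All artifacts are TSV/JSON/YAML; every output directory carries a
`provenance.json` with the seed and parameters.

## Python API sketch

```python
from tmelearn import io, scores, synthetic, training, views, evaluate

priors = synthetic.make_priors(seed=0)
expr, truth = synthetic.make_cohort(priors, n_samples=300, seed=0)
tasks = scores.compute_task_matrix(expr, priors.score_definitions)
cellfrac = views.deconvolve_cell_fractions(expr, priors.cell_signature)
ensemble = training.run_randomized_cv(cellfrac, tasks, n_runs=100, seed=1)
biomarkers = training.extract_biomarkers(ensemble)
io.save_model(ensemble, "model.json")
```

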