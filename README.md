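# dsplmf

Drug-sensitivity classification for cancer cell lines by
**neighborhood-regularized logistic matrix factorization**.

Given a panel of cell lines with multi-omic features (gene expression,
copy-number alteration, binary mutation calls), an IC50 response matrix over
a drug panel, and per-drug substructure fingerprints, the package

1. binarizes IC50 per drug at its median into a sensitive/resistant
   observation matrix *Q* (sensitive = IC50 strictly below the median);
2. embeds cell lines and drugs in a shared latent space, modeling
   *p(sensitive)* = σ(*u<sub>i</sub>·v<sub>j</sub>* + β<sup>c</sup><sub>i</sub> + β<sup>d</sup><sub>j</sub>),
   with graph penalties that pull the latent vectors of *k*-NN-similar cell
   lines (by a weighted blend of the four omics/response similarities) and
   *k*-NN-similar drugs (by fingerprint Jaccard) together;
3. predicts for cell lines never seen in training, whose IC50 profile — and
   hence latent vector — is unknown: a decision tree learns to recognize
   "IC50-neighbor" relationships from the three omics similarities, and the
   new line's latent vector is the average over the flagged neighbors;
4. evaluates by repeated cell-line-level cross-validation (accuracy, recall,
   precision, specificity, F1, MCC, AUC), and
5. correlates pathway activity scores (median-centered log2 fold-change sums
   over gene sets) with predicted responses to flag "assistant" (sensitizing)
   and "resistant" pathways per drug.

## Model

The training objective minimized over *U*, *V*, β<sup>c</sup>, β<sup>d</sup> is

```
J = Σ_ij [(1 + r·q_ij − q_ij)·log(1 + e^{z_ij}) − r·q_ij·z_ij]
    + ½ tr[Uᵀ(λ_c I + α H^c) U] + ½ tr[Vᵀ(λ_d I + β H^d) V]
```

with z<sub>ij</sub> the linear predictor, *r* ≥ 1 an importance weight for
observed sensitive pairs (default 1: both classes equally trusted), λ the
Gaussian-prior precisions, and H = (E + Ẽ) − (A + Aᵀ) the regularization
matrix of the directed k-NN adjacency A, which satisfies
Σ<sub>ij</sub> a<sub>ij</sub>‖x<sub>i</sub> − x<sub>j</sub>‖² = tr(Xᵀ H X).
Optimization is alternating AdaGrad (drug side, then cell-line side, each
epoch). Details, defaults and design choices: [docs/methods.md](docs/methods.md).

## Worked example

Every capability has a narrative script under `examples/`; they run on
synthetic cohorts with planted low-rank structure, so no downloads are
needed. For instance:

```bash
$ python examples/04_cross_validation.py
full pipeline   : {'accuracy': 0.756, 'recall': 0.804, 'precision': 0.731,
                   'specificity': 0.712, 'f1': 0.763, 'mcc': 0.515, 'auc': 0.839}
random latents  : {'accuracy': 0.502, 'recall': 0.504, 'precision': 0.498,
                   'specificity': 0.5, 'f1': 0.498, 'mcc': 0.004, 'auc': 0.517}
accuracy attributable to neighbor imputation: 0.253
```

Reading: 5-fold cross-validation (3 repeats) on a 60-cell-line × 10-drug
planted cohort classifies held-out (cell line, drug) pairs with 0.756
accuracy and 0.839 AUC; replacing the neighbor-imputed latent vectors with
random draws collapses performance to chance (0.502), so about 25 accuracy
points are carried by the neighborhood machinery — the package's central
claim, reproduced end to end.

A minimal library session:

```python
from dsplmf import FixtureSpec, generate, fixture_hyperparams, cross_validate

ds, truth = generate(FixtureSpec(seed=1))        # synthetic cohort
hp = fixture_hyperparams(seed=1)                 # cohort-scaled settings
summary = cross_validate(ds, hp, folds=5, repeats=3, seed=1)
print(summary.mean)                              # pooled metrics
```

Real data enter through `dsplmf.datasets`: `load_matrix` reads delimited
TSV/CSV tables (header identifiers, label column; `NA`/empty = missing),
`from_frames` aligns them into a cohort, `filter_cell_lines` drops lines with
more than 50 % missing values, and `impute_missing_knn` fills the rest from
the k nearest cell lines in expression space.

A thin CLI mirrors the library: `dsplmf synth | preprocess | fit | cv |
predict | pathway` (see `dsplmf --help`).

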