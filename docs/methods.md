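# Methods

## Problem and model

The package classifies cancer cell lines as *sensitive* or *resistant* to
each drug in a panel. Sensitivity is defined per drug relative to the
cohort: a cell line is sensitive to drug *j* iff its IC50 is strictly below
the median IC50 of drug *j* over the (training) cohort. The median is used
as a single universal cut because IC50 histograms vary in skew across drugs;
the median of an even-length column is the mean of the two middle values,
and ties at the median are labeled resistant (the rule is strict "below").

The resulting binary matrix Q (cell lines × drugs) is modeled by logistic
matrix factorization: each cell line *i* and drug *j* carries a latent
vector (u_i, v_j ∈ R^L) and a scalar bias (β^c_i, β^d_j) absorbing global
responsiveness ("this line responds to most drugs", "most lines resist this
drug"), and

    p_ij = σ(z_ij),   z_ij = u_i · v_j + β^c_i + β^d_j.

The fit minimizes the negative log-posterior

    J = Σ_ij [(1 + r q_ij − q_ij) log(1 + e^{z_ij}) − r q_ij z_ij]
        + ½ tr[Uᵀ(λ_c I + α H^c)U] + ½ tr[Vᵀ(λ_d I + β H^d)V],

where the first sum is a weighted Bernoulli deviance (r ≥ 1 up-weights
observed sensitive pairs; default r = 1 because both classes are equally
trustworthy here — sensitivity labels are not "verified interactions" as in
recommender settings), λ_c = 1/σ_c², λ_d = 1/σ_d² are the precisions of
zero-mean spherical Gaussian priors on the latent vectors, and the trace
terms are neighborhood penalties described next. The additive constant of
the log-posterior is dropped. Biases are left unconstrained: the gradient
updates take no projection, and the model is invariant to that choice up to
reparameterization (a non-negativity projection flag exists, default off).

## Neighborhood regularization

Cell-line similarity is a weighted average of four matrices — Pearson
correlation of expression profiles, of copy-number profiles and of IC50
profiles, and Jaccard similarity of binary mutation profiles:

    Sim_total = (w_exp S_exp + w_cnv S_cnv + w_mut S_mut + w_ic50 S_IC50) / Σw.

Before combining, a collinearity table (Pearson correlation of the
vectorized strict upper triangles) can be inspected; on real cohorts the
four matrices are built from largely disjoint gene panels and correlate
weakly, which is what justifies a linear blend. Drug similarity is the
Jaccard index on 881-bit substructure fingerprints.

From a similarity matrix, a *directed* k-NN adjacency A keeps, in row i,
the similarity values of i's k most-similar peers (ties at the k-th rank
broken by ascending index for reproducibility). Its regularization matrix

    H = (E + Ẽ) − (A + Aᵀ),

with E and Ẽ the diagonal matrices of row and column sums of A, satisfies
Σ_ij a_ij ‖x_i − x_j‖² = tr(Xᵀ H X); A is deliberately *not* symmetrized —
the (A + Aᵀ) term handles asymmetry exactly. tr(Uᵀ H^c U) therefore
penalizes latent spread across neighbor links, pulling similar cell lines
(and, via H^d, similar drugs) together in latent space. The identity is
enforced by a brute-force pairwise-sum oracle in the tests; the latent
gradient uses the full matrix-row product (λ_c I + α H^c)U, validated
against central finite differences.

Conventions in the similarity layer: Jaccard of two empty sets is 0
(featureless entities are not maximally similar); zero-variance rows get
Pearson similarity 0 rather than NaN, with a logged warning.

## Optimization

Alternating AdaGrad: each epoch first updates (V, β^d) with the cell-line
side fixed, then (U, β^c) with the drug side fixed. Every parameter steps
by `rate / sqrt(accumulated squared gradient + ε)` with rate 0.1 and
ε = 1e−8; 300 epochs by default (200 for the small synthetic cohort). These
optimizer settings are implementation defaults chosen so every bundled
fixture converges; they are fully configurable. U and V initialize i.i.d.
Normal(0, 1/L) — the 1/L variance keeps initial linear predictors O(1) for
any latent dimension — and biases at 0. Training is deterministic given the
seed; the objective trajectory (initial value plus one value per epoch) is
returned for descent diagnostics. A non-finite objective aborts with a
diagnostic naming the offending entry.

`fit` optionally accepts an observation mask excluding entries from the
data term (the regularizers always apply); this supports held-out-entry
assessment of the factorization itself, separate from the new-cell-line
prediction path.

## Predicting unseen cell lines

A new cell line has no IC50 profile, so S_IC50 — and hence its latent
vector — cannot be formed directly. Instead, a decision-tree classifier
(scikit-learn, unconstrained depth by default, fixed seed) is trained on
ordered training pairs (i, j) with features (S_exp(i,j), S_cnv(i,j),
S_mut(i,j)) and label 1 iff j is among the t most-IC50-similar lines to i.
For a new line, the tree flags candidate neighbors among training lines
from those same three similarities; if more than t are flagged, exactly t
are sampled uniformly without replacement (seeded), if fewer, all flagged
are used. The new line's latent vector is the mean of its neighbors' rows
of U; its bias — which the model does not otherwise define for unseen
lines — is the mean of the neighbors' β^c, mirroring the latent averaging. Per-drug
probabilities follow from the logistic map, and label 1 is assigned iff
p ≥ threshold (the boundary counts as sensitive). If the tree flags *no*
neighbors, strict mode raises; the default pipeline falls back to the top-t
lines by mean omics similarity, a robustness device disabled in strict mode.

## Evaluation protocol

Cross-validation operates at the cell-line level: per repeat, lines are
shuffled (seeded) and split into near-equal folds; per fold, *everything
derived from IC50* — S_IC50, the per-drug medians, Q — is rebuilt from the
training lines only, the model and neighbor tree are refitted, and held-out
lines are routed through the new-cell-line path. Held-out truth compares
each test IC50 to the *training* fold's per-drug median, so no response
information leaks (perturbing a test line's IC50 provably cannot change the
fitted model — asserted in tests). All (cell, drug) pairs of a fold pool
into one confusion report (accuracy, recall, precision, specificity, F1,
MCC; zero-denominator rates report 0 with a degeneracy flag) plus rank-based
AUC on the probabilities; folds with single-class truth flag AUC as
degenerate. Grid search evaluates a Cartesian grid of hyperparameters by
this CV and selects the point maximizing the sum of the six confusion
metrics.

## Hyperparameters

Real-data defaults (tuned by grid search on a 555-cell-line × 98-drug
panel and reused across cohorts): L = 95 (23 for a 363 × 24
cohort), k = t = 20, λ_c = λ_d = 0.6, α = 0.5, β = 0.1, similarity weights
(w_exp, w_cnv, w_mut, w_ic50) = (1, 1, 1, 3), probability threshold 0.6.
Search ranges for re-tuning: α, β ∈ {2⁻⁵…2²}; λ_c, λ_d ∈ {2⁻⁵…2¹}; weights
1–10; threshold 0.1–0.9 (a cut of exactly 1 can never label anything
sensitive, so the implementation requires threshold < 1); L up to the drug
count; k, t 1–50.

`fixture_hyperparams()` scales these to the bundled 60 × 10 synthetic
cohort: L = 8 (twice the planted rank), k = t = 10, 200 epochs, threshold
0.5 — neutral because the median rule makes the synthetic classes balanced
by construction.

## Synthetic cohorts

The generator plants ground truth the model assumes: latent factors
U* (n × L_true), V* ~ Normal(0, signal_strength/L_true) with small Gaussian
biases; score z = U*V*ᵀ + biases; IC50 = −z + Normal(0, noise_sd) (low IC50
⇔ sensitive, matching the median rule); expression/CNV = U* through random
gene loadings plus noise; mutation = thresholded loadings; fingerprint bits
Bernoulli with logits tied to V*, so similar drugs share substructure. All
draws are seeded.

Defaults: n = 60, m = 10, L_true = 4, 200/150/100 genes (paper-scale panels
run 10⁴–2.5×10⁴ genes; small widths keep tests fast), noise_sd = 0.5,
fingerprint_density = 0.1, signal_strength = 4.0. The signal scale is set
so the planted score (per-entry sd 2) dominates response noise (sd 0.5):
the Bayes ceiling of the default cohort (classifying from the true planted
score) is ≈ 0.85 accuracy / 0.93 AUC, leaving a non-trivial error floor
while keeping planted structure clearly recoverable — the regime a
method-validation fixture is meant to occupy.

What the fixture does *not* emulate: realistic marginal distributions of
expression or IC50, tissue stratification, gene–gene correlation, or
disjoint gene panels per omics layer (all synthetic omics derive from the
same factors, so the four similarity matrices correlate far more strongly
than on real cohorts). Passing tests demonstrate that the machinery
recovers planted structure under its own assumptions — not field
performance on public pharmacogenomic panels.

`worked_micro_example()` returns a constant 6 × 4 cohort whose mutation
Jaccard (1/3 for the documented pair), first-drug labels ((1,1,1,0,0,0)
around median 3.5) and regularization quadratic form are verified by hand
in the tests.

## Preprocessing conventions

Cell lines with missing-value fraction (over IC50, CNV and mutation slots)
strictly greater than 50 % are removed; a line at exactly 0.5 survives.
Remaining gaps fill from the k = 5 (configurable) nearest cell lines by
Euclidean distance on expression, which is assumed complete (it is in the
public GDSC/CCLE panels) — continuous entries by neighbor mean, binary by majority
vote (ties round up). Matrices are stored cell-lines-as-rows internally;
file orientation is auto-detected (a feature table taller than wide is
assumed genes-as-rows) and overridable. Fingerprints are 881-bit by
convention; other widths load with a warning.

## Pathway association

Fold change x_ij = log2 expr_ij − median_j'(log2 expr_ij') per gene
(expression is treated as already log2 by default; a raw flag applies the
transform and rejects non-positive intensities). Pathway activity
PAS_j(PW) = Σ_{g∈PW} x_gj, with absent genes dropped (warning) and fully
absent sets excluded. The association of drug d with pathway PW is the
Pearson correlation across cell lines between PAS(PW) and the drug's
predicted IC50, taken as the linear predictor z of the fitted model (the
logit of the sensitivity probability). Predictions come from a full-data
fit by default; cross-validated predictions can be substituted by fitting
per fold. Negative association = "assistant" (activity accompanies
sensitivity), positive = "resistant". Gene sets load from GMT or a
two-column TSV.

## Numerical and degenerate-input choices

- Probabilities are clipped to (1e−12, 1 − 1e−12) so saturated predictors
  never yield exact 0/1.
- log(1 + e^z) is computed as logaddexp(0, z); no overflow at any z.
- Constant IC50 columns binarize to all-zero labels and are logged as
  degenerate.
- All rank selections (k-NN, top-t) break ties by ascending index.
- Seeds: every stochastic step (initialization, CV shuffles, neighbor
  subsampling, ablation draws) derives from an explicit integer seed;
  identical seeds give bitwise-identical models, predictions and CV reports.

## Problem sizes used in bundled checks

The test suite and the acceptance script run on the default 60 × 10 cohort
(5-fold CV, 1–3 repeats), 20 random instances with n ≤ 6, m ≤ 5, L ≤ 4 for
the gradient oracle, and 100 random graphs for the trace identity. These
sizes exercise every code path at full fidelity; scaling up is a matter of
the same calls on larger inputs.

## Known limitations

- Unseen *drugs* are out of scope: the neighbor machinery handles new cell
  lines only.
- Grid search is exhaustive over the supplied grid; the full reference
  search space is large, and the default usage is a coarse subgrid.
- The fixture's omics share one factor structure; methods that exploit
  cross-omics disagreement will look better here than they would in the
  field.
- Significance of pathway associations (beyond the correlation value) is
  not assessed.
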