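# Methods note

This note records the statistical model, the default parameters and the
numerical choices made in `symclass`, together with the scope and limits of
the synthetic-data generator. It makes no empirical claims beyond quantities
computed by the package's own test and acceptance suites.

## 1. Symptom factor model

Items follow an ordinal-discretized linear factor model: latent item values
x\* = Λf + ε, with factor scores f ~ N(0, Φ), Φ a positive-definite factor
correlation matrix, independent normal unique terms, and uniquenesses
ψ = diag(I − ΛΦΛ′) so that the implied latent correlation matrix
R\* = ΛΦΛ′ + Ψ has unit diagonal. Observed items are x = q(x\*), a monotone
7-level discretization with floor-heavy thresholds (most mass on low
categories, as is typical of symptom scales).

### Estimation

* **ML EFA** maximizes the Wishart likelihood of the sample correlation
  matrix by profiling out the loadings: for fixed uniquenesses Ψ, the
  conditional loadings come from the top-k eigenpairs of Ψ^{-1/2}RΨ^{-1/2},
  and F(Ψ) is minimized over log-free uniquenesses with L-BFGS-B on the box
  [0.005, 1]. A uniqueness pinned at the lower bound is flagged as a Heywood
  case. The implementation was validated against R's `stats::factanal`
  (uniquenesses to 5·10⁻⁴, χ² to 10⁻⁴ relative) in the test suite.
* **Fit statistics**: Bartlett's correction
  χ² = F·(n − 1 − (2p+5)/6 − 2k/3), df = ((p−k)² − (p+k))/2, and
  BIC = χ² − df·ln N. This BIC convention (common in psychometric software)
  decreases — becomes more negative — for better models; model selection
  minimizes it.
* **Rotation**: varimax (Kaiser-normalized) followed by promax with power 4,
  matching `stats::promax`; the factor correlation is Φ = (U′U)⁻¹ normalized
  to unit diagonal, where U is the inverse rotation. Factors are ordered by
  explained common variance and sign-fixed so each column's loading sum is
  nonnegative. Power 4 is the conventional default; it is exposed as a
  parameter.
* **Factor scores** are Thurstone regression scores W = R⁻¹(ΛΦ), using the
  fit sample's item means/SDs as the frozen standardization reference. Note
  the sample covariance of regression scores is W′RW, not Φ; the test suite
  asserts the exact identity rather than the common approximation.

### Jackknife model selection and assignment

`jackknife_select` refits the EFA on every delete-1 subsample for each
candidate k (correlation matrices are obtained by rank-one downdating of the
full-sample sums, and each fit warm-starts from the full-sample solution, so
full leave-one-out at n≈360, k ∈ 1..5 takes seconds). Selection picks the k
with the lowest mean jackknife BIC; percentile 95% intervals and pairwise
paired tests over replicates are reported. `assign_subgroups` assigns each
subject to the factor with the highest regression score in every replicate
(after matching each replicate's factors to the full-sample solution by
Tucker congruence, with sign alignment); the final label is the majority
vote and **certainty** is the percentage of replicates agreeing with it.
Ties go to the lowest factor index and are flagged.

**Known property, documented as a failing acceptance assertion**: under a
delete-1 jackknife, removing one subject changes factor scores by O(1/n), so
replicate votes almost never flip and certainty is ≈100% regardless of how
small the true dominance margin is. A specification that expects the
certainty distribution to drop (median < 70%) at margin 0 is not attainable
with this estimator; the corresponding test is left failing on purpose, and
the measured behavior (median certainty 100 at margin 0, n=362) is recorded.

### Reliability and longitudinal stability

Standardized Cronbach's alpha uses α = m·r̄ / (1 + (m−1)·r̄) on the items
assigned to each factor (item → factor with the largest absolute pattern
loading; ties flagged). Longitudinal stability refits the EFA at follow-up,
correlates matched loadings, computes a Dice overlap of same-assignment
items, subgroup transition tables, per-group persistence (% keeping their
baseline subgroup) and factor-score correlations.

## 2. Classification

* **CV structure**: stratified outer CV, default 10 folds × 5 permutations;
  an inner CV of the same shape inside each outer training set selects the
  SVM slack C from the geometric grid 2⁻⁶..2⁴ (11 values) and, for
  modalities with a PCA step, the retained-variance energy from
  {0.4, 0.6, 0.8}, by mean inner multiclass BAC. Ties prefer the smallest C
  (strongest regularization), then the smallest energy. Classes smaller than
  the fold count reduce the fold count with a warning.
* **Learners**: per class pair, `LinearSVC` (hinge loss) with
  inverse-frequency class weights n/(2n_c), `tol=1e-3`, `max_iter=2000`,
  fixed `random_state`. The tolerance/iteration cap is a deliberate
  numerical choice: the hinge dual oscillates on heavily overlapping (null)
  data at large C, and further iterations change no predictions while
  dominating runtime.
* **ECOC decoding**: one-vs-one code matrix (+1/−1 per pair, 0 elsewhere);
  a subject's label minimizes the Hamming distance between decision-score
  signs and the class codes, a zero margin contributing half a mismatch to
  both classes of its pair. For one-vs-one codes this equals majority voting
  on every non-tied pattern (asserted exhaustively for k ≤ 5). Distance ties
  go to the larger summed |margin|, then the lower class index, and are
  flagged.
* **Aggregation**: out-of-fold decision scores are averaged over outer
  permutations; per-contrast sensitivity/specificity/BAC come from the sign
  of the aggregated score and the multiclass prediction from decoding the
  aggregated score vector. BAC = (sensitivity + specificity)/2.
* **Stacking**: meta-features for outer-training subjects are their
  inner-CV out-of-fold decision scores at the selected hyperparameters
  (cached during the scan, so stacking adds no refits of base models);
  outer-test subjects are scored by the base models trained on the full
  outer training set. The meta-learner is the same ECOC machinery after
  mean-centered winsorized scaling, with C selected on the inner CV.
* **Preprocessing** is embedded in the CV: chains are fitted on the training
  fold only (on the healthy-control reference where configured) and applied
  frozen. Default chains — neurocognition: covariate regression (age, sex) →
  z-score/winsorize; imaging (fALFF slow-5/slow-4, connectivity, GMV):
  site mean-offset correction → covariate regression (age, sex, framewise
  displacement) → reliability mask → PCA by energy → median-centered
  winsorized scaling, all on the HC reference; polygenic scores: covariate
  regression (age, sex, 10 ancestry components) → z-score/winsorize.
  Winsorization clips at ±4 SD. Weight vectors are archived after
  back-projection through the linear steps (PCA basis, masks) to input
  space.

## 3. Inference

* **Permutation test**: labels are shuffled once per iteration (optionally
  within one contrast's subjects only), the full deterministic pipeline is
  re-run, and the one-sided p uses the add-one rule
  p = (1 + #{null ≥ observed}) / (1 + n_perm). The CLI default n_perm=199 is
  a runtime compromise and is marked `scaled_down` in the output.
* **CVR**: per input feature, mean/SE of the archived weights across the
  ensemble; SE = 0 yields signed ±inf sentinels (0 if the mean is also 0).
* **Sign consistency**: over a feature's nonzero weights,
  f = max(#pos, #neg)/M, consistency c = 2f − 1,
  z = (f − ½)/√(¼/M), p one-sided normal. Because the statistic is folded
  (f ≥ ½), the null p lives on (0, ½]; calibration is checked on 2p, which
  is uniform up to binomial discreteness.
* **FDR**: Benjamini–Hochberg step-up mask at α = 0.05 by default.

## 4. Synthetic generator: scope and limits

The generator exists to give every pipeline stage ground truth: loadings,
factor correlations, subgroup labels, dominance margins, affected features,
site offsets, covariate confounds, and follow-up persistence. Defaults:
30 items in four blocks (8/8/7/7) with block loadings descending from 0.70
to 0.55 (±0.12 within block), factor correlations 0.25–0.35, floor-heavy
7-level thresholds; group sizes (92, 92, 82, 96) patients plus 338 controls
over 7 sites; modality effects are mean shifts of Cohen-d size on a seeded
subset of features with per-group sign patterns.

Limits to keep in mind:

* Items are conditionally independent given the factors; no local item
  dependencies, no missing data.
* Ordinal discretization attenuates Pearson correlations relative to the
  latent model (by roughly 20% at the default thresholds), so latent-scale
  parameters are recovered up to that attenuation, monotonically.
* Planted modality effects are linear mean shifts with Gaussian noise —
  adequate for validating the leakage-safe estimation machinery, not a
  generative model of any imaging modality.
* Follow-up data are generated by re-sampling with an explicit per-subject
  persistence switch (score-swap between the dominant and a random other
  factor), so "persistence" has an exact generator-side meaning. Recovery
  through the measured-item pipeline is attenuated by subgroup-label
  measurement error; the acceptance test uses a 1.5-SD dominance margin,
  at which the measured persistence matches the generator value within the
  asserted ±5 points.

## 5. Reduced problem sizes

Test and acceptance runs shrink permutations/folds (e.g. outer 5×2, inner
2×1–3×1, C grids of 2–3 values, n_perm = 199) purely for runtime; the code
paths are identical to the full-size configuration, and the CLI defaults
(outer 10×5, inner 10×5, full C grid) remain the recommended analysis
settings.
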