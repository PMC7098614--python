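# Methods

## Study design

`trialpower` implements a Monte Carlo comparison of univariate and
multivariate strategies for detecting treatment effects in small
preclinical trials.  One simulated trial has a control group and three dose
groups (equal n per group) measured on p = 18 correlated variables — six
endpoints, each observed on days 1, 7 and 14.  Scenarios cross four
factors:

| factor | default levels | meaning |
|---|---|---|
| `n_per_group` | 5, 10, 15, 20, 30, 40, 50 | subjects per group |
| `cohens_d` | 0, 0.2, 0.5, 0.8 (2.0 for ordination studies) | standardized effect size |
| `distribution` | normal, lognormal, gamma | marginal family |
| `variance_ratio` | 1, 2, 5 | treatment/control variance inflation |

giving the 252-cell default grid with 1000 replicate trials per cell.
Empirical type-I error (d = 0) and power (d > 0) use the pooled definition:
significant tests divided by total tests, pooled over variables/endpoints
and replicates, two-sided α = 0.05, no multiplicity correction.  Failed
fits count as non-rejections and appear in a diagnostics column.

## Population parameters

The control population is (μ₀, σ², R).  Three sources:

* **Bootstrap** (`bootstrap_population_params`): B = 10,000 resamples of
  complete subject rows from a pilot dataset (rows resampled jointly to
  preserve cross-variable covariance); the averaged covariance matrix is
  repaired by eigenvalue clipping (`nearest_positive_definite`, floor
  1e-8 × largest eigenvalue) and split into variances and a unit-diagonal
  correlation matrix.
* **CSV loader** (`load_population`): a means/variances/correlation triplet,
  e.g. transcribed from a published supplement; axes are validated and full
  float precision survives a write/read round trip.
* **Structural emulator** (`default_population`), used when no empirical
  parameters are available.  It is deterministic given its seed and encodes
  what matters structurally about such trials: positive means on
  heterogeneous scales (per-endpoint base scale log-uniform on roughly
  2–100 with ±30% drift over time), coefficients of variation U(0.2, 0.45),
  within-endpoint temporal correlations 0.75 (adjacent days) and 0.60 (day
  1 vs 14) — mean ≈ 0.7 — and cross-endpoint correlations with base
  U(0.3, 0.5) decaying mildly with temporal distance, repaired to a PD
  correlation matrix.  Its leading eigenvalue is ≈ 7.8 and the Kaiser
  criterion retains 7 components.

The emulator reproduces the *structure* of a neurotrauma pilot, not any
specific dataset; quantities that depend only on the marginal null
distribution of the tests (type-I rates, the Roy pathology, affine-invariant
identities) are unaffected by the exact values, whereas pooled power levels
and ordination rates shift with the correlation matrix.  Results quoted for
the defaults should be read with that caveat.

## Trial sampling

Treatment means are μ₁ = μ₀ + sign·s·d with s the control SD under equal
variance and the average of control and treatment SDs,
s·(1 + √v)/2, under variance ratio v; treatment variances are σ²·v with R
unchanged.  A per-variable sign/mask vector supports effects on a subset of
variables (the demo puts d = 2 on a random half).

* **Normal**: X = μ + (Z·R^{1/2})·σ.
* **Lognormal**: log-scale parameters solved in closed form
  (σ²_log = ln(1+cv²), μ_log = ln μ − σ²_log/2, and
  r_log = ln(1 + r·cv_i·cv_j)/√(ln(1+cv_i²)·ln(1+cv_j²))), so natural-scale
  means, variances and the variance ratio are exact; the log-scale
  correlation matrix is nearPD-repaired before use.
* **Gamma**: Gaussian copula (NORTA) — correlated standard normals pushed
  through Φ and the gamma quantile function with moment-matched shape/rate
  (α = μ²/σ², β = μ/σ²).  The copula-scale correlation equals R; the
  induced natural-scale correlation is mildly attenuated (a few percent at
  these cv values), which is accepted and documented rather than inverted.

Reproducibility design: the latent normal column for a variable comes from
a stream keyed by (seed, crc32(label)), and the correlation transform is
the unique symmetric PSD square root.  Together these make sampling
*permutation-equivariant*: permuting variables in the parameters permutes
the sampled columns identically, which the test suite checks exactly.
Replicate r of scenario i uses seed `base_seed + i·10⁶ + r`, so any cell is
reproducible in isolation and parallel execution cannot change results.

## Test battery

* **ANOVA / Welch's ANOVA** per variable.  Welch's statistic is computed
  from the standard weighted formulas (weights nᵢ/sᵢ²,
  Welch–Satterthwaite denominator df) and cross-checked against
  `pingouin.welch_anova` in the tests.  Note the g = 2 special case is the
  only one where Welch equals classical ANOVA exactly under equal sample
  variances; for g > 2 the correction factor in the denominator exceeds 1.
* **Linear mixed effects** per endpoint: value ~ treatment + time with a
  random intercept per subject.  For the balanced, complete designs
  simulated here the treatment Wald F with Kenward-Roger df is *exactly*
  the one-way ANOVA on subject means with df (g−1, N−g); that closed form
  is the default engine.  A statsmodels `MixedLM` REML fit with containment
  df and an ML likelihood-ratio engine are selectable
  (`df_method="containment" | "lrt"`) and the suite asserts the engines
  agree.  The closed form is what makes 252,000-fit grids affordable.
* **ANOVA on PC scores**: eigendecomposition of the *population*
  correlation matrix; components with eigenvalue strictly > 1 retained
  (Kaiser); scores are the pooled-standardized data times the retained
  eigenvectors (largest-|loading| positive sign convention).  Identity R
  retains nothing and contributes no tests.
* **MANOVA** per endpoint on its q = 3 repeated measures, computed from the
  eigenvalues of E⁻¹H (generalized symmetric eigenproblem).  F
  approximations follow the conventions of R's `summary.manova`: Rao's F
  for Wilks, the standard approximations for Pillai and Lawley–Hotelling,
  and the upper-bound F for Roy's largest root.  The Roy approximation is
  kept deliberately anticonservative — its inflated type-I error is a
  finding this package measures, not a bug to fix.  The tests verify exact
  agreement with R's conventions (statsmodels for Wilks/Pillai/Roy;
  statsmodels reports McKeon's variant for Lawley–Hotelling, so that
  criterion is checked through its q = 1 and g = 2 exact reductions).
* **Interaction + post-hoc workflow** (`lmm_interaction_posthoc`):
  value ~ treatment × time + random intercept.  The interaction F and the
  per-time dose-vs-control contrasts use the exact balanced split-plot
  decomposition; a contrast at one time point has variance
  2(σ²_b + σ²_e)/n, estimated by (MS_B + (T−1)MS_W)/T with Satterthwaite
  df.  Contrasts are computed unconditionally and the interaction gate
  reported, so the caller decides whether to filter (conditioning emission
  on a significant interaction would bias the contrasts' null behaviour).
  Multiplicity options per (endpoint, time): none (default), bonferroni,
  sidak.

## Ordination pattern analysis

PCA (correlation-matrix eigenvectors), LDA (Fisher directions via
pseudo-inverse of the within-scatter — deliberately unregularized so the
p > n overfitting pathology runs rather than crashes), RDA (PCA of
group-mean fitted values, subjects projected onto the constrained axes so
groups keep within-group scatter), and PLS-DA (two-component NIPALS via
scikit-learn, standardized X against one-hot groups).  All methods share a
sign convention (variable most correlated with an axis is positive) and
report per-axis explained-variance fractions and axis-1 variable
correlations.

The 95% confidence ellipse uses the sample covariance of a group's scores
scaled by χ²₀.₉₅(2) = 5.9915 (population-coverage convention; a
small-sample 2(n−1)/(n−2)·F quantile variant is selectable since plotting
libraries differ — all reported rates use one declared convention).
Disjointness is decided by sampling each boundary at K = 720 points plus
center-containment checks; the test suite pins the tangency of unit circles
at center distance 2 ± 0.01.  A pattern is detected when the control
ellipse is disjoint from **all three** dose ellipses; degenerate ellipses
(collinear scores, probability ≈ 0 for continuous data) count the replicate
as not detected and are logged.

With the default population at n = 5/group the null (d = 0) false-pattern
rates are ≈ 0 for PCA/RDA/PLS-DA and large (tens of percent) for LDA, and
sensitivity at d = 2.0 is low for all methods and ordered
PLS-DA ≥ RDA ≥ PCA within Monte Carlo error — the qualitative behaviour is
structural, while the exact percentages depend on the correlation matrix
supplied.

## Numerical choices and degenerate inputs

* `nearest_positive_definite`: symmetrize, clip eigenvalues at
  1e-8 × largest (absolute 1e-8 when none is positive); idempotent; the
  all-zero matrix maps to a tiny multiple of the identity, so a degenerate
  pilot (identical rows) still yields valid parameters.
* Zero within-group variance raises "degenerate data" for ANOVA; a
  zero-variance group is rejected by Welch (weights undefined); a
  zero-variance variable gets correlation 0 (with a warning) in the loading
  filter.
* MixedLM fits whose between-subject variance lands at the boundary are
  flagged in `TestResult.note` (threshold relative to the residual
  variance, since optimizers stop near rather than at zero).
* Monte Carlo orchestration converts per-test exceptions into NaN results
  counted as non-significant, so one pathological replicate cannot abort a
  scenario; failure counts are reported.
* Loading filter: |r| strictly below the 0.5 threshold is set to exactly 0
  (so r = 0.49 → 0, r = −0.51 kept), and the filter is idempotent.

## Replication sizes

Defaults are 1000 replicates per scenario.  The packaged acceptance run
(`scripts/acceptance.py`) uses 1000 replicates for the null-calibration,
Roy and large-effect-power quantities, 300 per cell for the
seven-sample-size small-effect sweep and 500 per cell for the
minimal-n-at-80%-power search; pooled rates at these sizes carry binomial
standard errors of 0.2–1.8 percentage points, which is small against the
effects being measured.  The same sizes are used by the test suite.

## Known limitations

* No missing data, unequal group sizes, or distributions beyond the three
  families; no family-wise error control across endpoints (both by design,
  matching the study being emulated).
* Kenward-Roger df are not computed in general — the balanced-design closed
  form coincides with them only for complete, equal-n random-intercept
  designs, which is the entire simulated design space here.  Unbalanced
  data should use the `containment` or `lrt` engines and interpret df
  accordingly.
* The gamma sampler controls copula-scale, not natural-scale, correlation.
* The Dunnett adjustment proper is not implemented; `sidak` is the
  closest offered option for many-to-one contrasts.
* Ordination rates are 2-D only (first two axes), and LDA's direction count
  is capped by g − 1 = 3; explained-variance fractions for LDA are ratios
  of discriminant eigenvalues, not data variance.
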