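# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `gsnue`. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## The prediction models

All nine predictors see the same inputs: a complete post-QC dosage matrix
(recoded to −1/0/+1 for the linear models), the genomic relationship matrix
(GRM), and a Gaussian kernel, per nitrogen level of the NUE trait.

**rrBLUP.** Intercept-augmented mixed-model equations
`[[n, 1ᵀX],[Xᵀ1, XᵀX + λI]]·[μ; g] = [1ᵀy; Xᵀy]` with λ = σ²ₑ/σ²_g from
REML when not supplied. For m > n the solver switches to the dual form
`ĝ = Xᵀ(XXᵀ + λI)⁻¹(y − 1μ̂)` via the Woodbury identity; a unit test pins
the two routes against each other and against a dense solve.

**gBLUP.** `û = G(G + δI)⁻¹(y − 1μ̂)` with a GLS intercept and
δ = σ²ₑ/σ²ᵤ. With `G = XXᵀ/c` and λ = δ·c this is algebraically identical
to rrBLUP — the module's central oracle test (agreement to 1e−8).

**LASSO.** The standard L1 objective `(1/2n)‖y − 1μ − Xβ‖² + λ‖β‖₁`,
solved by cyclic coordinate descent (scikit-learn's implementation);
λ on a log grid by inner CV when not supplied. The exact null threshold
λ_max = max|Xᵀ(y−ȳ)|/n and the single-predictor soft-threshold closed form
are asserted in tests.

**Bayesian ridge (BGLR-type).** `y = 1μ + Xα + e`, `α_j ~ N(0, σ²_α)`,
scaled-inverse-χ² priors (df 4) on both variances, Gibbs sampling. The
sampler runs in the SVD-rotated basis: with `X = USVᵀ`, the conditional
posterior of `a = Vᵀα` is diagonal, so one sweep costs O(rank) instead of
O(p³); the null-space effect mass enters the σ²_α update as a σ²_α·χ²_{p−r}
draw. This is an exact reparameterization, verified against the conjugate
ridge posterior at frozen variances (20,000 draws, tolerance 0.02). Marker
summaries (posterior means, sign probabilities) come from rotating thinned
draws back; sign probabilities deliberately summarize the row-space
component, the part the data inform.

**RKHS / SVR.** Kernel ridge `α̂ = (K + λI)⁻¹(y − 1μ̂)` (λ by REML on K,
exploiting RKHS/gBLUP duality) and ε-insensitive support-vector regression
in the dual on the same precomputed kernel. When the ε tube covers the
whole response range the SVR bias is non-unique; the midrange of y is the
deterministic tie rule. A brute-force lattice search over the dual box
confirms the solver's dual objective on a 5-point fixture.

**Boosting / bagging.** Stage-wise squared-loss boosting with F₀ = 0 and
depth-limited regression-tree weak learners (depth 0 = the constant mean
learner, giving the closed form `ȳ(1 − (1−v)^M)` used as a fixture);
bootstrap-aggregated trees with out-of-bag error and the bootstrap mean
reported. Both are authored loops over scikit-learn trees because the
stock ensembles expose neither F₀ = 0 nor depth-0 learners.

**Stacking.** Non-negative least squares with a free intercept over
out-of-fold base predictions (inner K-fold within each training split);
weights are reported, and the ε-insensitive meta loss
`Σ max(|r| − ε, 0)` is evaluated (exactly zero when all residuals sit
inside the tube). An oracle test checks that a base model equal to the
noise-free truth receives weight ≥ 0.9.

## REML variance components

For `y = Xb + g + e`, `g ~ N(0, Kσ²ₐ)`, the restricted likelihood is
profiled over δ = σ²ₑ/σ²ₐ after projecting out the fixed effects
(intercept by default; population-structure indicators optional) and
eigendecomposing the projected kinship once. The 1-D search is a 61-point
log₁₀ grid on [−6, 6] refined by bounded golden-section minimization.
h² = σ²ₐ/(σ²ₐ+σ²ₑ). A generic 2-D REML optimization over both variances
(Nelder–Mead on the unprofiled criterion) serves as the independent oracle
in tests. When K ≈ I the two components are not separately identifiable
and the estimator warns and returns a boundary fit.

At the recovery benchmark (h² = 0.6, n = 400, m = 2000, 30 populations)
the mean estimate is within 0.03 of the truth; the per-population scatter
(SD ≈ 0.085) is the information floor of REML at that sample size and
relatedness, not estimator error — the independent-oracle test pins the
estimator itself to 0.02.

## Cross-validation and accuracy

The two-level design is read as nested CV: outer 5-fold testing, inner
10-fold tuning (the inner folds also produce the stacking out-of-fold
matrix). Accuracy is the Pearson correlation r(y_obs, GEBV) computed
within each outer test fold and averaged. Pooling predictions across folds
instead would mix fold-specific intercepts into the correlation and biases
a permutation null to ≈ −0.1; the within-fold version is centered at zero
under permuted phenotypes (tested over 20 permutations). Variance
components in the report are averages of per-training-fold REML estimates
(the whole-set alternative is a one-line change).

## Bias–variance decomposition

For each complexity value (KNN neighbour count k), B training sets are
resampled, predictions collected at fixed test points, and
bias² = mean over test points of (mean prediction − truth)²,
variance = mean prediction variance across resamples,
expected loss = Monte-Carlo MSE against noisy test observations.
In synthetic mode the generator supplies fresh training noise and the true
irreducible error, so `Exp.Loss = bias² + variance + σ²ₑ` is checkable; the
module reports a per-row Monte-Carlo standard error for that identity gap
(from the per-resample loss differences), and tests assert the gap within
3 such SEs. "Bias" is reported as squared bias so the additive
decomposition holds. The classical monotone tradeoff (variance falling,
bias² rising in k) is asserted on a smooth low-dimensional response; on raw
high-dimensional marker data the nearest neighbour is not locally close, so
small-k bias need not vanish — the identity still holds and both checks run.

## Adaptive standard error of prediction

Each model's marker effects (ridge back-projection of GEBVs for models
without native effects) are standardized and resampled 2,000 times with
replacement under a N(0,1) null; markers rejecting a Benjamini–Hochberg
screen at FDR 0.05 are counted as "far from normal". The adaptive SE of a
model pair is the bootstrap SE of the paired difference in squared held-out
errors; pairs are declared different by a normal test of the mean paired
difference, BH-adjusted across pairs. Raw values are min-max normalized to
[−0.2, 1] (self-comparisons land on the lower bound). The combining rule
is a documented design choice: the source material specifies the
ingredients (2,000 resamples, the N(0,1) null, FDR 0.05, the normalized
heat-map scale) but not the formula. Under an exchangeable null the
declaration rate stays inside the binomial envelope of the nominal 0.05
(200-replicate test).

## Selection gain

Model power β = logdet(C)/dim(C) for Henderson's coefficient matrix
`C = [[XᵀX, XᵀZ],[ZᵀX, ZᵀZ + G⁻¹σ²ₑ/σ²ᵤ]]` — an information-content
reading adopted because the printed source formula is typographically
unrecoverable; X is the population-structure incidence, Z the genotype
design. Gain formulas are implemented literally as products
(ΔG = i·β·σₑ; R = i·r·y·β) with per-year division behind a flag, and
RE = r/R². Selection intensity i comes from the normal truncation relation
i = φ(Φ⁻¹(1−p))/p at the selected fraction (default 10/221 ≈ 0.045,
i ≈ 2.06). Per-genotype RE% in the top-10 table is a display convention:
the genotype's share of the top-set GEBV total scaled by the population RE.

## The synthetic population

Defaults are the study shape: 221 genotypes, 5,000 markers (2,000 in the
analysis scripts — a desk-scale stand-in for the 22,489-marker post-QC chip
panel), 3 subpopulations (Balding–Nichols drift F = 0.15, separable on two
principal components at ≥ 90 % purity), MAF drawn in [0.05, 0.5], LD by
blockwise haplotype copying (block length 5, per-marker redraw probability
0.1), 200 additive QTL with effects at the two N levels drawn from a
bivariate normal (correlation 0.8, emulating genotype × N interaction),
1 % missing calls completely at random. Trait scales: NUE mean 40 (SD 6)
under low N with 10 g N/m² supplied, mean 15 (SD 2.25) under high N with
25 g N/m² — high supply dilutes NUE, as in wheat N-response trials.
Heritability targets 0.45 (LN) and 0.60 (HN) sit inside the 0.28–0.71
range the motivating study reports; the noise scale is set so the
population-level ratio σ²ₐ/(σ²ₐ+σ²ₑ) equals the target exactly, with the
sample ratio converging as n grows (tested at n = 1000, ±0.05).

What the generator does **not** emulate: coalescent genealogies,
recombination maps, selection or pedigree structure, non-additive genetic
effects, genotyping-error mechanisms beyond random missingness, or
field-trial design effects (replicates, blocks, spatial trend). Passing
tests therefore demonstrate correctness of the estimators under a clean
additive world, not performance claims about real wheat data.

## Numerical choices

- QC boundary inclusive: markers with MAF ≤ threshold are removed; removal
  reasons follow the precedence MAF → HWE → call rate so report counts add
  up. HWE α = 1e−4 and call-rate 0.95 are exposed defaults (the protocol
  source states neither). Remaining missing calls are mean-imputed.
- GRM denominator `2Σp(1−p)`; centering makes dosage and −1/0/+1 codings
  give the same matrix. Kernel bandwidth: median off-diagonal distance.
- Regularized inversion starts at jitter 1e−6 and escalates ×10, logging
  escalations; MME log-determinants use `slogdet` with the same escalation.
- All stochastic components (generator, Gibbs, bagging, bootstraps,
  comparison resampling) draw from seeded `numpy` generators; pipeline
  manifests record sha256 checksums per artifact, and two identically
  seeded runs are byte-identical.
- Problem sizes in the test suite and acceptance script (2,000 markers,
  B = 60–200 resamples, 100–200 null replicates) are desk-scale choices
  that keep every distributional check at Monte-Carlo tolerances of a few
  percent.

## Known limitations

- The Bayesian model is a single Gaussian-prior ridge; BayesA/B/Cπ-style
  heavy-tailed or spike-slab priors are out of scope.
- Bias–variance "variance" is the resampling variance of predictions; the
  source text's phrasing ("difference between parameters of a model and its
  training set") is not operational as printed.
- The adaptive-SE combining formula and the exact role of the FDR screen
  are documented interpretations, not a verbatim algorithm.
- Train/test GEBV comparisons use Welch's t-test; the protocol source
  names no test.
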