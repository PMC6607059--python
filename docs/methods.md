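# Methods

## The model

`phenotrial` analyses multi-treatment plant phenotyping trials in which a
panel of genotypes is grown under a control and several stress treatments
with replicated plants per cell. For each trait the replicate-level
observations follow the Gaussian linear mixed model

    y_ijk = mu + r_k + t_j + g_i + (gt)_ij + eps_ijk

with replication `r_k` fixed (crossed with the treatment-by-genotype
grid) and treatment, genotype and genotype-by-treatment random:

    t ~ N(0, s2_T),  g ~ N(0, s2_G),  gt ~ N(0, s2_GT),
    eps_ijk ~ N(0, s2_E(j)).

Two residual models are fitted per trait — a pooled variance and one
variance per treatment — and the one with the lower AIC
(`-2 logREML + 2 k`, `k` = number of variance parameters) is kept; ties go
to the pooled model. Treatment enters the fit as a random term, but with
only four levels its variance is weakly identified; it is reported and
used in the variance-contribution shares, while sample-basis heritability
excludes it:

    h2 = s2_G / (s2_G + s2_GT + s2_E).

When the heterogeneous residual model is selected, the residual entering
h2 is the unweighted mean of the per-treatment variances — a documented
convention, since the quantity is otherwise ambiguous.

Genotype-by-treatment predictions (`mu + t_j + g_i + gt_ij`, the BLUPs,
with the fixed part averaged over replicates) are the substrate for every
downstream stage: correlation networks, penalized selection, stress
classification and AMMI.

## REML estimation

Estimation is REML on the mixed-model equations (MME). The design is
collapsed once into per-treatment Gram blocks `W_j'W_j`, `W_j'y_j`,
`y_j'y_j` (`W = [X | Z]`), so each likelihood evaluation is a dense
solve of the (p+q)x(p+q) MME system independent of n, using the identity
`log|V| + log|X'V^-1 X| = log|G| + log|R| + log|C|`.

The optimizer is a three-stage hybrid:

1. **EM warm-up** — the classic updates
   `s2_b <- (u_b'u_b + tr(C^bb))/q_b` and the residual analogue;
   monotone in logREML, stopped when its change drops below `tol`
   (default 1e-8) or after 200 iterations.
2. **L-BFGS-B on log-variances** with the analytic REML score (obtained
   for free from the same E-step traces), bounded below at 1e-10.
3. **Newton polish on the score** for interior parameters. The
   log-likelihood itself carries Cholesky round-off of order 1e-11,
   which line searches cannot resolve, while the analytic gradient is
   clean; a few Newton steps on `grad = 0` bring interior estimates to
   oracle precision. The polish targets a score tolerance tied to `tol`
   so routine fits stay cheap.

On balanced data with interior optima the result reproduces the
closed-form ANOVA (expected-mean-squares) estimator to ~1e-13 relative;
`fit_moments` implements that estimator (negative solutions truncated to
zero and flagged) as an independent cross-check. When the fixed
replicate term is included, the replicate sum of squares is removed from
the error stratum (df `(GT-1)(R-1)`) so the two estimators target the
same model.

Likelihood-ratio tests of a random term use the boundary mixture
`0.5 chi2_0 + 0.5 chi2_1` (for d dropped terms,
`0.5 (chi2_{d-1} + chi2_d)`). Outlier screening standardizes conditional
residuals by their exact prediction variances `diag(R - W C^-1 W')`;
observations beyond the threshold (default 3) are flagged, never
removed. The replicate fixed effect gets a plain z-test from the inverse
MME matrix — no small-sample df correction.

## Penalized trait selection

Ridge and lasso minimize the plainly scaled objectives

    RSS + lambda * sum(b^2)      and      RSS + lambda * sum|b|

on predictors standardized to unit sample variance (response centred).
Common software scales the loss by 1/(2n); cross-validated solutions are
identical up to a relabeling of lambda. Ridge is the closed form
`(X'X + lambda I)^-1 X'y`; lasso is cyclic coordinate descent with
soft-thresholding on the Gram system (exact zeros preserved, convergence
when the largest coefficient change per sweep is below 1e-8). The sweep
kernel is JIT-compiled with numba when available because the
cross-validation path evaluates ~500 fits per run; a NumPy fallback is
retained.

Lambda is chosen by five-fold cross-validated mean squared error on a
100-point log grid from `lambda_max = 2 max_j |x_j'y|` (the smallest
all-zero lambda, from the KKT conditions) down to 1e-4 of it, folds from
a seeded shuffle. The default pick is the MSE minimizer with ties broken
toward the larger lambda; a one-standard-error rule is available behind
a flag. Note the minimizer is deliberately liberal: on a pure-noise
response it retains a non-empty support in roughly half of the runs
(the 1-SE rule drops most of these), which is the familiar behaviour of
CV-tuned lasso rather than a defect of the implementation.

## Stress indices and classification

From dry-weight performance under non-stress (Yp) and one stress
treatment at a time (Ys), with stress intensity `SI = 1 - mean(Ys)/mean(Yp)`:

    SSI = (1 - Ys/Yp)/SI,  TOL = Yp - Ys,  MP = (Yp+Ys)/2,
    GMP = sqrt(Yp*Ys),     STI = Yp*Ys/mean(Yp)^2.

Each index is scored on a 1-10 grade. The grading map is a
reconstruction (the originating screening method is cited in the
literature without a closed formula): the default maps values linearly
between the population minimum and maximum,
`round_half_up(1 + 9 (x - min)/(max - min))`, after reversing SSI and
TOL (lower = more tolerant); a decile-rank variant
(`ceil(10 rank/n)`) is provided as an alternative, and constant input
maps to the neutral grade 5. Both variants are invariant under
increasing affine transforms of the index.

RCI (resilience capacity) is the mean of the SSI and TOL scores, PCI
(production capacity) the mean of the MP, GMP and STI scores. Quadrants
relative to the population means of RCI and PCI classify genotypes:
A = high/high, B = productive only, C = resilient only, D = low/low;
boundary values count as "high" so the partition is deterministic.
Groups A and D are compared trait-by-trait with Welch (unequal-variance)
t-tests, starred at 0.05 and 0.01.

Derived dry-weight indices are configurable formulas with defaults
SPW = BDw/PHg, WUE = BDw/water, PNUE = BDw/(BDw * NC/100); the exact
definitions used in any given study vary, so the formula registry is the
interface, not the defaults.

## AMMI stability

The genotype x treatment BLUP table for dry weight is double-centered,
`tg_ij = y_ij - ybar_i. - ybar_.j + ybar_..`, and decomposed by SVD.
Component k explains `100 lambda_k^2 / sum(lambda^2)` percent of the
interaction sum of squares. Biplot coordinates use symmetric scaling
(both sides multiplied by sqrt(lambda_k)), so genotype-by-treatment
score inner products reconstruct the interaction; the SVD sign is fixed
by making the largest-magnitude genotype loading positive per component.
A genotype's Euclidean distance from the origin in the IPC1-IPC2 plane
summarizes instability (0 = purely additive response); cosines with the
treatment vectors indicate which treatment an unstable genotype favours.
Dry weights are not standardized per treatment before centering.

## Synthetic trials

The generator is the sampling counterpart of the fitted model. Defaults
emulate the target study design: 20 genotypes x treatments
(C, N, W, N+W) x 8 replicates = 640 plants per trait, mean dry weight
20 g, and fixed treatment effects (0, -0.64, -3.86, -4.36) g chosen so
the expected mean reductions under N, W and N+W are 3.2 %, 19.3 % and
21.8 % — the average stress responses the pipeline is meant to resolve —
giving the ordering C > N > W > N+W. Default variance components
(s2_G, s2_GT, s2_E) = (2, 0.5, 1) g^2 put the within-treatment CV near
10 % (the low-to-moderate variability band typical of imaging traits)
and sample-basis heritability at 2/3.5 ~ 0.57. Residual variance may be
given per treatment; replicate effects default to zero but can be
injected. Strictly positive traits can be simulated on the log scale and
exponentiated.

The multi-trait panel draws each predictor trait as
`mu + t_j + sqrt(rho_b) * shared + sqrt(1-rho_b) * idio`, where shared
and idio are independent zero-mean draws of the full genotype + GxT +
residual structure; traits within a block therefore correlate at rho_b
(default 0.8) at replicate and genotype level, across blocks at zero.
Responses BDw (and BFw, scaled by a fresh-to-dry ratio of 4.2) are
sparse linear combinations `X beta` of the predictors plus noise;
alternatively, planted A-D archetypes assign each genotype a (Yp, Ys)
dry-weight profile — A (20, 18), B (24, 12), C (10, 9.5), D (12, 4) g —
chosen so that the scoring pipeline separates the four quadrants
cleanly, which is the fixture for classification-recovery checks.

What the generator does not emulate: growth over time (a single
end-point measurement is simulated), spatial/position effects,
non-Gaussian traits, missing data or unbalanced designs, and genuinely
nonlinear trait-biomass relations. Passing tests therefore demonstrate
correctness of the estimators and the pipeline plumbing under the
design's assumptions, not robustness to violations of them.

## Problem sizes and numerical choices

Calibration checks in the test suite use: 200 simulated trials at the
640-plant scale for variance-component recovery and for AIC
residual-model selection; 50 balanced fixtures (10 x 4 x 4) for
REML-vs-ANOVA oracle equivalence, with the dense n x n mixed-model solve
cross-checked on 10 of them; 100 seeded CV runs each for lasso support
recovery (3 true predictors among 25, SNR 10, n = 20) and for the
pure-noise null; 1000 draws for the stress-index identities and for
Welch type-I calibration (groups of 6 and 5). The acceptance script
scales the replicated studies down (60 trials, 50 CV runs) to keep a
single run under a minute; point estimates match the larger runs within
sampling error.

Variances are floored at 1e-10; MoM truncations at zero are flagged so
oracle comparisons can skip boundary cases. All randomness flows from
explicit seeds (`numpy` `SeedSequence` spawning per stage), and the
pipeline writes no timestamps, so identical config + seed reproduces
byte-identical outputs.

## Known limitations

- Balanced complete designs only; no spatial models, pedigrees or
  marker-based relationship matrices.
- The Wald test for replication is asymptotic (no Kenward-Roger).
- AMMI axis counts are not tested for significance; no GGE variant.
- Whether the replicate effect should be nested within treatment rather
  than crossed is design-dependent; crossed is the default and the only
  mode exercised by the generator.
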