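# Methods

`delibank` implements an item-bank construction workflow for delirium
screening instruments: starting from a persons × indicators matrix of
dichotomous symptom responses and per-person ratings of the four CAM
(Confusion Assessment Method) features, it screens out locally dependent
indicators, determines how many latent dimensions each indicator set
carries, fits two-parameter logistic (2PL) item response models, and
retains the indicators that are most informative where screening needs
precision — the median trait level of feature-positive evaluees.

## The measurement model

Each indicator *j* is a dichotomous symptom variable assumed to reflect a
continuous latent trait θ (e.g., severity of inattention), θ ~ N(0, 1):

    P_j(θ) = 1 / (1 + exp(−D·a_j·(θ − b_j)))

* `a_j` — discrimination: how sharply the response probability rises with
  the trait. Unitless slope; plausible clinical indicators run ~0.5–3.5.
* `b_j` — difficulty / symptom severity: the trait level at which the
  symptom is expressed with probability ½. On the θ scale (SD units).
* `D` — scaling constant, default 1.7, which places logistic parameters
  approximately on the normal-ogive (probit) metric. All outputs record
  the metric (`link`, `D`); information comparisons always use one fixed D.

Item information is `I_j(θ) = (D·a_j)² P_j(θ)(1 − P_j(θ))`, peaking at
θ = b_j with value (D·a_j)²/4. Under local independence, information adds
across items; the reliability of a trait estimate at θ* is
`TI(θ*) / (TI(θ*) + 1)` under the unit-variance prior.

## Pipeline stages and the choices inside them

**Tetrachoric correlations.** Pairs of dichotomous indicators are modeled
as thresholded bivariate normals; the latent correlation solves
P(X>τ_x, Y>τ_y; ρ) = p₁₁ with thresholds from the margins. The bivariate
normal CDF is computed from Owen's T function (machine precision,
vectorized), and ρ is found by bisection (52 halvings of [−1, 1], far
below the 1e−4 oracle tolerance used in tests). A pair is *inestimable*
when its 2×2 table has an empty cell, a margin with fewer than 5
positive or 5 negative responses, or a boundary solution |ρ̂| > 0.995.
This operationalizes "the model cannot estimate this correlation" in a
portable way; logically dependent indicator pairs (e.g., symptom-presence
followed by symptom-frequency) produce exactly such structural voids.
Estimation is pairwise complete-case. Matrices that are not positive
semidefinite are repaired for eigen-analysis by clipping eigenvalues at
1e−6 and rescaling to unit diagonal; the raw matrix is retained.

**Local-dependency screen.** Iteratively drops the indicator involved in
the most inestimable pairs until none remain (among droppable
indicators). Ties break toward the indicator with the more extreme
marginal proportion (farther from 0.5), then lexicographically, making
the result invariant to column order. Clinically essential indicators
can be force-retained; if inestimable pairs survive only among forced
indicators the screen stops with a warning rather than dropping them.

**Permuted parallel analysis.** Each permutation shuffles every
indicator's responses independently across persons — margins are
preserved exactly, all inter-indicator association is destroyed — and
the tetrachoric spectrum of the permuted data forms the null. A root is
significant when the observed eigenvalue exceeds the 97.5th percentile
of the corresponding permuted roots; the count m of *leading* significant
roots (stopping at the first failure) indexes dimensionality.
`n_permutations` defaults to 100 (40 is the floor needed to resolve the
97.5th percentile). Permutations whose tetrachoric matrix contains
inestimable pairs are redrawn up to 5 times; if voids persist (they
recur with the same probability on every redraw when an indicator is
rare), the offending pairs enter that permutation's matrix as 0 — their
exact value under the permutation null — and the event is logged.

**Factor models.** EFA uses principal-axis extraction (statsmodels) on
the PSD-repaired tetrachoric matrix with promax rotation for m ≥ 2.
Simple-structure CFA (each indicator on the factor of its largest
absolute EFA loading; ties to the lower index) and the bifactor model
(general factor on all indicators plus orthogonal specifics, factor
correlations fixed at zero) are fitted by unweighted least squares on
the off-diagonal correlations with L-BFGS-B. Two regularizers keep the
optimizer off pathological rays: a quadratic penalty on communalities
above 0.995 (Heywood boundary) and, in the bifactor model, a 1e−4 ridge
on specific loadings — a specific factor whose block carries no specific
variance is empirically underidentified from off-diagonals, and the
ridge selects the minimal-norm (zero) solution. Specific factors with a
single indicator are fixed at zero loading. Fit statistics use the
least-squares discrepancy F = Σ_{i<j}(r_ij − σ_ij)², χ² ≈ (n−1)·F
against the independence baseline, CFI = 1 − max(χ²−df,0)/max(χ²_B−df_B,0),
RMSEA = √(max(χ²−df,0)/(df(n−1))). These approximate, but are not, the
mean-and-variance-adjusted statistics of limited-information weighted
least squares software; absolute χ² values are therefore not comparable
across estimators, while the CFI/RMSEA good-fit regions behave as
expected in simulation (clean one-factor data lands at CFI > 0.94,
RMSEA < 0.05).

**Dimensionality adjudication.** One dimension is retained when parallel
analysis finds at most one significant root. Otherwise m > 1 is retained
on a preponderance of evidence: at least two of (a) m significant roots,
(b) the m-factor CFA improves CFI over the 1-factor model by ≥ 0.01,
(c) the bifactor model shows any indicator whose specific loading
exceeds its general loading. On a split, indicators partition by the
simple-structure pattern; sub-sets with fewer than 4 indicators are
reported but not IRT-modeled (latent-variable models below 4 indicators
are poorly determined).

**2PL estimation.** Marginal maximum likelihood via EM on a fixed
quadrature grid: 49 equally spaced nodes on [−6, 6] with renormalized
N(0,1) weights (equivalent results at 101 nodes to < 1e−3; the grid
quadrature converges superalgebraically for these smooth integrands).
The M-step solves per-item weighted logistic regressions by damped
Newton-Raphson in slope/intercept form. Missing responses contribute
nothing to the person likelihood (ignorable under the generator's
missing-completely-at-random mechanism). Convergence: largest absolute
parameter change < 1e−4, cap 500 iterations; the marginal log-likelihood
is asserted non-decreasing at every iteration. Identification: θ ~ N(0,1)
fixed, slopes kept positive (symptom-present coding). Full-information
MML replaces limited-information weighted least squares intentionally:
it is portable, handles missingness naturally, and agrees with it
asymptotically under the model.

**EAP scoring.** Posterior mean and SD over the same grid with the
N(0,1) prior; persons with no observed responses receive the prior back
(θ̂ = 0, SD = 1). EAP estimates are shrunken toward 0 — scores of
extreme-trait persons sit slightly below their true traits, which
slightly lowers percentile anchors relative to true-trait percentiles
(visible but immaterial in the selection-recovery simulations).

**Anchored selection.** θ₅₀⁺ is the 50th percentile
(linear-interpolation quantile) of EAP scores among persons rated
positive on the relevant CAM feature. Indicators are ranked by
information at θ₅₀⁺ (ties: smaller |b − θ*|, then id) and the top k = 5
are retained — four-plus indicators per trait are needed for stable
latent-variable modeling and returns diminish beyond five. A severe,
rare symptom with a sharp information peak far above the anchor
correctly ranks below a moderate symptom peaked at the anchor: screening
needs precision where the positives are, not where the sickest are.
Sensitivity analysis re-ranks at the 25th and 75th feature-positive
percentiles and reports pairwise top-5 overlaps and Kendall τ over full
rankings; selections are called "essentially the same" when both outer
percentiles share ≥ 4 of 5 picks with the median selection. When no
indicator reaches information 0.25 at θ₅₀⁺ (the peak information of an
a ≈ 0.59 item at D = 1.7 — a floor below which nothing measures well at
the median), the anchor falls back to the 75th percentile and selection
repeats there.

## The synthetic cohort generator

No screening cohort of this kind is publicly deposited, so the generator
emulates one: n = 4,598 evaluees, eight indicator sets (four CAM
features × direct-interview/observational mode), ten latent dimensions.
Latent traits are multivariate normal with correlation 0.6 between
dimensions of the same feature and 0.45 across features; responses are
2PL Bernoulli draws (D = 1.7); discriminations are uniform on
[0.5, 3.5]. Difficulty spans are feature-specific — most sets run from
mild to moderately severe (b ∈ [−1, 3] or [−1, 2.5]), while the
altered-level-of-consciousness observational set includes very severe,
rare signs reaching b = 4.5. That single severe set consequently loses
many indicators to degenerate margins at screening while the others lose
few, and two sets (inattention direct-interview; disorganized-thinking
observational, whose second dimension has only 3 indicators) split into
two dimensions — reproducing the qualitative structure reported for the
real cohort.

Feature-positive labels threshold the latent trait of one designated
dimension per feature, then flip with probability 0.02 (symmetric
misclassification). The four label traits are equicorrelated (0.45,
cross-feature), so they admit an exact one-factor reduction; the joint
probability that the CAM Boolean rule (feature 1 ∧ feature 2 ∧
(feature 3 ∨ feature 4)) fires is computed by 101-node Gauss–Hermite
quadrature over the common factor, including the flip channel, and a
common additive threshold shift is solved (Brent) so the delirium
prevalence is exactly 13.3% in expectation. This calibration is
deterministic to machine precision, which keeps identical seeds giving
byte-identical cohorts. Base marginal feature rates before the shift:
20% / 30% / 25% / 20% for features 1–4. Missingness is completely at
random at 2% (a mechanism had to be chosen; MCAR is the weakest
assumption compatible with pairwise-complete correlation estimation and
likelihood-based IRT). One logically dependent pair (presence → frequency)
is planted in the acute-change observational set; the child is forced to
0 wherever the parent is 0, producing the empty-cell signature the
screen is built to catch.

**What the generator does not emulate.** Clinician CAM ratings are
replaced by noisy trait thresholds — real ratings integrate multiple
dimensions and interviewer judgment. Responses are exactly 2PL given a
single dimension (no guessing, no local dependence beyond the planted
pairs, no differential functioning by age/sex/race). The logistic link
with D = 1.7 approximates the latent-normal model underlying the
tetrachoric only to ~0.01 in the CDF; for extreme difficulties
(|b| ≳ 2.5) the fatter logistic tails bias tetrachoric correlations and
factor loadings by up to ~0.05–0.07, which is why loading-recovery
claims are stated for moderate difficulty ranges. Passing tests
demonstrate internal consistency of the method under its own model, not
performance on real interview data.

## Problem sizes used in validation

Oracle-agreement checks run at full precision on 50 random 2×2 tables
(bisection against 64-point Gauss–Legendre integration of the bivariate
normal) and 100 response vectors (10,001-point grid posterior).
Parameter recovery uses 50 cohorts of n = 4,598 with 10 items each.
Parallel-analysis calibration uses 500 null data sets (k = 10,
n = 1,000) and 50 + 50 one-/two-factor cohorts at n = 4,598. End-to-end
selection recovery uses 50 two-set cohorts at n = 4,598 with
noise-free labels, so the truth's top-5 is computable in closed form
(median trait of positives = Φ⁻¹((Φ(c)+1)/2)). The generator-calibration
check simulates the full default cohort once and compares the CAM
prevalence to 13.3% within three binomial standard errors.

## Known limitations

* Fit statistics are least-squares approximations; absolute χ² values
  differ from mean-and-variance-adjusted limited-information estimators.
* The bifactor "large secondary loadings" flag uses the ≥ 1 indicator
  rule; no count threshold is imposed beyond that.
* The adjudication rule replaces expert-panel judgment with a fixed
  0.01 CFI-improvement vote; panels seeing interpretable secondary
  factors may decide differently. Manual overrides are available via
  forced-retain lists and by fitting models directly.
* Tetrachoric estimation assumes an underlying bivariate normal; with
  the logistic generator this is an approximation that degrades in the
  tails (see above).
* No computerized adaptive testing, no polytomous models, no
  differential item functioning analysis, no external validation cohort.
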