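# Methods

This note documents the statistical models, numerical choices and the
synthetic-data design behind `irtval`, and what the test suite does and
does not establish.

## Latent-trait model

All parametric stages assume a logistic graded response model (GRM): one
latent trait θ, scaled to mean 0 and SD 1 in the calibration population,
with an effective reporting range of [−4, 4].  Item *i* with m ordered
categories has a slope a\_i > 0 and strictly increasing thresholds
b\_{i,1} < … < b\_{i,m−1} (θ units).  Cumulative curves are plain logistic
— no D = 1.7 scaling — so slopes here match the convention of mainstream
IRT software for graded models; published slope ranges around 2–5 are
comparable only in this metric.  Category probabilities are adjacent
differences of the cumulative curves; Fisher information is
I\_i(θ) = Σ\_k (dP\_k/dθ)²/P\_k, test information is the sum over
administered items, SE(θ) = 1/√I, reliability = 1 − SE², and
T = 10θ + 50.

## Estimation

**MML-EM.** Calibration maximises the marginal likelihood over a fixed
quadrature grid: 49 equally spaced nodes on [−6, 6] with renormalised
N(0, 1) weights.  The grid resolution was checked against a 2001-node
grid (conditional probabilities agree to ~2·10⁻⁴ for slopes up to 5).
The M-step reparameterises each item as (log a, b₁, log threshold gaps),
which enforces positivity and ordering without constrained optimisation,
and takes a bounded number of quasi-Newton steps with analytic gradients
(a generalised EM step; the expected complete-data log-likelihood can
only increase, so the marginal log-likelihood is non-decreasing and this
is asserted every cycle).  Convergence: max absolute change in (a, b)
below 1e-4, cap 500 cycles.  Parameter standard errors come from the
empirical (outer-product) information of the per-person marginal scores,
computed as posterior expectations of complete-data scores.

**Scoring.** ML maximises the pattern log-likelihood on [−4, 4] (the GRM
pattern likelihood is log-concave, so bounded Brent search is exact to
its tolerance; verified against a 10 001-point grid).  Patterns consisting
exclusively of the lowest (highest) category have no interior ML maximum
and are clamped to −4 (+4) with an explicit flag, so reports can count
them separately.  EAP is the posterior mean under the N(0, 1) prior (its
SE the posterior SD); MAP adds the prior precision to the information.
The prior is fixed; no latent-density estimation is attempted.

## Dimensionality and local independence

Polychoric correlations use the standard two-step estimator: thresholds
from inverse-normal cumulative marginals, then the pairwise ρ by bounded
maximisation of the bivariate-normal contingency likelihood on
[−0.999, 0.999].  Rectangle probabilities are computed by Gauss–Legendre
integration (32 nodes per row interval) of φ(x)·ΔΦ terms with thresholds
clipped at ±8 — accurate to ~1e-10 and fully vectorised.  Estimates at
the ±0.999 bound are flagged as non-converged.  Each pair's asymptotic
variance comes from the numerical second derivative of its profile
log-likelihood.

The one-factor model is fitted to the (eigenvalue-smoothed, if needed)
polychoric matrix by diagonally weighted least squares over the unique
correlations, weights = reciprocal scaled asymptotic variances (unit
weights as fallback); loadings are bounded at ±0.999 and a Heywood flag
raised when the bound binds.  χ² = (n−1)·F\_min with the independence
model as CFI/TLI baseline; RMSEA uses (n−1); SRMR is the RMS off-diagonal
residual.  These are **unscaled DWLS statistics**: no mean-and-variance
(scaled/robust) adjustment is computed, which is flagged in every report.
Scaled indices from full WLSMV software will differ — RMSEA especially —
and no attempt is made to match them.  If the baseline χ² does not exceed
its df (e.g. an identity matrix), CFI is reported as 1 with a
degenerate-baseline flag.  The exploratory evidence (eigenvalue ratio
λ₁/λ₂ > 4, λ₁/p ≥ 20%) is computed from the polychoric matrix itself.
A one-factor model has positive df only for p ≥ 4 items; the pipeline
skips the CFA stage below that with an explicit reason.

## Mokken scalability and monotonicity

H coefficients follow the polytomous Loevinger construction:
H\_ij = cov(X\_i, X\_j)/cov\_max, where cov\_max is the covariance of the
comonotonic (sort-and-pair) coupling of the two observed marginals; item
and scale coefficients are ratio-of-sums aggregates.  cov ≤ cov\_max
always, hence H ≤ 1.

Monotonicity is operationalised (the traditional check is visual): for
each item, persons are grouped by rest score — ascending distinct values
accumulated until each group holds at least minsize = max(n/10, 50)
persons, a common default where none is prescribed — and a violation is a
decrease greater than 0.03 in P(X ≥ k) between adjacent groups.  The
0.03 tolerance absorbs binomial noise at the default group sizes; at
n = 5000 GRM-generated data produce zero violations, while at n ≈ 1000 a
handful of small violations can appear by chance and are reported as
counts, not failures.  Rest-score curves are exported for inspection.

## S-X² item fit

Observed category counts within rest-score groups (summed score over the
other items) are compared with their model-implied expectations,
E\_{s,k} = N\_s · ∫P\_{ik}(θ)P(S\_{−i}=s|θ)φ(θ)dθ / ∫P(S\_{−i}=s|θ)φ(θ)dθ,
using the generalized Lord–Wingersky recursion for P(S|θ) (verified
against full 5⁴ pattern enumeration).  Sparse tables collapse in two
stages: score groups merge toward the nearer distribution tail (ties to
the lower side) until each group's expected total reaches 2m, then
adjacent category cells merge within a group until every expected cell
reaches 1.  df = Σ\_groups (cells − 1) − (m free item parameters); items
with df ≤ 0 are reported untestable rather than flagged.  The two-stage
scheme was chosen because collapsing score groups alone leaves
conditionally rare category cells and measurably inflates the null
rejection rate; with it, refitting well-specified data flags ≈ 0.1% of
items at the p < 0.001 criterion, and a grossly misspecified slope is
flagged essentially always at n = 2000.

## DIF screening

Per item, three nested proportional-odds models: M1 (trait), M2 (+ group),
M3 (+ trait × group), fitted by quasi-Newton with analytic gradients and
ordered-intercept parameterisation (log-gap); separation triggers a
ridge-stabilised refit with a warning.  The trait score entering these
regressions is the EAP from the full bank — finite for all-extreme
patterns, unlike ML.  DIF is flagged at ΔR²(M3−M1) ≥ 0.02 (McFadden);
uniform vs non-uniform classification follows which component reaches the
threshold.  Two-level and ordered groups enter as a single ordinal code;
unordered multi-level groups as a reference-vs-level dummy block with ΔR²
on the whole block.  No multiple-testing correction is applied — the
effect-size rule is the criterion.  Purification rescores the trait from
unflagged items until the flag set stabilises (cap 10 rounds).  Each
group level must hold at least 50 persons (configurable floor).

## CAT simulation

Post-hoc replay: the recorded response to each selected item is revealed
in turn.  Selection is maximum Fisher information at the current estimate
(ties to the lowest index), starting at the most informative item for
θ = 0.  The interim estimator is ML; while the pattern is all-extreme the
estimate is pinned at ∓4 so information-based selection still proceeds.
Stopping is checked after each response: SE·10 ≤ 3 on the T metric
(reliability ≈ 0.91) with no minimum-item rule by default, or 12 items;
fixed-length mode administers exactly L items.  A one-item administration
is therefore possible in principle; observed minima of 2–3 items arise
from the data.  Cohort summaries report the reliability ≥ 0.90 fraction
over all persons, with boundary-clamped persons counted separately
(conventionally they are excluded from precision plots).  Short forms are
user-supplied fixed subsets scored non-adaptively.

## Synthetic cohorts

The generator emulates a general-population internet panel answering a
strong participation-type bank: θ ~ N(0, 1); 35 five-category items with
slopes uniform on [2.4, 4.8] and thresholds uniform (sorted, minimum gap
0.05 to avoid near-degenerate categories) on [−2.5, 0.6] by default; a
44-item variant uses slopes [2.3, 4.2] and thresholds [−2.1, 1.6].
Ceiling effects are emulated by shifting the θ mean — found by root
finding on the increasing branch of the model-implied all-extreme
fraction, to within far less than 0.005 — rather than by moving
thresholds, keeping bank parameters interpretable; targets of 7.7% and
2.8% all-extreme patterns reproduce the two study conditions.
Demographic labels (gender 52.4% female, three age bands with uniform
ages inside, education, region, ethnicity) follow Dutch
general-population proportions and carry no response effect unless a DIF
effect is injected (uniform DIF = threshold shift for the focal group;
non-uniform = slope multiplier).  All draws come from numpy's seeded
PCG64 generator; identical seeds give identical cohorts.

What the generator does **not** emulate: multidimensionality, local
dependence beyond what a test injects, non-normal or skewed trait
distributions, response styles, missing data, panel-recruitment artefacts
and longitudinal structure.  Passing tests therefore demonstrate that the
machinery is correct and calibrated under the stated conditions, not that
any particular real instrument satisfies them.

## Problem sizes and determinism

Tests and the acceptance script use cohorts of n = 1000–1002 with 10-,
35- and 44-item banks, 120 replicates for the S-X² null calibration and
100 for DIF power — sizes chosen so a full run completes in minutes on a
single CPU while leaving the binomial bounds on the calibration checks
meaningful.  Every stochastic step is seeded; the pipeline writes
byte-identical JSON reports for identical seed and config.

## Known limitations

* Fit indices are unscaled DWLS; they are not comparable to published
  WLSMV scaled values (RMSEA in particular).
* The S-X² collapsing scheme, while calibrated, is one of several in use;
  absolute p-values near the flagging threshold can differ between
  implementations.
* DIF screening assumes proportional odds within each model.
* No multiple-group concurrent calibration, no test–retest/longitudinal
  support, no live-CAT serving (post-hoc replay only).
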