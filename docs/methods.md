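# Methods

## The joint model

`covqtl` tests, marker by marker, whether genotype explains the joint
distribution of a longitudinal growth trait and a terminal static trait.
For individual *i* the stacked observation is
`Y_i = (y_i(t_1), …, y_i(t_T), z_i)`; with `J` observed genotype classes
at a marker the likelihood is a genotype-partitioned multivariate normal

    L(Ω) = ∏_{j=1..J} ∏_{i ∈ class j} N(Y_i | μ_j, Σ).

**Mean structure.** Rather than estimating `T` free per-time means per
genotype, the trajectory part of `μ_j` is a logistic growth law
`g_j(t) = a_j / (1 + b_j e^{−r_j t})` — asymptote `a_j` (trait units),
initial-condition shape `b_j` (dimensionless, `g(0) = a/(1+b)`), relative
growth rate `r_j` (per time unit) — with the static-trait mean `μ_jz`
appended as the (T+1)-th coordinate. This is the functional-mapping idea:
four parameters per genotype regardless of how densely the trait was
measured, and biologically interpretable contrasts.

**Covariance structure.** One `Σ` is shared by all genotype classes (it
carries no `j` index in the likelihood). Its longitudinal block is a
stationary first-order autoregression, `Σ_y[s,t] = σ_y² ρ_y^{|s−t|}`,
indexed by measurement order. The static trait has variance `σ_z²` and
couples to the trajectory through a correlation coefficient `φ`. The text
the model derives from fixes only that the cross block is "composed of φ
and σ_z²"; the exact T-vector is a design choice with two implemented
conventions:

* `decay` (default): `Σ_yz[t] = φ σ_y σ_z ρ_y^{T−t}` — the static trait,
  measured after the last longitudinal time point, correlates most with
  that last measurement and the correlation decays backwards at the AR(1)
  rate. This embeds `z` as one further step of the same Markov chain
  (rescaled to variance `σ_z²`), which has two consequences we exploit:
  `Σ` is positive definite whenever `|ρ_y| < 1` and `|φ| < 1`, and its
  inverse is tridiagonal, giving O(T) likelihood evaluations through
  innovation (conditional-regression) formulas.
* `constant`: `Σ_yz[t] = φ σ_y σ_z` for all `t`; positive definiteness is
  then a genuine runtime condition, checked by Cholesky, with violations
  mapped to −∞ log-likelihood rather than clamped.

Both conventions are exposed (`cross_structure=` in the library,
`--cross-structure` on the CLI); results tables name the covariance
parameters `sigma2_y, rho_y, phi, sigma2_z`.

## Estimation

Each model variant is maximized by Nelder–Mead simplex in an
unconstrained parameterization: variances on the log scale, correlations
through atanh, curve parameters natural. Parameter points that break the
model — non-positive asymptote, logistic denominator crossing zero on the
grid, overflowing variance transform, non-PD `Σ` — evaluate to +∞ so the
simplex never sees an exception.

Warm starts are deterministic and data-driven: per-class logistic
least-squares fits of the class mean series (multi-start trust-region
least squares; starts `a₀ = 1.05·max(y)`, `r₀ ∈ {0.1, 0.5, 1.0}`, `b₀`
solved from the first time point; box `a ∈ (0, 10·max y]`,
`b ∈ (−0.99, 10³]`, `r ∈ [−5, 5]`; ties broken by start order), class
means for `μ_jz`, pooled residual variance and lag-1 autocorrelation for
`(σ_y², ρ_y)`, and the last-time/static residual correlation for `φ`.

Convergence tolerances are `fatol = 1e−6`, `xatol = 1e−4` with a generous
evaluation cap (2000·dim) for reference fits; scan-internal fits
(permutation thresholds, power replicates) use `fatol = 1e−5`,
`xatol = 5e−4`, applied identically to the statistics being thresholded
and to the thresholds themselves so detection stays internally calibrated.

Two numerical guards matter in edge cases. First, variances are searched
as `σ² = floor + e^θ` with a data-scale floor (`1e−9·(mean squared value
+ 1)`): a degenerate phenotype coordinate (zero sample variance) would
otherwise send nested fits down an unbounded likelihood cliff at
independent rates and produce spurious LR values; with the floor both
fits level off at the same bounded optimum and the LR cancels. Second,
model mis-specification never raises inside a genome scan — failed fits
return `log_lik = −∞` and the marker is flagged, not fatal.

**Batched engine.** Permutation thresholds need on the order of 10⁴
marker fits per scan. Because the decay covariance has a tridiagonal
precision matrix, the likelihood touches the data only through class sums
of `y_d`, `y_d²` and `y_d·y_{d+1}` — sufficient statistics that make an
evaluation O(T), independent of sample size. `covqtl._batch` runs
thousands of these simplex searches in lockstep (one vectorized objective
evaluation per step, masked reflect/expand/contract/shrink updates
mirroring the classic algorithm, converged problems frozen). The scipy
path remains the reference implementation; the test suite asserts the two
engines reach the same optima (~1e−8 agreement on identical problems).
Missing genotypes, non-biallelic markers and the `constant` convention
fall back to the scipy path automatically.

## Test hierarchy and classification

* **Overall test**: full model (per-class `(a_j, b_j, r_j, μ_jz)`) vs the
  no-QTL model (one shared set; 4J+4 vs 8 parameters). The statistic is
  `LR = 2(ℓ_full − ℓ_null)`, clipped at 0. Significance uses a
  genome-wide empirical threshold: each permutation jointly reshuffles the
  individuals' whole `(y, z)` records against the genotype rows —
  preserving the dynamic–static correlation, since the null is about
  genotype–phenotype association, not about φ — rescans the markers, and
  records the genome-wide maximum LR; the threshold is the (1−α) quantile
  of those maxima (default 1000 permutations in the CLI scan).
* **Growth sub-test**: full vs shared `(a, b, r)` with per-class `μ_jz`.
* **Biomass sub-test**: full vs per-class curves with shared `μ_z`.

`Σ` is re-estimated under every constrained model (a full likelihood
ratio, not a fixed-Σ profile test). Sub-tests default to χ² reference
distributions with df `3(J−1)` and `(J−1)` at α = 0.05 — they are
marker-local, so standard asymptotics are defensible — with an exact
marker-local permutation mode available (`--subtest-null permutation`).
No multiplicity correction is applied across the two sub-tests; α is a
knob.

Classification of an overall-significant marker is a pure function of the
two sub-tests: growth-only → `growth`; biomass-only → `biomass`; both →
`pleiotropic`; neither → `covariation` — the joint test detected signal
that neither marginal mean carries, i.e. the locus acts through the
covariation between trajectory and terminal trait.

**Effect and heritability trajectories.** For a biallelic fit the genetic
effect is `effect(t) = (g_1(t) − g_2(t))/2`, and heritability is the
variance partition `h²(t) = σ_g²(t) / (σ_g²(t) + σ_y²)` with
`σ_g²(t) = Σ_j p_j (g_j(t) − ḡ(t))²` at observed class frequencies `p_j`
(for `J ≠ 2` the genetic standard deviation replaces the half-difference).
The static trait gets the scalar analogues with `σ_z²`. This variance
partition is this package's declared reconstruction — reasonable, unit
tested, but not the only possible definition.

Markers are skipped (flagged, not errored) when any genotype class has
fewer than `min_class_size = 5` individuals — four mean parameters per
class need data. Individuals with any missing time point are dropped
(complete-case); individuals missing a genotype call are dropped from
that marker only.

## The synthetic-data generator

The generator emulates the motivating study system: an *Arabidopsis*-style
RIL population scored weekly (t = 1..9) for leaf number with whole-plant
dry weight at the end of the life cycle.

* **Genotypes**: binary (RILs are effectively homozygous), 1000 markers
  on one chromosome, Markov chain with switch probability 0.05 between
  neighbours (adjacent-marker correlation 0.9, Haldane, no interference),
  allele frequency 1/2; one causal marker in the middle.
* **Phenotypes**: each individual's `(y, z)` is multivariate normal with
  its causal-genotype mean vector and the decay-convention `Σ`.
  Scenarios 1–4 set φ = 0.65, 0.4, 0.2, 0.
* **Causal effect**: genotype curves `a = (55, 45)`, `b = (12, 12)`,
  `r = (0.7, 0.6)` — the leaf-number regime of the working example —
  with `ρ_y = 0.7`, `σ_z² = 1`, static means centred at 5.05 (the
  observed mean dry weight scale). The static means are split to ∓δ with
  `δ² / (δ² + σ_z²) = h²`, **opposing** the curve effect: the genotype
  with the taller, faster trajectory gets the smaller dry weight,
  mirroring the parental contrast of the working example (more leaves,
  opposite dry-weight trend). The anti-alignment matters: with φ > 0 it
  is what makes the joint test's noncentrality grow with the correlation,
  i.e. what gives the joint model its advantage on strongly correlated
  data.
* **Heritability calibration**: the longitudinal residual variance is
  solved (scalar root-find) so the curve heritability
  `σ̄_g² / (σ̄_g² + σ_y²)` — time-averaged genotype variance of the mean
  curves at frequencies 1/2 — equals the requested h² (0.05 or 0.10).
  `h² = 0` collapses both genotypes onto one curve and one static mean
  (size-control studies), with `σ_y²` held at the 0.05-calibration value
  (the null statistic is scale-invariant).

What the generator does **not** emulate: genotyping error and missing
calls, non-Gaussian or heteroscedastic residuals, multiple or epistatic
QTLs, selection/segregation distortion, and real linkage-map geometry.
Passing power and calibration tests therefore demonstrates correctness of
the method under its own assumptions, not robustness to their violation.

## Power study protocol

Per cell (scenario × n × h²): detection thresholds are computed once from
a reference replicate — 100 permutations scanning 100 evenly spaced
markers for the joint and univariate-functional-mapping LR thresholds,
500 cheap vectorized permutations of the maximum ANOVA F over all 1000
markers — then 200 fresh replicates are simulated and the causal marker
fit under each method. The scan-subset size and shared-threshold
approximation (`threshold_mode="shared"`; `"per-replicate"` exists but is
computationally disproportionate) are runtime choices of this package;
evenly spaced subsampling keeps the effective number of independent tests
close to the full panel's because neighbouring markers are highly
correlated.

The **traditional comparator** declares detection when either one-way
ANOVA on the static trait or univariate functional mapping on the
trajectory (this package's own machinery with the static coordinate
removed — logistic means, AR(1) covariance) rejects at its own
genome-wide 5% threshold; an all-must-reject variant is a flag
(`traditional_rule="both"`).

The curve-recovery report refits the joint model at the causal marker
across replicates and checks pointwise 95% confidence bands from the
delta method (numerical Hessian of the negative log-likelihood at the
optimum, gradient of the logistic curve in `(a, b, r)`).

## Known limitations

* Single-marker association only: no interval mapping between markers, no
  multi-QTL or epistatic models, no joint estimation across linked loci.
* One longitudinal trait plus one static trait; AR(1) is the only
  longitudinal covariance family (no antedependence or nonparametric
  structures).
* The exact cross-covariance vector of the source analysis is unknowable
  from its description; both implemented conventions are documented and
  `decay` is the default on positive-definiteness and interpretability
  grounds.
* Permutation counts: the CLI scan defaults to 1000 permutations; the
  power harness uses 100 per cell (the source describes both figures in
  different places). Thresholds at 100 permutations carry quantile noise
  of a few LR units.
* χ² sub-test reference distributions are asymptotic; at small n the
  permutation sub-test mode is the safer choice.
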