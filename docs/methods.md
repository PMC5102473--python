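# Methods

## The dimensionless growth-model framework

Every determinate growth trajectory handled here is written as

    m(t) = M f(s) + M_c,    s = k (t − t_c),

with asymptotic mass `M` (g), growth constant `k` (1/day), time offset
`t_c` (day), mass offset `M_c` (g; zero unless input data specify
otherwise) and a dimensionless sigmoid `f`. The three classical sigmoids
are supported:

| model           | f(s)            | C = max df/ds | d = f(argmax) | D = C/d |
|-----------------|-----------------|---------------|---------------|---------|
| logistic        | 1/(1+e^−s)      | 1/4           | 1/2           | 1/2     |
| Gompertz        | exp(−e^−s)      | 1/e           | 1/e           | 1       |
| von Bertalanffy | (1−e^−s)^3      | 4/9           | 8/27          | 3/2     |

`C` fixes the peak growth rate `G_max = M k C`; `d` is the fraction of
asymptotic mass at the inflection (50% logistic, ≈37% Gompertz, ≈30% von
Bertalanffy), so the body mass at maximum growth is `BMatMG = M d`. Two
mass-specific normalisations follow: `kC = G_max / M = k C` and
`kD = G_max / BMatMG = kC / d = k D`. These identities are exact algebra
and the test suite verifies the constants against brute-force numerical
maximisation of `df/ds` (tolerance 1e-6). Note that `D = C/d` for the
logistic model is 1/2 — it follows directly from C = 1/4 and d = 1/2.

The von Bertalanffy cubic is only a mass fraction on the branch `s > 0`
(it is negative for `s < 0`); numerical maximisation and simulated series
are restricted to that branch.

### Curve fitting

`fit_growth_curve` minimises squared mass error with trust-region least
squares from 11 data-derived starts (asymptote factors 1.05/1.5/3 of the
maximum observed mass; `k` from the endpoint log-slope scaled by
0.5/1/2; `t_c` at the age midpoint and endpoints), convergence tolerances
1e-12. Two practices common in fossil growth studies are supported
explicitly and flagged in the output: fixing the asymptote to a
literature value (removing `M` from the free set) and appending a
hypothetical neonate (age, mass) point. Hypothetical neonate masses must
be supplied by the caller; no empirical neonate-mass formula is built in.
Units are fixed internally (g, day, g/day); converters belong at the I/O
boundary.

`time_to_fraction` inverts `f` in closed form for the logistic
(`s = logit(p)`) and Gompertz (`s = −ln(−ln p)`) models and by bracketed
root finding (Brent, tolerance 1e-12) for von Bertalanffy.

## Allometric regression and the shear diagnostic

The allometric hypothesis `G_max = a M^b` is fit as weighted OLS on
log10 axes; since `G_max = M · kC`, the equivalent form `kC = a M^(b−1)`
differs only by the planar shear `(x, y) → (x, x+y)`. Consequences that
are exact algebra (and tested as such): the slope shifts by exactly one,
residuals are identical, and the slope CI width is unchanged. R² is *not*
shear-invariant: with identical residual sums of squares, R² grows under
the shear exactly when the total sum of squares grows. In population that
requires `b > 1/2`; in the empirically relevant regime (`b ≈ 0.75`,
groups of tens of species, log10 scatter ≤ 0.35 over ≥ 2.5 decades of
mass) the inflation is essentially deterministic, and that is the regime
in which the property tests assert it. For `b < 1/2` the shear deflates
R² instead; the diagnostic is about the *choice of variables* changing
R² while leaving the hypothesis test untouched, not about a universal
direction.

Confidence intervals use the t distribution with n−2 degrees of freedom.
Weighted fits give each taxon total weight one, split equally among its
points; R² is 1 − weighted RSS / weighted TSS about the weighted mean.
The 95% confidence band is the standard mean-response band; the
prediction band adds the residual variance of a single unit-weight
observation. Grid points outside the fitted data's x-range are computed
but flagged as extrapolated. `fixed_slope_adjust` reduces each point to
the intercept it would imply under a fixed slope (b = 0.75 or 0.66 by
convention), i.e. its log rate adjusted to a 1 g body mass.

## Overlap classification

Species-level overlap is measured in (log10 mass, log10 rate)
coordinates three ways, in increasing order of restrictiveness:

1. **Convex hulls** (shapely): membership counts of every group's points
   in every group's hull. Boundary points count as inside, with tolerance
   1e-9 in log10 units (membership is computed as distance-to-geometry ≤
   tolerance, which also covers degenerate segment/point hulls for groups
   with < 3 or collinear points).
2. **Residual parallelograms**: the regression line shifted through the
   extreme residuals, over the data's x-range. These contain the hulls by
   construction, so they show at least as much overlap.
3. **Nearest regression line**: each point assigned to the group whose
   line is nearest, by perpendicular Euclidean distance in the log-log
   plane (vertical distance available as an option); ties go to the
   point's own group when it is among the tied lines.

`pooled_overlap` repeats the machinery after pooling all endotherms and
all ectotherms. The hull "overlap fraction" is the intersection area
relative to the smaller hull, estimated on a 512×512 rasterisation of
the joint bounding box; it is a convenience metric with no inferential
claim attached.

## Curvature model selection

Log-log rate data are fit with the seven intercept-containing subsets of
{x, x², x³} (linear, quadratic1 = {x, x²}, quadratic2 = {x²},
cubic1 = {x, x², x³}, cubic2 = {x, x³}, cubic3 = {x², x³},
cubic4 = {x³}); the label→powers map is overridable. Models are ranked by
Gaussian AICc,

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1),

with `k` counting coefficients plus one for the residual variance;
weighted data use the weighted RSS. ΔAICc is taken to the per-group
minimum (ties broken toward smaller `k`), and ΔAICc < 2 marks strong
support. Models with `n ≤ k+1` are inadmissible and reported as NaN.

One property of AICc worth stating: under an exactly linear truth, the
probability that some higher-order model attains ΔAICc = 0 does not
vanish with more data (AICc is not a consistent selector) — it is ≈20%
with this family, independent of the noise level because nested RSS
ratios are scale-free. Recovery checks therefore use the strong-support
criterion for the linear case (true rate ≈92% at n = 40) and best-model
identity for the cubic case (≈100%).

## Growth–metabolism tests

`bmr_adjust` rescales a BMR measured at mass `M_met` to adult mass under
`BMR ∝ M^0.75` within ontogeny. `direct_test` evaluates the fixed
proportionality `BMR = c · G_max` (`c` = 0.6 by default, absorbing the
unit bridge between watts and g/day) and reports the worst over- and
under-prediction factors, both clamped at ≥ 1. `transitivity_report`
runs the three pairwise log-log regressions kC~M, BMR~M, BMR~kC.

The synthetic metabolic generator draws `BMR = a1 M^b1 10^ε_B` and
`kC = a2 M^(b2−1) 10^ε_G` with independent noises by default. Under that
model the population identity r(BMR, kC) = r(BMR, M) · r(kC, M) holds
exactly, so R²(BMR~kC) = R²(BMR~M) · R²(kC~M) — always below both
marginals, which is the fallacy-of-averages geometry the generator
demonstrates, and the closed form the tests check against
(`expected_r2_bmr_kc`). What the generator deliberately does *not*
emulate: real compilations show a cross-correlation far below even that
product, implying residual structure (e.g. metabolic-class offsets
anti-aligned with the mass covariance) beyond a single shared mass
driver with independent noises. Passing tests therefore show the
decoupling mechanism, not the full strength of the empirical
non-transitivity. With a shared (rather than independent) noise draw the
covariance acquires an extra `+sd_B sd_G` term; because the mass-induced
covariance is negative (b2 − 1 < 0), same-sign shared noise *shrinks*
the correlation magnitude here — also verified against the closed form.

## The ecological-fallacy bootstrap

A scalar-trait classification demo: two trait distributions (normal
stand-ins parameterised by their means — 83.1 and 72.0 kg for adult male
and female body mass — with user-chosen sd, or empirical samples), a
sample of size N drawn wholly from one, classified by nearest hypothesis
mean. `minimal_group_size` finds the smallest N whose worst-case correct
classification rate reaches the confidence level (default 0.95, 10 000
replicates), by doubling then bisection. The `pure_or_mixed` scenario
adds a third hypothesis — a 50/50 mixture with each observation's source
drawn independently — which halves the relevant mean separation and
roughly quadruples the required N; with unknown mixture odds the problem
has no finite N, reported as unattainable. Because the bundled
distributions are parametric stand-ins rather than survey microdata, the
checks are against the normal-theory requirement N ≥ (2σ z₀.₀₅/Δ)² and
the pure < mixed ordering, not against any particular published N.

## Synthetic data: what it emulates and what it does not

`generate_group` draws log10 mass uniformly over a group-specific range
and log10 kC from the group power law plus Gaussian scatter; G_max,
BMatMG and kD are then derived exactly under a declared sigmoid (default
Gompertz), so the algebraic identities hold by construction. The default
four-group template (two endotherm groups with intercepts ≈1–1.3 decades
above two ectotherm groups, scatter 0.30–0.50, overlapping 4–5-decade
mass ranges) reproduces the qualitative geometry of real compilations:
cleanly separated group regressions with heavily overlapping hulls.
`generate_age_mass` spaces ages over a window in the dimensionless
variable `s` and applies multiplicative Gaussian noise; truncating at
`s ≤ 0` emulates fossil series that end before the inflection, where a
free asymptote is badly constrained (the simulated contrast the tests
assert). Not emulated: phylogenetic covariance, per-taxon replicate
structure, measurement-era heterogeneity, and the residual structure
noted above for metabolic data — so green tests validate the machinery
and the stated statistical mechanisms, not empirical conclusions about
any particular clade.

All generators are seed-deterministic; multi-group convenience wrappers
derive per-group seeds from a master seed below 2^31.

## Numerical choices

- log10 throughout the allometry (slopes are base-invariant; intercepts
  are reported in log10 units).
- Point-in-polygon boundary tolerance 1e-9 log10 units; nearest-line
  tie tolerance 1e-12.
- AICc of an exact fit (RSS = 0) is −∞, which correctly ranks it best.
- Growth fits bound `M, k > 0`; non-convergence of every start raises a
  fit error carrying the taxon name.
- Problem sizes in the test suite (e.g. 200-seed recovery runs, 1000
  shear datasets, 100 oracle-checked hull datasets, 4000-replicate
  bootstrap searches) were chosen so the full suite completes in well
  under a minute while keeping Monte-Carlo error small relative to every
  asserted margin.

## Known limitations

- OLS only; no phylogenetic regression (PIC/PGLS), RMA/SMA, or
  heteroscedasticity-robust errors.
- Point estimates only: fit covariance is not propagated from growth
  curves into the allometry.
- The hull overlap area fraction is rasterised, not exact.
- Reproduction of published species-level results requires the source
  compilations, which are not redistributed; `scripts/validate_external.py`
  runs those analyses on user-transcribed tables.
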