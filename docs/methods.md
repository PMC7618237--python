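# Methods

## The outcome measure

The pipeline's primary quantity is the unconditional probability of
dying from a set of causes between two exact ages — the probability a
person would face if only those causes operated.  It is computed from
an abridged lifetable restricted to the causes of interest: band death
rates `m` (deaths per person-year, summed over the cause set within
each age band) are converted to conditional probabilities of dying
with

    q = n·m / (1 + (n − aₓ)·m),

where `n` is the band width in years and `aₓ` the separation factor
(average years lived in the band by those who die in it), and the
probability over the age range is one minus the product of the band
survival factors `1 − q`.  Because competing causes never enter `m`,
the measure depends only on the rates of the cause set: it is
unaffected by mortality from other causes and by the population's age
structure (beyond composition within bands).

Defaults and their rationale:

- **Age grid.** 17 contiguous half-open bands covering [0, 80): an
  infant band [0,1), a childhood band [1,5), and fifteen 5-year bands.
  Mortality above 80 is ignored by construction — the measure is a
  probability *before* age 80, not a life expectancy.  The SDG-3.4
  variant uses eight 5-year bands on [30, 70) and only cause groups
  tagged as cancers, cardiovascular, chronic respiratory, or diabetes.
- **Separation factor.** `aₓ = n/2` for every band, including infancy.
  This matches the convention of the WHO lifetable method behind the
  SDG 3.4 indicator on 5-year bands (`aₓ = 2.5`).  The usual downward
  skew of `a₀` in all-cause infant mortality is driven by perinatal
  deaths and is not clearly applicable to NCD-only schedules, so the
  mid-band value is the documented default; `aₓ` is per-band
  configuration on `AgeGrid` for users who want a different infant
  convention.
- **Precision.** Probabilities are carried at full float precision;
  any display rounding (e.g. one decimal in percentage points) is the
  caller's concern and never feeds classification or decomposition.

## Cause groups

All analyses run on 20 mutually exclusive, collectively exhaustive NCD
cause-of-death groups: 16 named leading causes or aetiologically
related groups, plus four residual groups (other circulatory diseases,
other malignant neoplasms, other neuropsychiatric conditions, other
NCDs).  The assignment of a data source's detailed cause codes to the
20 groups is configuration (YAML), validated on load for the 16+4
structure and mutual exclusivity.  The packaged default map carries
the group labels themselves as codes (an identity map), which is the
schema the synthetic generator writes; users of real detailed-cause
data supply their own code lists.  Upper-aerodigestive cancers and
lymphomas & multiple myeloma are folded into the other-malignant
residual in the default 16, a choice that is deliberately editable
since published analyses differ in which 16 causes lead.

## Change, classification, and summaries

Change over a period is `100·(q_last − q_first)` percentage points,
using endpoint years only — no trend model, no linearity assumption.
The decadal scheme compares `δ₁` (2001–10) with `δ₂` (2010–19):

| condition | category | direction |
|---|---|---|
| δ₁<0, δ₂<δ₁ | larger decline | improvement |
| δ₁>0, δ₂<0 | reversal of increase | improvement |
| δ₁>0, 0<δ₂<δ₁ | smaller increase | improvement |
| δ₁<0, δ₁<δ₂≤0 | smaller decline | deterioration |
| δ₁<0, δ₂>0 | reversal of decline | deterioration |
| δ₁>0, δ₂>δ₁ | larger increase | deterioration |
| δ₂=δ₁ | unchanged pace | neutral |

Boundary conventions: a flat first period (δ₁=0) followed by a decline
(increase) counts as a larger decline (increase); a flat second period
after a decline (increase) is a smaller decline (increase).  Equality
is assessed at a numerical tolerance of 1e-9 pp (configurable,
including exactly 0) so that ties planted by the scenario generator's
root-finding — equal to ~1e-12 pp but not bitwise — classify as ties.
These cases have measure zero in data but are documented rather than
silent.

Regional summaries use the unweighted mean of `−δ` over **all**
countries of a region (increases enter negatively), alongside counts
and shares of countries with `δ<0`; population coverage weights
declining countries by population of the analysed sex; convergence is
the within-region sample SD (n−1); the level–change association is
plain Pearson correlation.  The regional benchmark is, per sex, the
eligible country (high-quality members of the decomposition subset)
with the most negative 2010–19 change, in absolute percentage points;
regions with fewer than three eligible countries get no benchmark.
Ties break toward the higher 2010 level (the harder starting point),
then alphabetically — deterministic and documented.

The decomposition-country rule is configuration with defaults
mirroring standard practice: high-quality registration with population
above 2 million (interpreted as both-sex total for the reference
year), an explicit override list for countries whose estimates draw on
richer data than their registration tier suggests, medium-quality
countries among the five largest of their region, and each region's
largest country regardless of tier.

## Horiuchi decomposition

For a scalar functional `f` of covariates `x` (here: 100 × the
unconditional probability, as a function of the band × cause rate
vector), the difference `f(x₂) − f(x₁)` is attributed to covariates by
discretising the straight path from `x₁` to `x₂` into N equal
sub-intervals.  In sub-interval j, covariate i's effect is the change
in `f` from moving `x_i` across its sub-interval span while all other
covariates sit at the sub-interval midpoint.  Key properties, all
enforced by tests:

- a covariate with zero change contributes exactly 0, bitwise;
- if only one covariate changes, its contribution telescopes to the
  whole difference exactly, for any N;
- for `f` linear, contributions equal `w_i·Δ_i` to machine precision;
- the residual `(f(x₂) − f(x₁)) − Σ contributions` is reported, never
  redistributed, and decays empirically as N⁻².

N defaults to 100, where the residual of a typical within-period
decomposition is ~1e-7 pp — far below the 0.1 pp at which
contributions are usually read — and the cost is ~1 s per
country/sex.  N is a parameter and is recorded with every result.

The decadal-difference and benchmark-gap questions are answered as
cellwise differences of two within-period decompositions.  This
preserves exact additivity to `δ₂ − δ₁` (respectively the gap in
changes) and keeps within-period contributions reusable.  The
alternative — a single Horiuchi pass over a stacked covariate vector —
would also be additive but differs at the order of the residual;
differencing is the package's choice because the two constituent
decompositions are already the published within-period quantities.

Implementation note: the functional is evaluated in batch over all
active covariates of a chunk of sub-steps (vectorised over a 2-d array
of rate vectors), which keeps the default 17×20-covariate
decomposition at N=100 around a second on one CPU without
approximation.

## Uncertainty

The default uncertainty mechanism resamples death counts cell by cell
as Poisson(observed deaths), recomputes rates, and re-evaluates the
statistic on every replicate surface; the 95% interval is the
2.5th–97.5th percentile of the replicates under numpy's
linear-interpolation percentile rule (fixed and documented for
bit-reproducibility given a seed).  The replicate container
(`DrawSet`) also accepts externally produced rate draws, isolating the
pipeline from the draw source.  `ui_excludes_zero` marks changes
distinct from no change at the interval's level.  Intervals computed
this way are approximate parametric-bootstrap intervals: their
empirical coverage on a known-rate simulation is 92–98% at the count
sizes of the default scenarios (checked in the test suite), with the
usual deterioration when expected counts per cell are very small.

## The synthetic generator

The generator emulates the structure of cause-of-death estimate inputs
while staying fully self-contained:

- **Age gradient.** Band all-NCD hazard `α·exp(β·age_mid)` with
  β = 0.09 per year and α = 3.0e-5 (females) / 4.5e-5 (males) at age
  0, giving birth-to-80 NCD probabilities near 0.36 and 0.47 — close
  to published global levels (roughly 38% and 51%).  Country level
  effects are mean-one lognormal with CV 0.25.
- **Cause composition.** Age-varying weights per group: circulatory
  causes and dementias rising with age, cancers from mid-life,
  alcohol/cirrhosis peaking in working ages, a congenital-type infancy
  component inside the residual NCD group, and sex-specific
  breast/cervical/prostate cancers (zero weight for the other sex, so
  structural-zero cells are exercised).
- **Trends.** Per-cause log-linear annual trends with different means
  in 2001–10 (−0.020) and 2010–19 (−0.014): progress that slows
  between decades on average.  Cause-level spread (sd 0.008),
  per-cause country spread (sd 0.006), and a country-wide per-period
  effect (sd 0.008) make the decadal improvement/deterioration split
  vary realistically across countries (roughly a third improving under
  defaults) instead of being uniform.
- **Counts.** When requested, deaths are Poisson(rate × person-years)
  with person-years from a lognormal country population (median 8
  million per sex) spread over a gently tapering pyramid; rates are
  then recomputed from counts so the surface invariants hold exactly.
- **Scale.** Defaults are 24 countries (8 regions × 3) and 19 years;
  the full pipeline on this scenario runs in seconds on one CPU, and
  tests use the three analysis years where the intermediate years are
  irrelevant.

Two fixture scenarios plant recoverable truths: the improvement
scenario solves (by bracketed root finding on a uniform rate scale)
for rate paths that put each country in a prescribed decadal category
with at least 0.5 pp margin from every boundary; the benchmark
scenario gives one country per region uniformly steeper second-period
declines in every cause, with baseline levels and first-period trends
shared within the region so the planted country's reduction is
guaranteed largest and every laggard's gap margin is non-negative in
every cause.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: registration incompleteness and
cause-assignment error (garbage codes), non-log-linear trends and
shocks, correlated errors across ages or causes, migration and cohort
effects, and upstream estimation uncertainty beyond Poisson count
noise.  Recovery results on synthetic surfaces demonstrate the
correctness of the computations, not the accuracy of any source's
estimates.

## Numerical choices and degenerate inputs

- Rates must be finite and non-negative; where counts are present,
  `rate = deaths/person_years` is enforced at 1e-12 relative
  tolerance.
- Index completeness is a hard error with the offending cells listed;
  explicit zeros are required because silent imputation would mask
  data problems.
- Unmapped cause codes and negative counts fail loudly, naming the
  code or rows.
- Age windows must tile exactly onto band edges; an empty cause set is
  an error (an all-zero cause set yields probability exactly 0).
- The q-formula never reaches 1 at finite rates, so no clamping is
  applied anywhere.
- Zero-variance inputs make the level–change correlation an error, not
  a NaN.

## Known limitations

- No lifetable closure above 80 and no life-expectancy or
  cause-deleted competing-risk variants (out of scope by design).
- The decomposition treats rates per (band, cause) as the covariates;
  it does not separate incidence from case fatality.
- Poisson draws understate real uncertainty where the dominant error
  is estimation rather than sampling.
- The default cause map's identity codes are a stand-in: analysis of
  real detailed-cause data requires the user's own code lists.
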