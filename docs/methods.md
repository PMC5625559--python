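# Methods

## Model

The package computes population attributable fractions (and, more
generally, potential impact fractions) for a continuous exposure under a
log-linear dose-response. Three assumptions define the model:

1. **Log-linearity of risk.** `ln RR(x) = β·x` for daily dose `x` in
   g/day, so `RR(0) = 1` exactly and the meta-analytic RR at the reference
   dose fixes `β = ln(RR_ref)/d_ref`. No threshold, no flattening at high
   intake. Nonlinear (spline/categorical) shapes are out of scope.
2. **Multiplicative decomposition of incidence.** Each sex/age stratum's
   observed rate factorizes as `r_obs = r₀ · E[RR]` where `r₀` is the rate
   the stratum would have at zero exposure. This makes the reference
   scenario reproduce the observed incidence *exactly* by construction
   (verified to 1e−12 in the tests) and makes the single-stratum PAF equal
   the closed form `1 − 1/E[RR]`.
3. **No latency.** Exposure change takes effect immediately. For a pure
   PAF the lag between exposure and risk is irrelevant, so the default
   configuration evaluates reference and intervention on the same year's
   population and rates. `apply_latency` delays the intervention effect in
   multi-year streams for users who want it; latency 0 is the identity.

PAF is computed from summed expected case counts per sex, with
age-standardized rates reported separately. These differ slightly (the
ASR re-weights ages by the standard population), and count-based PAF is
the convention this package follows for its headline numbers.

## Exposure distributions

Surveys supply only a mean and SD of intake per stratum. The default
family is gamma, moment-matched (`k = m²/s²`, `θ = s²/m`), because
single-day 24-h-recall intake is non-negative and right-skewed with SDs
running near the means, and because the gamma admits the exact oracle
`E[exp(βX)] = (1 − βθ)^(−k)` (valid for `βθ < 1`; at the doses and RRs in
scope `βθ` ≈ 0.05–0.2). A zero-truncated normal is available for
comparison; its mean/SD parameters are those of the underlying normal.

**Discretization.** Bins `[0, s), [s, 2s), …` of width `s` (default
20 g/day, the calibration table's grid unit) out to the 0.999 quantile;
the final bin absorbs the tail and uses the conditional tail mean
`E[X | X > q]` as its representative dose, because a bin-center midpoint
would bias `E[exp(βX)]` downward where the integrand grows fastest.
Interior bins use centers. At the default 20 g/day step the discretized
`E[RR]` sits within ~0.1% of the gamma closed form for the shipped
parameters; at 0.1 g/day it converges to it (a test asserts 0.1%
agreement, and a refinement-stability test asserts Cauchy-style
convergence as the step halves).

**Age broadcasting.** Consumption strata are broad (0–14, 15–44, 45–54,
55–64) while incidence/population tables use 5-year groups to 80+. Each
5-year group is assigned the broad stratum containing its lower bound;
groups above the surveyed range inherit the oldest stratum and groups
below it the youngest. Assignment, not interpolation — matching the
granularity at which the inputs exist. This matters: incidence peaks
above the surveyed age range, so the oldest stratum's distribution
dominates the PAF.

## Demography

Rates are per 100,000 person-years in 5-year groups; expected cases are
`rate × count / 100,000`. Direct standardization uses the canonical Segi
world standard (12000, 10000, 9000, 9000, 8000, 8000, 6000, 6000, 6000,
6000, 5000, 4000, 4000, 3000, 2000, 1000, 500, 500 for 0–4 … 85+; sum
100,000). Each standard group is matched to the rate-table group
containing its lower bound, so a table topping out at 80+ absorbs the
standard's 80–84 and 85+ weights (merged top weight 1000). A standard
group not covered by the table raises a coverage error unless zero-fill
is requested.

## Sensitivity analysis

Three complete pipeline runs with the risk function calibrated to the
lower, central and upper RR bounds. Monotonicity of `E[RR]` in β
guarantees `PAF_lower ≤ PAF ≤ PAF_upper`; the lower intervention-case
count pairs with the upper PAF. Uncertainty in exposure and incidence is
not propagated (their sampling CIs are narrow relative to the RR's).

## Rounding and display

Computation keeps full precision everywhere. Printed intercepts round to
3 decimal places, half up; PAF percentages round half-up to integers
(`format_percent`), alongside a full-precision column, because published
tables mix the two conventions (e.g. a count ratio of 14.60% prints as
15 under half-up but is often quoted as 14).

## Synthetic data

The generator emulates the statistical *shape* of the real inputs, not
their values:

- **Consumption.** Per-subject gamma draws per stratum. The default
  "colombia-like" fixture uses the published sex-level means (red meat
  62.4 g/day male / 55.0 female; processed 58.3 / 50.7) with age
  multipliers 0.75 (0–14), 1.10 (15–44), 1.00 (45–54 and 55–64) shaped on
  the published age anchors (lowest in early childhood, peak in young
  adulthood), and SD = 0.95 × mean, consistent with published SDs running
  near the means. Flat intake at 45+ is a simplification; the fixture is
  illustrative of the published marginals, not a reconstruction of the
  unpublished stratified table.
- **Incidence.** `rate(g) = r₄₀ · exp(0.42·(g − g₄₀))` over 5-year group
  index `g`, anchored at 6 per 100,000 at ages 40–44, with seeded
  lognormal noise (σ = 0.05). The slope gives roughly a doubling every
  two groups and ~170 per 100,000 at 80+, typical of colorectal cancer.
- **Population.** 2.3 million per sex at ages 0–4, declining 7% per
  group — a young national pyramid at the ~45 million scale.
- **Seeding.** One `numpy` generator per fixture, seeded from the config;
  the demography stream is seeded from `(seed, 1)` so exposure and
  demography draws are independent. Seeds are recorded in output
  metadata; identical seeds give byte-identical directories.

What passing tests on this fixture do **not** show: recovery of any
published national estimate. The absolute case counts and ASRs of a real
analysis depend on the actual stratified exposure, incidence and
population inputs, which are not public; the fixture instead verifies the
*mechanics* (calibration, discretization against closed forms, exact
reference reproduction, monotonicity, conservation) and that PAFs land in
the plausible band around published central estimates (8–20%) when the
published sex-level consumption summaries and RRs are used. Real 24-h
recall data also carry within-person day-to-day variance that inflates
the SD relative to usual intake; no deattenuation is applied, matching
how such summaries are typically fed into this kind of model.

## Problem sizes

Default runs use 2 sexes × 4 exposure strata × 10,000 subjects and
2 × 17 demographic strata; the full test suite (including a 50-seed
parameter-recovery study) completes in a few seconds, and the acceptance
script in about two. These sizes were chosen as the scale at which the
survey-sampling error on a stratum mean (~0.5 g/day) matches published
CI widths.

## Known limitations

- Factors are modeled one at a time; joint red+processed PAFs would need
  a joint consumption distribution.
- No multi-year demographic projection or trend impact fractions; the
  latency hook is the only time-dynamic element.
- The engine assumes harmful exposures (`E[RR] ≥ 1`) when interpreting
  PAF; protective factors produce negative PAFs that are computed but not
  specially reported.
- Gamma moment-matching is undefined for `mean = 0` with `sd > 0`; such
  strata must be declared `point_mass`.
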