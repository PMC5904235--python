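# Methods

This note documents the statistical models and numerical choices behind
`hipfrax`, what the synthetic-registry generator does and does not
emulate, and the limitations a user should keep in mind.

## Registry filtering

Candidate case records are partitioned into included and excluded sets
under six rules. Exclusion reasons are tested in a fixed precedence
order — out_of_window, age (< 50 completed years at event), nonresident,
pathological, high_energy, duplicate — and the first matching reason is
recorded, so counts per reason are reproducible. The precedence is a
package convention: a record failing several rules is counted once,
under the highest-precedence reason.

De-duplication implements the registry convention that a repeat
admission for the same fracture site within the window is the same
fracture, while a contralateral fracture is a new event. For each
person, events that survive the other rules are sorted by (event date,
case id) and an event is marked `duplicate` if its site matches an
earlier kept event of that person. Sorting makes the rule independent of
input order; the case-id tiebreak makes same-day pairs deterministic.
Two configurable conventions, chosen because the field has no standard:

- `unspecified_site_matches_both` (default true): a `hip_unspecified`
  event matches either side during de-duplication. Conservative against
  double counting; disable to treat unspecified as a distinct site.
- `strict_mechanism` (default false): `mechanism=unknown` is treated as
  low-energy by default, on the grounds that registry cases are
  clinically validated before entry; strict mode excludes unknowns as
  high-energy.

Unknown sex values or missing dates raise a record-level error naming
the offending case ids rather than silently dropping records.

The ascertainment summary reports hospitalization percentages and the
female:male ratio on included cases, rounded half-up to one decimal
(the reporting convention of the surveys this package serves).

## Incidence estimation

Person-years use the static-population approximation: census count ×
observation duration, with no attrition from migration or mortality
during the window. For a two-year survey this overstates person-time
slightly (those who die mid-window contribute a full two years); the
bias is small relative to Poisson noise at registry scale but is a known
limitation.

Cell rates are n/PY × 10⁴. Confidence limits are exact Poisson
(Garwood) limits, `low = χ²(α/2, 2n)/2`, `high = χ²(1−α/2, 2n+2)/2`,
scaled by person-years — chosen over normal approximations because many
cells in a small registry have 0–5 cases, where exact limits remain
valid (a zero-count cell gets [0, 3.69]/PY at 95%). Exact intervals are
conservative: simulated coverage sits above the nominal level.

Direct standardization normalizes the supplied weights internally, so
any positive weight scale is accepted. The CI uses the delta-method
variance Σ w̃² n/PY² on the rate scale with a normal quantile; for the
small counts typical here this CI is approximate (the point estimate is
exact arithmetic regardless).

Burden projection is deterministic arithmetic; expectations are
reported both at one decimal and as rounded integers.

Band ladders must match exactly between tables (rates vs weights,
rates vs target pyramid); mismatches raise errors naming the bands
rather than intersecting silently. The terminal 85+ band is open-ended
and must be present in target tables.

## Ten-year fracture probability

The engine computes the cause-specific cumulative incidence of a first
fracture over a 10-year horizon under competing mortality, using
one-year piecewise-constant hazards:

    λ_i = rr · h_frac(a+i),  μ_i = h_death(a+i),  τ_i = λ_i + μ_i
    q_i = (λ_i/τ_i)(1 − e^(−τ_i)),  S_0 = 1,  S_{i+1} = S_i e^(−τ_i)
    p10 = Σ_{i=0}^{9} S_i q_i

This is the standard multi-decrement life-table sum; within each year
the two risks are constant and independent, so the within-year split
λ/τ is exact. The sum is deterministic and satisfies, by construction:
p10 ∈ [0,1]; p10 = 0 iff the fracture hazard vanishes on the horizon;
monotone non-decreasing in rr and non-increasing under pointwise
increases of mortality; and sub-multiplicative, p10(rr=k) ≤ k·p10(rr=1).
Constant-hazard inputs reduce to the closed form
(λ/τ)(1 − e^(−10τ)), which the test suite checks to ≤ 1e−12 relative
error, and zero mortality reduces to 1 − e^(−10λ).

**Hazard construction.** Band-level tables (per 10,000 person-years —
one unit convention for incidence and mortality alike) are expanded to
single-year-of-age hazards either by step assignment (each band's value
on every age it contains) or, by default, linear interpolation between
band midpoints (52.5, 57.5, …; the open 85+ band uses 87.5) with
constant extension below the first and above the last midpoint.
Midpoint interpolation is the default because risk-calculator practice
smooths band rates; step mode is retained for transparency. Ages beyond
the ladder hold the terminal hazard constant to `a_max` (default 100) —
deliberately conservative; no Gompertz extrapolation is attempted
beyond the data.

**Incidence as hazard.** The observed incidence rate is used directly
as the hazard of first fracture, with no adjustment for the
first-versus-subsequent fracture distinction made by full FRAX
methodology. This overstates first-fracture hazard slightly where
repeat fractures contribute to incidence.

**MOF imputation.** Major-osteoporotic-fracture incidence is hip
incidence × an age/sex-specific MOF:hip ratio (≥ 1, since MOF includes
hip), the standard device where only hip rates are observed. Imputed
tables carry no counts or CIs — sampling uncertainty does not propagate
through the ratio, and the output is flagged `imputed`. MOF
probabilities run through the same engine with the same death hazard.

**Risk-factor scenarios.** Clinical risk factors are named
multiplicative relative risks on the fracture hazard. The default
bundle defines `prior_fracture: 2.0`, a demonstration value reflecting
the roughly-doubled probabilities reported for that factor, not a
calibrated coefficient; full CRF regression models with BMD
interactions are out of scope.

**Independent oracle.** `mc_probability_oracle` simulates individuals
year by year with competing exponential draws and is kept free of the
life-table code; engine-versus-oracle agreement within 3 binomial SE at
n = 200,000 on randomized hazard curves is part of the acceptance
suite. Its SE is the binomial √(p(1−p)/n), slightly optimistic at
estimates near 0.

## Synthetic registry generator

The generator emulates a single-city, two-year prospective hip-fracture
survey of an Eastern-European catchment:

- **Population**: fixed pyramid of 21,069 women and 14,380 men in
  5-year bands from 50 to 85+, with a plausible old-age taper.
- **Incidence**: per-sex Gompertz hazards h(a) = h0·e^(γ(a−50)),
  evaluated at band midpoints. Defaults: women h0 = 1.2374e−4,
  γ = 0.125; men h0 = 2.6778e−4, γ = 0.098. The slopes correspond to an
  incidence doubling time of ~5.5–7 years of age, the canonical shape
  for hip fracture; the intercepts are solved so the expected
  qualifying counts over two years are 76 women and 41 men (≈117
  total). Male rates exceed female below age 70 and female rates exceed
  male in the 80+ bands, with an old-age female excess of ~27% — the
  qualitative crossover the surveys report, though a steeper female
  excess (60%+) cannot be combined with these totals and a rising
  probability curve under Belarus-like mortality (the slopes it forces
  are too shallow against mortality growth).
- **Counts**: qualifying cases per (band, sex) are Poisson with mean
  pop × years × h(midpoint); ages uniform within band (85+ spans
  85–94), dates uniform in the window, sides equiprobable.
- **Ascertainment**: hospitalization is Bernoulli with logit
  1.65 − 0.09·(age − 70) − 0.4·1[female] (≈71% hospitalized overall),
  so non-hospitalized cases are older and more often female.
  Non-hospitalized cases are sourced `primary_care`, mirroring surveys
  that canvass general practices precisely because such cases never
  reach hospital registers.
- **Contaminants**: per type (high-energy, pathological, non-resident,
  under-50, duplicate), counts are Poisson with mean p × n_qualifying;
  each contaminant violates exactly one rule and is labeled in the
  truth object. Duplicates clone a qualifying case with a later date
  and the same site. A single RNG stream draws qualifying cases first,
  so changing contamination probabilities never perturbs the qualifying
  sample at a fixed seed.

What the generator does **not** emulate: migration and mid-window
mortality (person-years are exact in the simulation by construction),
seasonality, within-band age gradients (ages are uniform in band while
the hazard is evaluated at the midpoint), record-linkage noise in
identifiers, and under-ascertainment — every qualifying fracture is
observed, so passing recovery tests demonstrates estimator correctness,
not robustness to incomplete capture in real registries.

Truth tables store the band-midpoint rates and expected counts;
recovery is assessed by z = (est − true)/SE with SE = √(true·10⁴/PY)
on the per-10,000 scale, and summarized as the share of cells with
expected count ≥ 5 inside 3 SE (below that threshold the normal z
approximation to Poisson error is too coarse to be informative).

## Problem sizes and determinism

The test and acceptance workloads are sized for a laptop-class single
core: 200 simulated registries (~150 records each) for recovery, 20
random hazard curves at n = 200,000 for the Monte-Carlo cross-check,
2,000 replicates for CI coverage. All simulation flows through
`numpy.random.default_rng` seeds carried in parameter objects;
`scripts/acceptance.py` derives all stream seeds from its `--seed` via
`SeedSequence`.

## Known limitations

- Standardized-rate CIs are delta-method approximations; exact
  standardized-rate intervals (e.g. gamma-based) are not implemented.
- The probability engine treats within-year hazards as constant;
  finer-than-annual discretization is not supported.
- MOF imputation inherits the hip rates' age pattern; countries where
  forearm fractures deviate from the hip-implied pattern will be
  misrepresented by any ratio table.
- Bundled `*_synthetic.csv` tables are constructed stand-ins with
  realistic orders of magnitude, not sourced statistics; conclusions
  about any real country require real input tables.
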