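# Methods

This note documents the models, conventions and numerical choices behind
`climvuln`, in the order the pipeline applies them.

## 1. Extreme-climate indices

Seven indicators summarize a multi-year daily series (tmax, tmin,
precipitation) into one scalar per region.  Where a multi-year summary
convention had to be fixed, we follow common ETCCDI practice:

| index | definition | multi-year aggregation |
|-------|------------|------------------------|
| TXx, TNx (°C) | block maximum of daily tmax / tmin | mean of annual maxima |
| TX90p, TN90p (% days) | share of days strictly above the calendar-day 90th percentile | percentage over all days of the record |
| DTR (°C) | mean diurnal range tmax − tmin | mean of monthly means |
| CDD (days) | longest run of days with precip < 1 mm | mean of annual maxima |
| R99p (mm) | precipitation total on days strictly above the wet-day 99th percentile | mean of annual totals |

Conventions, all exposed through `ClimateConfig`:

- **Percentile thresholds** for TX90p/TN90p are computed per calendar
  day from a centered 5-day window pooled across all years of the base
  period, with linear-interpolation empirical quantiles.  The base
  period defaults to the full record (base ≈ analysis period), so no
  in-base bootstrap correction is applied.  Calendar days are aligned
  on a fixed leap-year calendar so 29 February pools with its
  neighbours.
- **Strict exceedance** (`>`) defines warm days/nights and extremely
  wet days.
- **Wet day** means precip ≥ 1 mm (the Climdex convention); the R99p
  threshold is estimated from wet days only, and a region with no wet
  day in the base period is a hard error.
- **Missing data**: values are NaN, never silently zero.  A month/year
  with more than 20% of the relevant variable missing is excluded from
  aggregation (configurable); a block with everything missing is
  skipped with a warning.  Missing days terminate a dry run, since a
  dry spell cannot be asserted across an unobserved day.
- **Quintile coding**: each index is cut into five cross-region
  categories at the 20/40/60/80th percentiles (category = 1 + number of
  bounds strictly exceeded).  If ties empty a category, assignment
  falls back to rank order with a stable region-id tie-break and a
  warning; an all-constant index puts every region in category 1.  The
  coding is invariant under strictly monotone transforms of an index.

## 2. Grade of Membership model

Regions × indices × quintile categories enter a mixed-membership model:
membership vectors g_i ~ Dirichlet(α), per-profile multinomials λ_kj·,
and cell probability Σ_k g_ik λ_kjl.  We use the (ξ, α₀)
reparameterization (ξ_k = α_k/α₀ expected profile proportions, α₀ the
membership spread; smaller α₀ ⇒ memberships nearer the simplex
vertices).

Estimation is a conjugate Gibbs sampler over per-(region, item) latent
profile indicators, with defaults of 5,000 retained draws after a 2,500
burn-in.  Priors: λ_kj ~ Dirichlet(1,…,1) and independent Gamma(1,
rate = 0.1) priors on each α_k — which factorize exactly into
ξ ~ Dirichlet(1,…,1) and a diffuse Gamma(K, 0.1) prior on α₀ — updated
by a log-random-walk Metropolis step (scale 0.3, acceptance typically
0.2–0.5).  These are standard weakly informative choices for this
parameterization; all are exposed in `GoMConfig`.

Numerical and reporting choices:

- **Label switching** is undone post hoc: each draw's profile labels
  are permuted to minimize the squared distance of λ to a reference
  draw (the draw closest to the element-wise median of the chain).
  The result is deterministic given the draws and unique up to one
  global label order.
- **Memberships** are reported as posterior means; classification uses
  point memberships with inclusive cutoffs 0.90 / 0.75 / 0.50 and exact
  ties going to the lower profile index with a warning.
- **Convergence** is summarized by a split-chain potential scale
  reduction factor on the log-likelihood trace; values above 1.1 warn
  but never trigger silent re-runs.
- **Degenerate items** (a single observed category) are a hard error;
  missing cells are disallowed — the upstream coding always emits
  complete matrices.
- One master seed drives the chain; identical config and seed give
  bit-identical draws.
- Profile *naming* (ER vs ED-HT) keys on the fitted dry-spell response:
  the profile with mass in higher CDD categories is the drought/heat
  zone (fallback: reversed R99p).
- K is user-chosen (default 2); no automated model-order selection is
  attempted, as no formal criterion is defined for it.

## 3. Alkire-Foster vulnerability index

Eighteen indicators span three equally weighted dimensions — exposure
(the 7 climate indices, w = 1/21 each), susceptibility (5
sociodemographic indicators, w = 1/15) and adaptive capacity (6
infrastructure/health-supply indicators, w = 1/18).  Deprivation rules:

- "4th quartile" indicators: deprived iff value ≥ the cross-region Q3
  (inclusive, so boundary regions are deprived deterministically);
- "1st quartile" indicators: deprived iff value ≤ Q1 (inclusive);
- the absolute income rule: deprived iff income < R$296.8 (strict; the
  alternative preset R$255.00 — half the 2010 minimum wage — is
  accepted via `default_schema(income_threshold=...)`).

Quartile bounds are always computed on the pooled study area and reused
in subgroup analyses; this is what makes the subgroup decomposition
identity exact.  The weighted formulation (c_i = Σ w_j flag_ij,
vulnerable iff c_i ≥ k_p) is used throughout; at equal weights it
reduces to the counting definition ("deprived in at least k of I
indicators"), which the test suite exploits as an independent oracle.
All headline statistics are population-weighted; an unweighted
(region-counting) mode exists for the verbal definitions.

Standard errors (the index's sampling design is not specified anywhere,
so this is a package design choice): a nonparametric bootstrap over
regions (default B = 1000, seeded) or a Taylor linearization treating
CH and ECVI as population-weighted means and DI as their ratio (delta
method).  Groups with a single region get NaN SEs with a warning.

## 4. Choosing the multidimensional cutoff k_p

`climvuln.kp` evaluates ECVI/CH/DI on a grid (default 0.05–1.00 in
steps of 0.05) and selects the grid point whose next t curve values
(default t = 3) have minimal variance — the flattest forward window.
Window variance is the population variance (divide by t), which is
scale-consistent across window lengths and invariant to adding a
constant to the curve.  Ties, including floating-point near-ties below
1e-12, break to the smallest cutoff.  When groups are compared, window
variances are averaged across group curves on a shared grid.

The criterion is advisory: a flat tail of near-zero index values can
attract it to a cutoff that censors almost everyone, so the report
always includes the vulnerable share at the suggested optimum (flagged
when below 5%) alongside a second advisory — the grid point where
|CH − DI| is smallest — and the user-chosen cutoff (default 0.25).
Neither the grid nor t has a canonical value; both are config-exposed
and recorded in every report.

## 5. Synthetic studies

The generator emulates the *structure* of the real inputs, not their
physics:

- memberships g_i ~ Dirichlet(α₀·ξ) with defaults α₀ = 0.5,
  ξ = (0.5, 0.5) — well-separated regimes with both zones expected;
- daily precipitation from a two-state wet/dry Markov chain whose
  parameters are membership-weighted mixtures of two regimes: the
  rain-extreme regime (wet-day persistence 0.70, dry→wet 0.45, gamma
  amounts with scale 10 mm, heavy-event probability 0.012 adding an
  exponential 60 mm tail) and the drought/heat regime (dry→wet 0.06,
  giving long dry runs; scale 6 mm; heavy probability 0.001);
- temperatures as a seasonal sinusoid (amplitude 3 °C) plus a regime
  mean shift (tmax 31 vs 36.5 °C; diurnal range 8 vs 12 °C) and
  Gaussian noise (sd 1.5 °C);
- social indicators as baseline + effect × 1[dominant profile is
  drought/heat] + noise, with effects signed so that zone is worse off
  (poorer, less literate, worse sanitation) except primary-care
  coverage, which is scarcer in the rain zone; populations log-normal
  (median ≈ 490k, sd of log 0.7);
- annual disease counts Poisson(pop × rate/1e5) over 5 years with
  log rate = log(300) + 2.5 · c_i in the weighted deprivation score.

Defaults are study-scale (62 regions, 34 years of daily data); the
`fast` profile (30 regions, 3 years) is the package's deliberate
test-scale choice.  The generator omits spatial autocorrelation,
realistic weather physics, gridded output and measurement error, so
passing tests demonstrate the *statistical machinery* (index coding,
membership recovery, decomposition identities, stratification), not
fidelity to any real climate or census data.

## 6. Test design and problem sizes

- Exhaustive oracle checks enumerate every 0/1 deprivation pattern on
  micro-panels (4 regions × 4 indicators, and 2 × 5, for the core
  statistics; 3 × 3 and 2 × 4 for both decompositions), comparing the
  weighted implementation at equal weights against the counting
  definition computed in pure Python.  Cutoffs are placed at
  (k − ½)/I so float summation can never flip a boundary comparison.
- Decomposition identities are additionally checked to 1e-12 on 200
  random panels under the full 18-indicator schema.
- Membership recovery uses the well-separated design (60 regions,
  profiles concentrated on opposite extreme categories, α₀ = 0.5) over
  5 seeds at the full 5,000/2,500 chain length, requiring ≥ 90%
  dominant-profile agreement among regions with true dominant
  membership ≥ 0.75; unit tests use shorter chains (≈ 800/400) for the
  same design.
- Climate-index implementations are compared exactly against explicit
  brute-force scans (per-calendar-day sorting, run-length scans) on
  series up to three years.

## 7. Known limitations

- The GoM sampler runs a single chain; the split-chain PSRF on the
  log-likelihood is a coarse convergence diagnostic and multimodality
  across label-invariant modes is handled only by post-hoc relabeling.
- The forward-local-variance criterion depends on grid resolution and
  window length; it is reported, never silently applied.
- The per-calendar-day percentile thresholds use no in-base/out-of-base
  bootstrap adjustment, which matters only when the base period is a
  strict subset of the analysis period.
- Bootstrap SEs resample regions as if independent; spatial dependence
  between neighbouring regions is ignored.
- The NetCDF grid-to-region reader is out of scope; inputs are
  long-format CSV.
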