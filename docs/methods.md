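# Methods

## Scope and assumptions

The package projects cardiovascular-disease DALYs for adults aged 30+
under one deliberately narrow counterfactual: age- and sex-specific DALY
rates stay at their base-year (2005) level, and every projected change in
burden is demographic. No trend in risk factors, treatment, or case
fatality enters the model; the projection answers "what does population
growth and aging alone do to the burden", not "what will the burden be".
Burden is the composite DALY; no years-lived-with-disability /
years-of-life-lost split is modelled.

"Direct age standardization" is operationalized as exactly this
constant-rate computation: base-year age-specific rates applied to
projected population structures, summed crudely. No external standard
population enters the default pipeline, because the reference projection's
totals are crude column sums; `age_standardized_rate` provides
standardization against an explicit standard pyramid for comparisons, but
nothing in the default pipeline calls it.

## Rate model

Coarse adult age groups (30–44, 45–59, 60–69, 70–79, 80+) each carry one
DALY rate. `fit_rate_line` regresses rate on the coarse-group midpoint by
OLS (delegated to statsmodels; tests check it against a direct
normal-equations solve to 1e-9). Midpoints: arithmetic for closed groups
(30–44 → 37, 45–59 → 52, 60–69 → 64.5, 70–79 → 74.5); the open 80+ group is
closed 5 years above its lower bound (→ 85), a conventional choice
configurable via `group_midpoint(..., open_offset=)`.

Decisions that shape the numbers:

- **Rate denominator.** The reference equations state no scale. Raw DALY
  counts are inconsistent with the magnitude of the reference projection
  table, whereas reading the equations as *rate per 100,000 at the group
  midpoint* and multiplying by group population reproduces its order of
  magnitude (511.47/100k × ~6M persons ≈ 30.7k DALYs for 30–34 in 2005,
  against the table's 30,850.99). The package adopts the per-100,000
  interpretation, records it in every run manifest, and exposes the
  denominator in `RunConfig.rate_denominator`.
- **Age coding.** "Age" in the lines is the interval midpoint in years,
  not a group index: a slope of ~174 per year over a 65-year span is only
  consistent with midpoint coding.
- **Clamping.** Negative predictions clamp to zero. All three reference
  lines cross zero below age 30 (e.g. 5047.25/173.71 ≈ 29.06), so clamping
  never activates on the adult grid.
- **Terminal group.** 100+ is assigned zero burden, matching the zero row
  of the reference projection; the linear extrapolation is not trusted 15+
  years past the oldest coarse midpoint.
- **No renormalization.** Fine rates are the line evaluated at midpoints,
  with no rescaling to preserve coarse-group totals; whether the original
  analysis renormalized is unknowable from what it reports, and direct
  application is the simpler reconstruction.

## Cohort-component projection

Discrete 5-year steps on 5-year age groups (0–4 … 95–99, 100+), by sex.
Survivorship ratios move each cohort up one group; the 100+ group keeps
its own survivors plus entrants from 95–99. Births over a period are
5 × Σ ASFR(a) × W(a), with W the start-of-period female counts — the
simplest consistent exposure choice; `exposure="mid"` switches to the
average of start- and end-of-period counts (differences are absorbed by
the synthetic calibration either way). Births split 1.05 male : 1 female
and survive into 0–4 with sex-specific birth survival. Migration is zero
throughout: the model's reference scenario never mentions it, and adding
it would only obscure the aging signal.

The five TFR trajectories (medium 1.96→1.36, high →1.86, low →0.86,
constant 1.77, instant replacement 2.1 flat, over periods 2000–2005 …
2020–2025) are immutable fixtures; any other path is supplied as a
`ScenarioTFRPath`. A pyramid labelled year Y is mid-year Y; the step from
Y uses period "Y–Y+5". Annual values, where needed, come from cell-wise
linear interpolation between quinquennial pyramids.

## Synthetic inputs: what they emulate and what they do not

- **Pyramid** (`make_base_population`): a discretized Gaussian bump over
  age (scale `spread`) on a flat floor (1e-4 of the peak), normalized to
  the target total exactly. Group weights use the distance from the bulge
  age to the *interval* (zero inside it), which makes the containing group
  strictly modal for every parameterization. The 30+ male−female gap is
  imposed exactly by a compensating transfer between the sexes' adult
  cells. The seed perturbs only the within-group sex split (sd 0.5%).
  Defaults emulate Iran 2005: 70,122,200 people, bulge at 22 (modal group
  20–24), spread 18, male surplus 889,000. With these defaults the 30+
  share is 39.5%, within 2 points of the observed 38.01%. The shape is
  smoother than a real pyramid — no birth-cohort notches, no war or
  famine scars — so tests passing on it show the arithmetic is right, not
  that any real population is well described by a Gaussian.
- **Survivorship** (`make_mortality_schedule`): Gompertz force of
  mortality (exponential in age), female slope slightly below male, both
  sexes anchored so 30–34 survivorship = `adult_level` × 0.995. The curve
  is deterministic; the seed argument exists only for interface symmetry.
  Child and young-adult mortality are near-flat, which understates real
  infant mortality; this biases the 65+ share of the synthetic projection
  low but leaves every monotonicity and conservation property intact.
- **Fertility** (`make_fertility_schedule`): a fixed hump-shaped relative
  pattern over 15–49 (peak 25–29) scaled so 5 × Σ ASFR equals the TFR
  target exactly.
- **Coarse DALY table** (`make_coarse_daly_table`): line value at the
  coarse midpoint plus additive Gaussian noise on the rate scale,
  truncated at 0 — the same error model OLS assumes, so refits are
  unbiased (checked over 500 replicates).

## Uncertainty propagation

Undercounting is one-sided by construction: if a fraction u of CVD deaths
is missing from registration, recorded burden is (1−u) of the truth and
the correction divides by (1−u); an undercount can never lower the true
burden. Population error e is symmetric. Deterministic bounds for a cell
(e, u) are [P(1−e), P(1+e)/(1−u)].

Monte Carlo intervals sample e ~ Uniform(−e, e) and u ~ Uniform(0, u) —
maximum entropy given only the stated ranges, declared in the interval
metadata — and report percentile (not normal-approximation) intervals.
Default 100,000 draws, default seed 20050101, both configurable. Because
the sampling distribution's support is the bounds interval, Monte Carlo
intervals always nest inside the deterministic bounds; the published
min/max values for these scenarios were produced by unstated machinery and
are not exactly recoverable from any simple closed form tested against the
reference total, so the package defines its own distributions and
documents the divergence rather than reverse-engineering printed bounds.
Population error is applied as a single multiplicative factor on totals
(the per-age-group alternative changes nothing under a common factor).

## Numerical and interface choices

- Exact arithmetic wherever possible: pyramid totals, the 30+ sex gap and
  implied TFRs are imposed to machine precision, not approximately.
- The wide burden CSV rounds to 2 decimals; stored published totals are
  preserved on read and must agree with recomputed column sums within
  0.05 (rounding slack of a two-decimal table). Long-format CSVs write
  full `repr` precision and readers parse with round-trip float precision,
  so run artifacts round-trip bitwise.
- The run manifest records package version, a configuration hash
  (excluding the output directory), all seeds and the rate-denominator
  interpretation; equal hashes imply byte-identical artifacts.
- Degenerate inputs raise: non-positive totals/spreads/TFRs, undercount ≥
  1, fewer than two distinct midpoints in a fit, zero-total pyramids in
  share computations.

## Problem sizes

The default pipeline projects 21 age groups × 2 sexes over 4 steps and is
effectively instantaneous; Monte Carlo uses 100,000 draws per cell. Tests
use 500 refit replicates for OLS unbiasedness and 10,000 replications for
the 95% ± 1.5% coverage check — sizes at which the binomial noise on the
checked proportions is comfortably inside the asserted bands.

## Known limitations

- Constant rates are the point of the design, but they are also its main
  limitation: real CVD rates trend with risk factors and treatment.
- The linear rate-age model is an interpolation device, not biology;
  rates need not be linear in age, especially past 80.
- The synthetic demography is calibrated to one summary (the 30+ share),
  not to a full observed pyramid; projected totals and the 65+ share are
  qualitative, and external population figures are reference points, not
  targets.
- The sensitivity model treats e and u as the only error sources and as
  independent uniforms; registration error in the base-year rates
  themselves (beyond undercounting) is not modelled.
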