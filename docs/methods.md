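# Methods

## The experimental design this package models

One female per vial, housed with either one male (monogamy) or three males
(polyandry) at one of three constant temperatures (20, 24, 28 °C). Females
are flipped to fresh vials twice a week (alternating 3- and 4-day
intervals, so the collection calendar is `[0,3), [3,7), [7,10), …, [38,42)`),
and the adult offspring emerging from each vial are counted — an
interval-censored fecundity schedule. Offspring collection stops at day 42;
survival is then followed until every female dies. Females lost to handling
are right-censored at the last day they were seen alive. Day 0 is the first
day of cohabitation; all ages are integer day offsets from it.

Censored females contribute to survivorship until their censor day but are
excluded from per-female summaries (LRS, components, H): a censored female
has no complete lifetime observation, and treating her truncated count as a
lifetime total would bias fitness downward. This mirrors the convention of
reporting final sample sizes net of lost females while censoring them in
survival analysis.

A recording ambiguity is resolved explicitly: offspring counted in the vial
spanning a female's death day are attributed to that interval as recorded
(they were laid before death); and a missing count for an interval in which
a female was alive is a validation error, never imputed as zero.

## Statistics

**Relative harm.** `H = (W_mono − W_poly)/W_mono`, with `W` the arm mean of
LRS over uncensored females. Uncertainty: percentile bootstrap, resampling
females with replacement independently within each arm (default 2000
draws, seeded). H is scale-invariant and at most 1; it is undefined when
`W_mono = 0`.

**Fitness-component partition.** Early reproduction sums counts in
intervals lying in days 0–14, late reproduction days 14–28; the
reproductive-aging score is `late − early` (negative = senescence). An
interval straddling a week boundary is attributed to the side containing
its midpoint — with twice-weekly flips the straddle is at most two days and
the midpoint rule is unbiased on average; on the default calendar the
boundaries at days 14 and 28 align exactly. Weeks 5–6 are not used as the
late window because mortality is already heavy there, making the per-female
late rate noisy. Actuarial aging is operationalized as lifespan
(`death_day`).

**Rate-sensitive fitness.** Reproduction is discounted by timing:
`ω_ind(r) = Σ_j e^(−r x_j) c_j` with interval counts `c_j` at midpoint ages
`x_j`, and `ω_pop(r) = Σ_j e^(−r x_j) l_j m_j` where `l_j` is the
product-limit (Kaplan–Meier, daily resolution, censoring handled with the
standard death-before-censor tie convention) probability of still being at
risk at the interval's start, and `m_j` is the interval's total offspring
among at-risk females divided by the at-risk count. These conventions make
three identities exact rather than approximate, and the tests assert them
at machine precision:

- `ω_ind(0) = LRS` for every female;
- `ω_pop(0) = mean LRS` of the group when no female is censored
  (`l_j m_j` telescopes to total offspring over initial n);
- `1 − C_r(0) = H` under the same condition, where
  `C_r = ω_pop(poly)/ω_pop(mono)`.

`r` is unitless in the source convention; we interpret it per day on the
interval-midpoint age axis (*Drosophila* demography is conventionally
daily). A `time_scale` argument rescales ages for other unit conventions;
ω is invariant under `t → t/k, r → r·k`. The default grid is
`{−0.1, −0.05, 0, 0.05, 0.1}` per day. Using interval midpoints rather than
exact lay days introduces a discretization error bounded by a factor
`e^(|r|·w/2) − 1` (w = interval width, ≤ 4 days), i.e. ≤ ~22 % at the
extreme `|r| = 0.1` and far smaller on the rest of the grid; the
event-space oracle test checks this bound.

**Behavioural indices.** Courtship intensity = courtship count /
(females × hours); rejection and aggression = count / hours; rejections per
courtship = rejection / courtship, absent (not zero) when courtship is zero
since the quantity conditions on courtship occurring. Rates divide by total
observation time (8 h), not effective scanned time — the scan design (one
complete sweep every 10 min, 49 per vial) is built to approximate
all-occurrence recording over the window. Aggression requires >1 male and
is absent under monogamy. Matings are carried as a count but never
modelled: first-day mating frequency is not a reliable mating-rate measure.

**Model scaffold.** Responses are Box–Cox transformed (profile
log-likelihood over λ ∈ [−2, 2] step 0.05; responses with zeros are shifted
by `1 − min(y)` first, the shift recorded), then fitted by Gaussian OLS with
temperature as a centred continuous covariate, mating system, and their
interaction. Each term's type-III F is a full-versus-reduced change-in-SSE
comparison; when the interaction is the target, the model is refitted
without the main mating-system effect (the collinearity refit). Follow-up
models estimate the polyandry−monogamy difference per temperature stratum.
Benjamini–Hochberg step-up adjustment is applied across the family of
responses tested in one experiment. Temperature can alternatively be coded
as a factor with orthogonal linear+quadratic contrasts (2-df tests).
Survival (Cox), Gamma/binomial and zero-inflated fits are deliberately out
of scope: the exported component tables are analysis-ready inputs for
standard survival/GLM software.

## The synthetic cohort generator

Each female's death time is Gompertz, hazard `a·e^{b t}`, drawn by inverse
transform and recorded as the integer day `⌈t⌉`. Her expected daily
offspring is `v·f0·e^{−δ t}` (exponential reproductive senescence, thinned
by egg-to-adult viability `v`), and each interval's count is Poisson with
mean summed over the days she is alive within the reproductive window.
Under polyandry, harm enters as per-temperature multipliers (≥ 1) on the
baseline hazard (`harm_hazard_mult`) and on the senescence rate
(`harm_fecundity_mult`); monogamy parameters are temperature-independent,
so monogamous fitness is flat across temperatures by construction. Harm
multipliers are constant in time; cumulative damage emerges from
compounding, not from time-varying parameters. Random right-censoring
(default 4 % per female, roughly the loss rate in assays of this design)
draws a uniform censor day before death. All draws flow from one
`numpy` generator seeded by the config.

Defaults (`f0 = 6` adults·day⁻¹, `δ = 0.05` day⁻¹, `v = 0.8`,
`a = 9.79e−5` day⁻¹, `b = 0.12` day⁻¹) give a monogamous mean lifespan of
~55 days and mean LRS of ~85 adult offspring — realistic for individually
housed wild-derived *D. melanogaster* females at benign temperatures — with
mortality concentrated late enough that a 42-day reproductive window
captures most reproduction.

**Calibration.** `paper_like_config()` solves, per temperature, for the
hazard multiplier reproducing the target lifespan decrease (35/31/22 % at
20/24/28 °C) and then for the fecundity multiplier reproducing the target
relative harm (0.22/0.36/0.10), using the model's closed-form large-sample
expectations `E[LRS] = v f0 Σ_d e^{−δ' d} S(d)` and `E[lifespan] = Σ_d S(d)`
(the infinite-n limit of a Monte-Carlo calibration, with no sampling
noise). Each solve is a bracketed 1-D root find; lifespan depends only on
the hazard multiplier, so the sequential solve is exact. The resulting
multipliers are hazard ≈ 10.5/8.0/4.3 and senescence ≈ 1.29/1.71/1.12 at
20/24/28 °C — i.e. cold-temperature harm loads on survival, mid-temperature
harm on both channels, matching the qualitative finding structure.

**What the generator does and does not emulate.** It reproduces the design
(cell sizes, calendar, censoring), the mean structure (flat monogamy,
temperature-dependent harm, its split between actuarial and reproductive
channels) and Poisson count noise. It does not model vial-level shared
environments, male replacement at week 3, individual frailty
(overdispersion beyond Poisson), density effects, or behavioural coupling
between harassment and fecundity. Passing tests therefore demonstrate that
the estimators recover known effects under the stated stochastic model —
not that real data meet those assumptions (real LRS is typically
overdispersed, so real-data CIs will be wider than the generator's).

The behaviour generator draws per-vial Poisson counts at configurable
hourly rates per treatment cell — sufficient for testing rate recovery and
summaries, with no within-observation temporal structure.

## Numerical and design choices

- Problem sizes: the test suite's simulation studies use 50 cohorts of 12
  females per cell for the exact identities, 200 seeds at the study's cell
  size (78) for parameter recovery and CI coverage (bootstrap 400 draws in
  the coverage study; the analysis default stays 2000), 500 null datasets
  of 40 per cell for type-I-error calibration, and 100 random instances per
  oracle-equivalence check. The acceptance script uses 2000 females per
  cell, where Monte-Carlo error on H is ≈ 0.005.
- Gompertz inverse-CDF sampling uses `log1p`/`expm1` forms for numerical
  stability at small `a`.
- Bootstrap CIs are percentile; bootstrap replicates with a zero resampled
  monogamy mean (possible only in degenerate tiny groups) are dropped from
  the percentile computation.
- Per-temperature bootstrap seeds are spawned from one master seed via
  `numpy.random.SeedSequence`, so per-cell results are reproducible under
  partial re-runs; the CLI `run` command derives stage seeds the same way.
- The week-boundary attribution rule, the censored-exclusion rule and the
  at-risk life-table convention are each chosen to make a downstream
  identity exact (see above) rather than approximately true.
- Ties in BH adjustment use a stable sort; adjusted p-values are capped at
  1 and mapped back to input order.
- The reproductive-aging response is the difference `late − early` rather
  than a ratio or late-only measure: a decline measure whose negative sign
  directly encodes senescence and which is well-defined for females with
  zero late (or zero early) reproduction, where a ratio would be undefined
  or degenerate.

## Known limitations

- H's bootstrap is design-based (females resampled within arms); it does
  not propagate vial-level dependence, which the monogamy/polyandry design
  largely removes but a shared-incubator effect could reintroduce.
- `ω_pop` treats `m_j` as a cohort-level per-capita rate; partial-interval
  exposure of females dying mid-interval is not prorated (their laid eggs
  and their full interval presence cancel to first order, and the r = 0
  identity is exact regardless).
- The Gaussian-after-Box–Cox scaffold is an approximation for count
  responses; its type-I error is verified ≈ 0.05 under the generator at
  n = 40 per cell but is not exact for heavily skewed small samples.
- The generator's Poisson counts understate real overdispersion; effect
  sizes are calibrated on means, not variances.
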