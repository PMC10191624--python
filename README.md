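# conflictdemog

Demographic analysis of **sexual conflict**: how much does male harm cost
females — and populations — and how does that cost depend on the thermal
environment and on population demography?

In many species, male adaptations to intra-sexual competition (harassment,
toxic ejaculates) reduce female fitness. The standard assay in *Drosophila*
contrasts females kept under **monogamy** (1 male : 1 female, low
competition) with **polyandry** (3 males : 1 female, high competition),
following each female's twice-weekly offspring production over a six-week
reproductive window and her survival until death. This package turns such
longitudinal records into the quantities that matter for demography:

- **Relative harm** `H = (W_mono − W_poly) / W_mono`, the proportional drop
  in mean female lifetime reproductive success (LRS) attributable to male
  harm, with a stratified percentile-bootstrap CI.
- **Fitness-component partition**: early reproductive rate (offspring in
  weeks 1–2), reproductive aging (offspring in weeks 3–4 minus weeks 1–2),
  actuarial aging (lifespan).
- **Rate-sensitive fitness**: `ω_ind(r) = Σ_j e^(−r·x_j) c_j` per female and
  `ω_pop(r) = Σ_j e^(−r·x_j) l_j m_j` per cohort (product-limit survivorship
  `l`, per-capita fecundity `m`, interval-midpoint ages `x`), across a grid
  of intrinsic growth rates `r`. The **relative population cost** of
  polyandry is `C_r = ω_pop(poly)/ω_pop(mono)`, reported as `1 − C_r`.
  At `r = 0` these collapse exactly to LRS, mean LRS and `H`.
- **Behavioural rates** from scan sampling: courtships per female per hour,
  rejections per hour, male–male aggressions per hour, rejections per
  courtship.
- A statistical scaffold (Box–Cox transform, Gaussian linear models with a
  temperature × mating-system interaction and type-III F tests,
  per-temperature follow-ups, Benjamini–Hochberg correction) for the
  headline comparisons.

A calibrated **synthetic cohort generator** (Gompertz mortality, exponential
fecundity senescence, per-temperature harm multipliers) reproduces the
design and effect-size structure of the reference experiment — harm peaking
at intermediate temperature (H ≈ 0.36 at 24 °C vs 0.22 at 20 °C and 0.10 at
28 °C) and lifespan costs largest in the cold (≈ 35/31/22 % at 20/24/28 °C)
— so every stage is testable without external data.

## Worked example

```python
from conflictdemog import MaleHarm, paper_like_config, simulate_cohort

cohort = simulate_cohort(paper_like_config(seed=1))   # 78 females per cell
res = MaleHarm(cohort).fit(n_boot=2000, seed=1)
print(res.summary())
```

```
Male harm analysis
==================================================================
females analysed (uncensored): 451

Relative harm H = (W_mono - W_poly)/W_mono, 95% bootstrap CI
   20.0 degC  H =  0.214  [ 0.177,  0.248]  (W_mono=84.7, W_poly=66.6, n=77/74)
   24.0 degC  H =  0.353  [ 0.328,  0.380]  (W_mono=84.5, W_poly=54.6, n=77/75)
   28.0 degC  H =  0.108  [ 0.069,  0.151]  (W_mono=86.6, W_poly=77.2, n=74/74)

Mean lifespan decrease under polyandry
   20.0 degC   35.8%  (54.1 -> 34.8 days)
   24.0 degC   29.9%  (55.8 -> 39.1 days)
   28.0 degC   15.5%  (52.9 -> 44.7 days)

Population cost of polyandry, 1 - C_r (rows: temperature)
        r=-0.10  r=-0.05  r=+0.00  r=+0.05  r=+0.10
  20.0    0.502    0.350    0.211    0.123    0.077
  24.0    0.633    0.498    0.353    0.243    0.173
  28.0    0.218    0.161    0.111    0.081    0.065

Type-III F (Box-Cox response ~ temperature x mating system)
  lrs_bc           F_1,448 =    6.01  p = 0.0146  p_BH = 0.0585
  early_bc         F_1,448 =    0.01  p = 0.926  p_BH = 0.926
  repro_aging_bc   F_1,448 =    4.75  p = 0.0299  p_BH = 0.0789
  lifespan_bc      F_1,448 =   14.17  p = 0.000189  p_BH = 0.00152
```

Reading it: male harm to individual females peaks at 24 °C (a 35 % fitness
drop) and is mildest at 28 °C; the *population* cost of that harm is largest
in declining populations (`r < 0`, where late-life reproduction — the part
harm erodes most — carries more weight) and shrinks as `r` grows. The column
at `r = 0.00` equals H. At 20 °C the harm falls mostly on survival (35.8 %
lifespan loss), consistent with cold-temperature harm acting through
actuarial rather than reproductive aging.

The same pipeline runs from the shell on any cohort CSV
(`female_id, temperature, mating_system, death_day, censored, censor_day,
d0_3, d3_7, …` — one count column per collection interval):

```sh
conflict-demog run --seed 1 --outdir out/            # simulate + analyse
conflict-demog fitness --in cohort.csv --out comp.csv --harm harm.csv
conflict-demog rate-sensitive --in cohort.csv --out rs.csv
conflict-demog behavior --in scans.csv --out indices.csv
```

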