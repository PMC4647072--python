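# Methods

## Model

`sulfosim` is a daily time-step, process-based simulator of vegetative
oilseed-rape (*Brassica napus*) growth and sulfur dynamics, covering the
window from the end of the vegetative rest (post-vernalization) to the
onset of pod formation.  The plant is three compartments:

- **big leaf (BL)** — all in-planta leaves, photosynthetic and senescing,
  aggregated into one pool with a leaf area, a dry weight, an organic-S
  pool and a mobile (sulfate) S pool;
- **fallen leaves (FL)** — abscised tissue; its organic S and any sulfate
  not salvaged on the day of fall are permanent losses;
- **rest of the plant** — roots, taproot, stem, inflorescences and young
  pods, with a dry weight and organic/mobile S pools.

The clock is thermal time: each day contributes
`dTT = max(0, (Tmin + Tmax)/2 − Tbase)` °Cd with `Tbase = 5 °C`.  The
arithmetic-mean day temperature is the standard crop-modelling reduction of
min/max probe records.

Each day, leaf-area expansion is the *minimum* of three candidate
increments (law of minimum):

1. **temperature** — the increment of a sigmoid potential-area time course
   `LA(TT) = LA0 + (LAmax − LA0)·TTⁿ/(Kⁿ + TTⁿ)` (Hill form: `K` °Cd is the
   half-saturation thermal time, `n` a dimensionless shape exponent);
2. **carbon** — `β·dTDW·SLA`, where `dTDW = RUE·PARabs/ds` is the day's
   per-plant biomass production (Beer–Monteith:
   `PARabs = PARi·(1 − e^(−k·LAI))`, `LAI = LA_BL·ds`), `β` the maximal
   leaf allocation fraction and `SLA` the constant specific leaf area;
3. **sulfur** — `dQSoffer·SLA/[S]crit_BL`, the area the day's whole S offer
   could build at the big leaf's critical S content.

Whole-plant dry weight always grows by the full day's production; whatever
the leaves cannot use accrues to the rest compartment.  This makes per-area
canopy dry weight exactly linear in accumulated absorbed PAR, so the
regression of one on the other returns the configured RUE identically —
the defining property of an RUE-based carbon budget, and the package's main
deterministic self-check.  RUE is the one parameter that depends on the S
treatment (4.59 g DW MJ⁻¹ high-S vs 3.11 low-S); all others are shared.

### Sulfur budget

Growth requirements are *critical dilution curves*: the minimal organic-S
concentration compatible with maximal growth declines as a power law of
compartment dry weight, `[S]crit = α·DW^β` (the critical-N dilution concept
transposed to S, with sulfate excluded because the storage form plays no
structural/metabolic role).  Big leaf: `α_BL = 5.11 mg S g⁻¹`,
`β_BL = −0.52`, replaced by a constant floor of 3 mg S g⁻¹ below 3 g
because the power law cannot be extrapolated to small canopies.  Rest:
`α_rest = 1.83`, `β_rest = −0.004` (nearly flat).

The daily offer is the sum of (i) uptake, the increment of an exponential
cumulative-uptake input curve `aQS·(e^(bQS·TT) − 1)` fitted to observed
uptake (the model does not predict soil supply), (ii) the sulfate carried
by today's falling leaf tissue (a biomass-proportional share of the leaf
sulfate pool), and (iii) the whole-plant mobile (sulfate) pool.  The offer
serves the big leaf's organic requirement first, then the rest's, drawing
uptake → mobile pool → falling-leaf sulfate in that order, so sulfate about
to be lost with a leaf is salvaged only when actually needed.  The unspent
uptake + pool is the day's surplus, stored as sulfate and split between
leaf and rest with coefficient `ε`: `ε = ε_pot = 0.8` when uptake covers
the day's requirements, scaled down linearly by the uptake-to-requirement
ratio otherwise, and 0 when the leaf requirement was negative (a shrinking
leaf receives no sulfate).  The linear scaling is the simplest monotone
rule consistent with the described endpoints; the true modulation under
restriction is not published.  Any falling-leaf sulfate not drawn is lost
to the FL pool.

Leaf fall itself is an S-independent fitted time course (senescence is not
accelerated by S deficiency, since sulfate remobilizes from mature leaves
without proteolysis).  Falling tissue removes dry weight, area (via SLA)
and a proportional share of both leaf S pools.

### Time-course providers and thermal-time scales

The exact fitted forms of the potential-area, uptake and leaf-fall curves
are not published; all three are injected as named, swappable providers so
alternatives can be dropped in without touching the stepper.  Two scales
matter:

- The **simulation clock** starts at 0 at the end of the vegetative rest.
  The uptake curve and the fallen-leaf curve are anchored there (cumulative
  uptake 0, FL dry weight = its initial value).
- The **leaf-area sigmoid** is expressed on thermal time since *sowing*:
  its half-saturation constant (872.96 °Cd) sits mid-window only on that
  scale, matching the reported dynamics (expansion rate rising to full
  flowering, declining at pod formation ≈ 980 °Cd after sowing).
  `tt_offset` (480 °Cd for the calibration experiment, 565 for the
  evaluation experiment) maps the clock onto that scale inside the stepper.
  Evaluated without the offset, the sigmoid would make potential growth
  essentially zero for the first ~50 days, which contradicts every reported
  trajectory.

The default leaf-fall provider is `exp_amplitude`,
`LDW_FL(tt) = DW_FL0 + a·(e^(b·(tt+offset)) − e^(b·offset))`, reading the
printed coefficient `a = 0.0092` as an amplitude on the from-sowing scale.
This is the reading of the printed coefficients that keeps fall negligible
early and steepest near pod formation, and that predicts ≈ 0.1 g of fallen
dry weight at 565 °Cd after sowing, consistent with the 0.05 g initial
value recorded for the evaluation experiment.  Reading `a` as a rate
(`rate_integral` provider, `DW_FL0 + a·(e^(b·tt) − 1)/b`, linear limit as
`b → 0`) implies an initial fall of ~0.09 g per day, which would consume
the 0.5 g initial big leaf within a week under any configuration; it is
retained as a selectable alternative, not the default.

### Numerical choices

- Explicit Euler, one day per step; PAR absorption uses the leaf area at
  the start of the day.
- Within-day order: thermal time → PAR absorption → production → candidate
  increments → leaf fall (and its S withdrawals) → offer → law of minimum →
  biomass bookkeeping → S allocation and partitioning.
- Leaf fall is capped at the remaining big-leaf biomass (the deficit is
  logged on the flux record and as a warning); with the cap, dry-weight and
  sulfur closure hold to ~1e-12 relative at every step, and state fields
  can only go negative through round-off, where they are clamped at zero
  with a logged deficit.
- Ties in the law of minimum are labelled in the order temperature →
  carbon → sulfur.
- Initial mobile (sulfate) pools are zero — the initial-state table gives
  only total compartment S, and the reported pools are near zero until
  ~450 °Cd — so all initial S is organic.
- The initial rest dry weight is the residual
  `TDW0 − LDW_BL0 − DW_FL0`.
- Configuration TOMLs serialize floats with `repr` (17 significant
  digits); load → save → load is exact.

## Calibration

Each sub-function is fitted independently, mirroring how the model was
parameterized:

- **potential-area sigmoid** — nonlinear least squares of the produced
  leaf area (big leaf + fallen) on thermal time, in increment-anchored
  form: `y(tt) = y0 + LA(tt + offset) − LA(offset)` with `LA0` fixed at the
  measured initial area (it is an initial state, not a fitted parameter;
  only `LAmax`, `K`, `n` are free, plus the nuisance anchor `y0`);
- **uptake and leaf-fall curves** — nonlinear least squares of their
  provider forms;
- **RUE** — ordinary least squares of per-area canopy dry weight on
  accumulated absorbed PAR (the intercept absorbs initial biomass);
- **dilution curves** — least squares in log–log space of organic-S
  content, `(total S − sulfate S)/DW`, on compartment dry weight
  (log–log linearizes the power law and makes multiplicative noise
  additive);
- **SLA** — the slope of produced leaf area on produced leaf dry weight,
  exact because the model converts mass to area with one constant.

Nonlinear fits run five seeded, jittered multi-starts (log-normal factor,
σ = 0.2; fixed seed 20151117) and keep the best SSE; parameters with no
leverage on the residuals (zero Jacobian column, e.g. the shape parameters
of a constant series) are flagged as degenerate rather than silently
reported.  `β` (leaf allocation) and `ε_pot` (sulfate repartition) have no
fit operation: the prescribed observation table cannot identify them (leaf
growth in the data is min-limited, not allometric; `ε_pot` would need
within-day pool dynamics), so calibration leaves template values in place.

The classical critical-point construction for dilution curves (binning by
growth stage, minimal content at maximal biomass across many N or S
levels) needs a designed response surface that a two-treatment experiment
cannot provide; the package fits the power law directly to critical-status
content samples instead.

## Synthetic data

No measured dataset is published, so testing rests on two generators:

- **weather** — a seeded greenhouse-like series: daily mean =
  15 °C + 4 °C seasonal sinusoid + N(0, 1.5 °C); min/max = mean ∓/± 5 °C
  (so `Tmax ≥ Tmin` by construction); PAR ~ N(5, 1) MJ m⁻² d⁻¹ truncated
  at 0.  These are plausible spring-greenhouse magnitudes for the
  simulated window, not a reconstruction of any particular recorded
  season.
- **pseudo-observations** — the simulator is run, sampled at five (by
  default) thermal times spanning the window — mimicking the five
  destructive harvests from leaf development to early pod formation — and
  each sampled value receives mean-one multiplicative log-normal replicate
  noise (default σ = 5%, 3 replicates, matching the order of the reported
  error bars); the table holds replicate means and standard deviations.
  In **critical-status mode** (default) the S columns are synthesized so
  organic content sits exactly on the critical dilution curves with the
  simulated sulfate pools on top — the reference-status plants a dilution
  curve is built from — which is what makes the noise-free calibration
  round-trip exact.  With `critical_status=False` all columns are the
  trajectory's own values.

What passing tests on such data do **not** show: fidelity to real
greenhouse measurements (none ship with the package), SLA drift over
development, within-canopy leaf-age structure, N–S interactions, or soil S
supply — all outside the model's scope.

## Evaluation statistics

RMSE (variable units) and Willmott's index of agreement
`d = 1 − Σ(Sᵢ−Oᵢ)² / Σ(|Sᵢ−Ōm| + |Oᵢ−Ōm|)²` (dimensionless, `d = 1` iff
exact agreement).  Some reports print the denominator without absolute
values; because its terms can cancel, the absolute-value form is the
default and the printed form is available as `variant="printed"`.
Observations are matched to trajectory rows by nearest thermal time within
a tolerance (default 10 °Cd); unmatched rows are reported, never dropped.

## Problem sizes and tolerances in the test suite

Deterministic checks use 60-day constant-weather runs (600 °Cd, the full
simulated window).  The conservation suite runs 1,000 randomized 60-day
simulations (jittered parameters, seeded synthetic weather) and asserts
closure to 1e-9 relative at every step.  Noise-free calibration recovery
is asserted to 1e-6 relative; noisy recovery (5% noise, 4 replicates,
13 harvests) against per-parameter Monte-Carlo tolerances pre-registered
as the ceiling of the 99th-percentile spread over a 200-seed pilot —
`β_rest ≈ −0.004` gets an absolute tolerance (0.025) because its relative
error is meaningless near zero.

## Known limitations

- Uptake is an input curve, not predicted from soil supply.
- Sulfate is the only mobile S form; glutathione, glucosinolates and
  S-methyl-cysteine sulfoxide pools, which matter under severe restriction,
  are not represented.
- Constant SLA; no photoperiod, vapour-pressure or CO₂ effects; no
  post-pollination pod photosynthesis; one-day resolution.
- The rest compartment's biomass growth is never S-limited; only leaf
  expansion is (its organic pool can simply fall below critical).
- The exact published forms of the three fitted time courses are not
  available; the shipped defaults are this package's own, documented
  choices, selectable via the provider registry.
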