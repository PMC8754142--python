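# Methods

## Model structure and assumptions

The model follows a starved, clonal budding-yeast population partitioned
into quiescent (Q) and nonquiescent (NQ) biomass, together with two nutrient
pools: the limiting resource `R` of fresh medium and a recyclable pool `U`
fed by dead biomass and by residues in spent medium.  Units are chosen so
that nutrients are measured in *cell-equivalents* (the number of new cells
they can yield), making the yield coefficient 1 and turning
`Q + NQ + R + U` into a book-keeping total that is exactly conserved when
recycling is perfect (`ε = 1`) and monotonically decreasing otherwise.
Biomass is expressed per 200 µl well-equivalent, the volume in which optical
density is read.

Core biological assumptions, each carried by one term of the right-hand
sides:

* Q cells do not divide; they die slowly (rate `d_Q`) and leak into the NQ
  pool at a constant rate `τ` during starvation.
* NQ cells die faster (`d_NQ > d_Q`) but divide on whatever usable nutrients
  exist: `R` during growth/regrowth, `U` during starvation — the latter only
  in the complex environment.
* Differentiation into quiescence happens late in batch growth, as nutrients near
  depletion: its rate `σ(R) = σ_max·K_diff/(K_diff + R)` is negligible at
  high `R` and approaches `σ_max` as `R → 0`.  It is not instantaneous and
  only converts NQ → Q; the reverse flux exists only under starvation (`τ`).
* Nutrient recycling is an environment property, not a cell property:
  sterile water (simple environment) cannot supply the complementary
  compounds needed to reuse dead-cell material, so in the simple environment
  the pool `U` is inert — neither consumed nor replenished.  In spent medium
  (complex environment) a fraction `ε` of dead biomass returns to `U` and NQ
  cells divide on it with the same Monod kinetics as on `R`.
* Regrowth on fresh medium is Monod growth delayed by phenotype-specific
  lags.  A hard gate (indicator `t ≥ lag`) keeps each subpopulation inert
  until its lag ends; woken Q cells convert into the dividing pool at rate
  `w` rather than instantaneously.  No mortality is modelled over the 24 h
  assay.

## Parameters, units, defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `v_max` | maximal division rate | 0.45 h⁻¹ | ~95 min doubling in rich medium |
| `k_m` | Monod half-saturation | 3.2×10⁶ ceq | 10% of the fresh-well resource |
| `yield_coeff` | cells per cell-equivalent | 1 | unit choice |
| `d_q`, `d_nq` | starvation death rates | 2.07×10⁻⁴, 5.22×10⁻³ h⁻¹ | `−ln(0.87)/672 h`, `−ln(0.03)/672 h` from 4-week CFU viabilities |
| `tau` | Q→NQ leak | 4×10⁻⁴ h⁻¹ | ~1%/day; slow but nonzero |
| `sigma_max`, `k_diff` | differentiation kinetics | 0.1 h⁻¹, 3.2×10⁵ ceq | onset within hours once R < 1% of R₀ |
| `epsilon` | recycling efficiency | 0.5 | half of dead biomass reusable |
| `lag_q0`, `lag_nq0` | week-0 lags | 1.5 h, 2.2 h | measured monoculture baselines |
| `lag_q_slope`, `lag_nq_slope` | lag growth | 0.1/6, 1.2 h/week | linear interpolation to the measured week-6 lags (1.6 h, 9.4 h) |
| `lag_q_short`, `lag_nq_short` | 4-day-starvation gates | 1.5 h, 0.5 h | see below |
| `wake_rate` | post-lag Q conversion | 2 h⁻¹ | fast (~30 min) waking |
| fresh resource `R₀` | per-well nutrients | 3.2×10⁷ ceq | matches the observed regrowth plateau |

The lag-vs-starvation law is linear in weeks and clamped at zero; the data
motivating it show lags consistently growing with starvation time, and two
anchor points per cell type determine slope and intercept.  The **short-
starvation gates** are calibrated to the observable rather than set equal to
it: with hard gating on a 0.5 h sampling grid, the ΔOD = 0.01 threshold
estimator necessarily reports the first sample *after* growth resumes, so
gates of 1.5 h (Q) and 0.5 h (NQ) yield measured lags of exactly 2 h and
1 h — the values the threshold rule reports on real short-starvation
cultures.

## Protocols

Long protocol: cultures are initialised at OD 0.8 (biomass split 100/0,
0/100 or 75/25 for Q, NQ and 3:1-mixed compositions), optionally frozen
(survival 40% Q / 10% NQ, killed biomass entering `U`), then starved for six
weeks.  Weekly, a sample is transferred to a fresh well — the 275 µl →
550 µl → 200 µl bench geometry amounts to plating the cells of 0.1 ml of
culture, i.e. halving the per-200 µl biomass — with the starvation
supernatant (and `U`) discarded and `R` set to `R₀`; regrowth is followed
for 24 h at 0.5 h resolution.  Weekly sampling is treated as
non-destructive (~5% of culture volume per week, ignored; it affects all
compositions equally).  Short protocol: cells starved 4 days are suspended
directly in rich medium at OD 0.4 and regrown; no freezing, no starvation
mortality.  The complex environment seeds `U` with 2% of `R₀` (residual
amino acids in spent medium); both this seed and `ε` are exposed in config.

## Numerics

Phases are integrated with an adaptive, stiffness-switching solver (LSODA)
at `rtol = 1e-8`, `atol = 1e-2` cells.  The regrowth right-hand side is
discontinuous at the lag gates, so integration is split at the gate times
and solver output is stitched; an optional logistic gate of configurable
width is available if a smooth field is preferred.  Negative undershoots
within the solver's own error scale (`atol + rtol·max|y|`) are clipped to
zero; larger ones raise an integration error rather than being silently
repaired.  The test suite holds the production solver to a fixed-step RK4
oracle (Δt = 10⁻³ h, relative error < 10⁻⁴ over 48 h) on all three phase
dynamics, and to closed-form exponential solutions where they exist.

Lag estimation: the threshold rule returns the first *sampled* time with
OD − OD(0) ≥ 0.01 and a typed sentinel (`None`) when the threshold is never
crossed; downstream statistics exclude sentinels and report retained counts.
The maximum-growth-rate estimator differentiates biomass with centred finite
differences on the raw grid (no smoothing by default; an optional 3-point
median prefilter is provided) and takes the earliest maximiser among
interior grid points.  Its primary definition is the maximum *first*
derivative of biomass — the literal maximum growth rate — with the
maximum-second-derivative variant behind a flag, since the two definitions
are sometimes conflated but differ (the second-derivative peak precedes the
inflection).

Fitting: sum of squared residuals in biomass (cells), comparing observed
curves (OD converted through the calibration cubic) with trajectories
re-simulated by the same scenario machinery used everywhere else.
Differential evolution uses the rand/1/bin strategy with `F = 0.8`,
`CR = 0.9`, population `10×dim` by default, bounds enforced by clipping,
and early stopping when the best objective stalls.  Candidate parameter sets
that violate model invariants or break the integrator contribute a large
finite penalty instead of aborting the fit.  The optimiser is implemented
in-package and cross-checked in tests against an independent reference DE
implementation.

## Synthetic data

The generator emulates the deposited data's shape: 3 compositions × 2
environments × 5 replicates over 6 weeks on a 0.5 h grid within a 24 h
window, plus a 16-replicate short-starvation plate.  Replicate variability
is modelled as a per-culture jitter of the lag pair, with SD scaled by each
cell type's death rate relative to `d_NQ` — encoding the observation that NQ
cultures, whose residual division during starvation exposes them to drift
and selection, scatter more than Q cultures by weeks 5–6.  Measurement noise
is multiplicative plus additive on OD (defaults 1% and 0.005 OD), truncated
at zero with truncations counted.  Biomass below the calibration cubic's
intercept (220,300 cells/well) has no positive OD preimage and is recorded
at the OD 0 detection floor.  What the generator does *not* emulate: the 70 h
full reader run beyond the 24 h analysis window, plate-position effects,
replicate dropout (available behind a flag, default off), and any
evolutionary change (mutators, GASP-like phenotypes) during starvation —
so passing tests demonstrate correctness of the analysis chain under the
model's own assumptions, not robustness to every artefact of real plates.

## Scaled problem sizes

The parameter-recovery study fits `d_nq` and `lag_nq0` on NQ-monoculture
data from the simple environment, weeks 1–3, five replicates, additive OD
noise of 0.005, over 20 seeded repeats with a 12-member DE population and a
30-generation budget — sizes chosen to keep a full recovery study in the
order of a minute while leaving both parameters well identified (observed
recovery errors are ~1–3%, far inside the 20% acceptance band).

## Known limitations

* The supplementary equations of the source model are not available; the
  right-hand sides here are a reconstruction in which every term maps to a
  stated assumption.  The rhs functions are isolated so alternative forms
  can be swapped in.
* Death is switched off during regrowth; over 24 h in rich medium this is a
  <1% effect at the default death rates.
* The wake-rate mechanism makes Q and NQ monocultures asymmetric even with
  equal lags; they coincide only in the fast-waking limit (tested at
  `w = 500 h⁻¹`).
* Statistics are the study's own: one-way ANOVA + Tukey at chosen time
  points and pairwise t tests on lags, with no correction across time
  points (noted in output metadata) and no mixed-effects modelling of the
  full time course.
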