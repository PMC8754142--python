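# qnq — quiescent/nonquiescent yeast dynamics through starvation and regrowth

Glucose-starved *Saccharomyces cerevisiae* populations are phenotypically
heterogeneous: some cells actively exit the cell cycle into a stress-resistant
**quiescent (Q)** state, while the rest remain **nonquiescent (NQ)** — cycling,
shorter-lived, but able to divide on residual nutrients and to restart growth
quickly after a brief starvation.  `qnq` implements an ecological ODE model of
this two-phenotype system and the plate-reader analytics used to study it,
letting you simulate and analyse the classic experiment: starve Q
monocultures, NQ monocultures and natural 3:1 Q:NQ mixtures for up to six
weeks — in sterile water (*simple* environment) or spent medium (*complex*
environment, where nutrient recycling is possible) — and follow their weekly
regrowth on fresh rich medium.

## The model

State variables: viable Q biomass, viable NQ biomass, limiting resource `R`
and recyclable nutrient pool `U` (all in cells / cell-equivalents per 200 µl
well).  Three phases:

* **Growth & differentiation** — NQ cells divide with Monod kinetics
  `v_max·R/(K_m+R)` and differentiate into Q at rate
  `σ(R) = σ_max·K_diff/(K_diff+R)`, which switches on as nutrients near
  depletion.
* **Starvation** — `dQ/dt = −(d_Q+τ)·Q`,
  `dNQ/dt = −d_NQ·NQ + τ·Q + v_max·U/(K_m+U)·NQ`, with a fraction `ε` of dead
  biomass returned to `U`.  Division on `U` and recycling operate only in the
  complex environment.  Death rates are calibrated from 4-week CFU
  viabilities (87% Q, 3% NQ): `d = −ln(s)/t`.
* **Regrowth** — each subpopulation is inert until its lag ends; Q cells then
  wake into the dividing pool at rate `w`, NQ cells grow with Monod kinetics.
  Lags grow linearly with starvation weeks (Q: 1.5 → 1.6 h; NQ: 2.2 → 9.4 h
  over six weeks); after a 4-day "short" starvation the ordering inverts
  (measured lags 2 h for Q vs 1 h for NQ).

On top of the model: the protocols (freezing stress with 40%/10% Q/NQ
survival, 275 → 550 → 200 µl transfer geometry), the OD600↔biomass
calibration cubic, two lag estimators (ΔOD = 0.01 threshold rule and
maximum-growth-rate rule), relative-biomass normalisations, ANOVA + Tukey and
t-test comparisons, an in-package differential-evolution (rand/1/bin) fitter,
and a synthetic plate-reader data generator with replicate and measurement
noise.

## Worked example

```python
import numpy as np
from qnq import (ModelParams, Scenario, run_long_starvation,
                 run_short_starvation, lag_threshold, GrowthCurve)
from qnq.synthetic import _biomass_to_od_floor

params = ModelParams()

# Q-monoculture advantage over NQ at 2 h of regrowth, weeks 1..6 (simple env)
q  = run_long_starvation(Scenario(composition="Q",  environment="simple"), params)
nq = run_long_starvation(Scenario(composition="NQ", environment="simple"), params)
print(np.round([q[w].biomass[4] / nq[w].biomass[4] for w in range(6)], 1))
# [  9.7  21.5  46.8 101.6 219.9 475.8]

# short starvation: the NQ lag is now the shorter one
for comp in ("Q", "NQ"):
    assay = run_short_starvation(
        Scenario(composition=comp, environment="simple", freezing=False,
                 starvation_days=4, initial_od=0.4), params)
    od = _biomass_to_od_floor(assay.biomass)
    print(comp, lag_threshold(GrowthCurve(assay.times, od)), "h")
# Q 2.0 h
# NQ 1.0 h
```

The first block shows the Q monoculture's early-regrowth biomass advantage
growing week by week — the signature of lower Q mortality during starvation.
The second reproduces the short-starvation lag inversion: after only 4 days
of starvation NQ cells resume growth a full hour before Q cells.

Command-line equivalents:

```bash
qnq generate --seed 1 --out data.csv        # synthetic 30-culture dataset
qnq analyze  --data data.csv --out-dir analysis
qnq report   --seed 1 --out-dir run1        # full pipeline + summary.json
qnq fit --data data.csv --free d_nq,lag_nq0 --bounds bounds.yaml \
        --seed 1 --out fit.json
```

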