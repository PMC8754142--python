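# Plate layout of the study: 3 compositions x 2 starvation environments,
# 5 replicates each, starved (after freezing) for 6 weeks with weekly
# 24 h regrowth assays; plus a 16-replicate short-starvation plate
# (4 days stationary phase, no freezing, OD 0.4).
scenarios:
  - {composition: Q,     environment: simple,  freezing: true, starvation_weeks: 6, initial_od: 0.8, n_replicates: 5}
  - {composition: NQ,    environment: simple,  freezing: true, starvation_weeks: 6, initial_od: 0.8, n_replicates: 5}
  - {composition: mixed, environment: simple,  freezing: true, starvation_weeks: 6, initial_od: 0.8, n_replicates: 5}
  - {composition: Q,     environment: complex, freezing: true, starvation_weeks: 6, initial_od: 0.8, n_replicates: 5}
  - {composition: NQ,    environment: complex, freezing: true, starvation_weeks: 6, initial_od: 0.8, n_replicates: 5}
  - {composition: mixed, environment: complex, freezing: true, starvation_weeks: 6, initial_od: 0.8, n_replicates: 5}
  - {composition: Q,     environment: simple, freezing: false, starvation_days: 4, initial_od: 0.4, n_replicates: 16}
  - {composition: NQ,    environment: simple, freezing: false, starvation_days: 4, initial_od: 0.4, n_replicates: 16}
  - {composition: mixed, environment: simple, freezing: false, starvation_days: 4, initial_od: 0.4, n_replicates: 16}
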