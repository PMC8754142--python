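# Default model parameters.  Rates are per hour, lags in hours, nutrient
# levels in cell-equivalents (cells per 200 ul well-equivalent).
v_max: 0.45                 # maximal per-capita division rate (1/h)
k_m: 3.2e6                  # Monod half-saturation resource level
yield_coeff: 1.0            # cells produced per cell-equivalent consumed
d_q: 2.0723521924629116e-4  # Q death rate (1/h); exp(-d*672 h) = 0.87
d_nq: 5.218092109107115e-3  # NQ death rate (1/h); exp(-d*672 h) = 0.03
tau: 4.0e-4                 # Q -> NQ transition rate during starvation (1/h)
sigma_max: 0.1              # maximal NQ -> Q differentiation rate (1/h)
k_diff: 3.2e5               # resource level of half-maximal differentiation
epsilon: 0.5                # recycling efficiency (complex environment only)
lag_q0: 1.5                 # Q lag at week 0 (h)
lag_nq0: 2.2                # NQ lag at week 0 (h)
lag_q_slope: 0.016666666666666666  # Q lag increase (h/week): 1.5 -> 1.6 h by week 6
lag_nq_slope: 1.2           # NQ lag increase (h/week): 2.2 -> 9.4 h by week 6
lag_q_short: 1.5            # Q regrowth gate after 4-day starvation (h)
lag_nq_short: 0.5           # NQ regrowth gate after 4-day starvation (h)
wake_rate: 2.0              # post-lag Q -> dividing-pool conversion rate (1/h)
gate_width: 0.0             # 0 = hard lag gate; >0 = logistic gate width (h)
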