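# Measurement/replicate noise defaults, matched to the order of magnitude
# of the replicate error bars in the study's growth-curve figures.
sigma_add: 0.005        # additive OD noise SD
sigma_mult: 0.01        # multiplicative OD noise SD
replicate_effect_sd: 0.25  # per-replicate lag jitter SD (h) at death rate d_nq
seed: 0
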