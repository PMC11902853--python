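# Default synthetic-cohort study: 14 HC-like vs 34 TLE-like subjects,
# 20 regions x 1000 samples at 500 Hz, +0.3 coupling on 5 planted edges.
# All keys are PipelineConfig fields; omitted keys keep their defaults.
seed: 1
n_regions: 20
sim_order: 2
n_samples: 1000
n_group_a: 14
n_group_b: 34
n_effect_edges: 5
effect_gain: 0.3
methods: [gca, pcc]
order_mode: bic
alpha: 0.05
train_frac: 0.7
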