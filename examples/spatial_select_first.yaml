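# Spatial heterogeneity only, select-first life history, island dispersal.
# A quick-look scale: 20 demes, 500 generations, 3 replicates.
n_demes: 20
carrying_capacity: 100
order: select_first
dispersal_pattern: island
dispersal_rate: 0.32
sigma: 2.0
n_generations: 500
n_replicates: 3
base_seed: 3
report_window: 100
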