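# Default desk-scale study configuration.
# Two synthetic seasons of 24 trees x 5 fruits, photographed ~5 times per
# resolution tier on each water-potential measurement day.
seed: 11
n_trees: 24
fruits_per_tree: 5
marker_side_mm: 15.0
season: [2023-07-21, 2023-11-09]
rain_events: [2023-08-16]
images_per_date: 5
psi_floor: -2.0
psi_baseline_c: -0.4
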