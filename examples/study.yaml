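# Simulated six-FA reporter study: dose series + pair/triple mixtures.
# Run:  pparmix simulate --config examples/study.yaml
#       pparmix analyze  --config examples/study.yaml   (after pointing
#       'input' at the simulated CSV, or use the analysis/ drivers)
out_dir: results/example
seed: 1
alpha: 0.05
viability_threshold: 0.7
pair_scale: 1.0
triple_scale: 0.333333333333
simulation:
  n_dose_points: 10
  n_replicates: 4
  n_vehicle_per_replicate: 8
  noise_cv: 0.10
  viability_onset: 125.0
  viability_rate: 0.004
  mixture_mode: weighted
  kappa: 1.0
  base_firefly: 50000
  base_renilla: 25000
  panel:
    "C12:0":      {max_dose: 500, b1: 0.0066,       b2: 0.0}
    "C16:0":      {max_dose: 316, b1: 0.0278481013, b2: -8.8126902e-05}
    "C16:1":      {max_dose: 316, b1: 0.0202531646, b2: -6.4092934e-05}
    "C18:0":      {max_dose: 380, b1: 0.0221052632, b2: -5.8171745e-05}
    "C18:1":      {max_dose: 316, b1: 0.0189873418, b2: -6.0086525e-05}
    "C20:0 BCFA": {max_dose: 316, b1: 0.0227848101, b2: -7.2104150e-05}
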