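# Two-condition steered-association pipeline, scaled for a quick desk run.
# `pocketdyn pipeline --config configs/quickstart.yml --out results/pipeline`
base_seed: 1

defaults:
  start_distance: 27.0      # Å, initial cofactor COM distance from the lysine
  n_replicates: 10
  n_steps: 20000
  dt_ps: 0.001
  temperature_K: 300.0
  friction_per_ps: 1.0
  record_stride: 200        # one recorded frame per 0.2 ps

conditions:
  occluded:                 # reference condition: gated pocket
    pocket: occluded
  open:                     # alternative condition: accessible pocket
    pocket: open

ts_criteria:
  d_max: 4.0                # Å, strict
  attack_angle_tol: 30.0    # degrees around 109
  linearity_tol: 30.0       # degrees around 180

contact:
  cutoff: 4.5               # Å, heavy-atom pair, strict

volume:
  spacing: 0.4              # Å
  distance_cut: 0.4         # Å
  contiguity: 3
  hull: false               # the pocket shell itself bounds the cavity
  proximity_mode: vdw
  spheres:                  # sized to cover the toy pocket around the lysine
    - center: [0.0, 0.0, 1.0]
      radius: 3.5
  subsample_fraction: 0.1   # triplicate 10% frame subsamples
  n_subsamples: 3
  threshold: 100.0          # Å³, toy-scaled "large volume" band (empty pocket
                            # ≈ 120 Å³, cofactor-occupied ≈ 90 Å³)

stats:
  binomial_construction: upper_tail_alt_at_ref_rate
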