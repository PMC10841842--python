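# Demo pipeline configuration: 60/40 monomer/dimer population at mNG
# activity with 5% one-step background, rendered to noisy traces and
# re-counted before fitting. Run with:  simpull report examples/demo_config.yaml
components:
  - [1, 0.6]
  - [2, 0.4]
fluorophore: mNG
activities: {mNG: 0.74, SNAPf: 0.78}
n_spots: 5000
background_rate: 0.05
background_step_dist: {1: 1.0}
seed: 2024
use_traces: true
frames: 400
step_intensity: 1.0
bleach_rate: 0.02
noise_sd: 0.2
control_scale: 1.0
fit: {k_max: 4, m_max: 10}
aic_variant: paper
out_dir: simpull_run
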