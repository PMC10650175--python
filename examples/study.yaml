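# A compact two-condition synthetic study (12-channel montage, one block).
# The O1 condition carries an extra occipital -> contralateral-frontal
# coupling confined to the 48-92 ms window; the contrasts should flag the
# F4 <- O1 edge in that window with a positive sign.
#
#   tepnet run-all --config examples/study.yaml --out study/

study:
  subjects: 18
  seed: 7

montage: small12
srate: 500.0
times: {start: -260.0, stop: 260.0}
session: {blocks: 1, trials_per_block: 60}

network:
  order: 1
  diag: [0.5]
  noise_std: 1.0
  trial_noise_sd: 0.2
  # common couplings, written in the O1 frame and mirrored for O2
  couplings:
    - [O1, P3, 1, 0.30, 12.0, 240.0]
    - [P3, F3, 1, 0.25, 48.0, 240.0]
  effect_couplings:
    O1:
      - [O1, F4, 1, 0.35, 48.0, 92.0]
    O2: []

ep: {enabled: true, amplitude: 0.8, jitter_sd: 0.1}
tep: {methods: [ca]}
connectivity:
  order: 1
  band: [1.0, 40.0]
  window_boundaries: [12.0, 24.0, 48.0, 92.0, 124.0, 240.0]
  baseline_window: [-240.0, -12.0]
graph: {threshold: 0.5}
stats: {alpha_edges: 0.001, alpha_gmfp: 0.05}
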