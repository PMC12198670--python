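# Demo study: small synthetic cohort with an efferent group-by-task effect.
seed: 42
output_dir: cmcpipe_out

synthetic:
  n_per_group: 3
  trials_per_task: 2
  bands: [alpha, beta]
  band_effects:
    amputee/EC/alpha/efferent: 2.0
  base_spec:
    delay_ms: 24.0
    direction: efferent
    snr_db: 10.0
    coupling_strength: 0.5

surrogates:
  n_surrogates: 20

stats:
  n_perm: 499
  nmds_restarts: 4
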