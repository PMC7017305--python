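# Full synthetic run: a 200-gene splicing panel with planted effects,
# a planted enriched term, and a scored interactome with planted hubs.
seed: 1
synthetic:
  n_genes: 200
  probes_per_gene: 2
  baseline_log2_mean: 8.0
  noise_sd_log2: 0.5
  # group_sizes defaults to the cohort design: 18/13/10 cortex, 17/13/10 spinal
  effects:
    - {kind: state_main, gene: 0, state: SALS1, shift: 2.0}
    - {kind: state_main, gene: 1, state: SALS1, shift: 2.0}
    - {kind: state_main, gene: 2, state: SALS2, shift: -2.0}
    - {kind: state_main, gene: 3, state: SALS2, shift: -2.0}
    - {kind: tissue_main, gene: 4, tissue: motor_cortex, shift: 1.5}
    - {kind: interaction, gene: 5, shift: 1.5}
  interactome:
    edges_per_new_node: 2
    planted_hubs: [0, 2]
  annotations:
    n_terms: 12
    planted_term:
      name: planted_term
      members: [0, 1, 2, 3]
alpha: 0.05
fc_cut: 2.0
top_fraction: 0.15
ss_type: 3
gating: effect
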