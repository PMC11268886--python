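# Synthetic end-to-end fixture: simulate a DIA peptide report and run the
# full enrichment pipeline with the published defaults.
seed: 2024
output_dir: proxidia_demo
synthetic:
  n_proteins: 120
  peptides_per_protein: [8, 18]
  spike_fc: 4.0
  spike_fraction: 0.04
  frac_phospho: 0.05
thresholds:
  fc_threshold: 1.5
  q_threshold: 0.05
network:
  score_cutoff: 0.7
  bait: Rac1
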