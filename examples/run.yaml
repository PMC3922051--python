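# Full pipeline on a simulated seven-sample 454-style run.
# Usage: brine18s run --config examples/run.yaml
out_dir: scratch/example_run
seed: 42
panel:
  n_kingdoms: 6
  per_kingdom: 2
  seq_length: 450
  inter_kingdom_divergence: 0.30
  intra_kingdom_divergence: 0.04
simulate:
  n_reads: 60              # per sample; 7 samples use the study barcodes
  composition: archetypes  # mat-like / interface-like / sediment-like mixtures
  false_amplicon_fraction: 0.05
  short_read_fraction: 0.03
  ambiguous_base_fraction: 0.03
  homopolymer_fraction: 0.03
  lowq_fraction: 0.03
levels: [0.03, 0.20]
bootstrap: 100
min_support: 0.5
k_axes: 2
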