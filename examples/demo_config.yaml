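# Demo run: synthetic study at the package's default study conditions
# (12 samples in 5 design cells; 2000 mRNA probes with 50 planted
# differentially expressed per group plus 25 shared between the two
# hyperoxia groups; 521 miRNA assays with planted effects and 20% of
# assays forced above the 35-cycle detection ceiling; two prediction
# databases with different miss rates).
outdir: scratch/demo_run
seed: 42
synthetic: {}
thresholds:
  mrna_fc: 2.0
  mirna_fc: 4.0
  fdr: 0.05
  low_expression_min_log2: 5.0
  detection_min_fraction: 0.5
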