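# Demo run: four repeat classes with six copies each, three replicates per
# condition, IAP-like class activated fifteenfold in the depleted condition.
seed: 7

simulation:
  n_classes: 4
  copies_per_class: 6
  copy_length_range: [800, 7000]
  inter_copy_divergence: 0.02
  read_length: 50
  background_fraction: 0.9
  replicate_cv: 0.1
  class_fold_changes:
    IAPEz: 15.0
  n_peaks: 300
  peak_enrichment_fraction: 0.8
  enriched_classes: [IAPEz]
  bs_reads_per_treatment: 2000
  bs_replicates: 2

merge_names: [IAPEz]

thresholds:
  merge_gap: 100
  detection_rpm: 0.25
  copy_fold: 10
  pseudocount_rpm: 0.1
  de_lfc: 1.0
  de_alpha: 0.05
  min_coverage: 100
  n_shuffles: 1000
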