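# Full study-replica configuration using the packaged presets.
# Any CohortConfig field may be overridden under `cohort:`; variant lists may
# be preset names or explicit profile mappings.
cohort: table2_defaults
matching:
  age_caliper: 1.0
classifier_variants: classifier_ladder
detector_variants: detector_ladder
classification_threshold: 0.5
iou_thresholds: [0.5]
master_seed: 0
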