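# Pipeline thresholds; keys mirror ampliseq.panel.CallerConfig.
min_mean_quality: 25
min_read_length: 75
min_strand_depth: 15
min_vaf: 0.20
max_depth: 10000
strand_bias_p: 0.01
hp_min_length: 5
hp_carrier_threshold: 0.10
recurrence_fraction: 0.75
consensus_votes_required: 5
consensus_votes_total: 7
min_emit_count: 2
strand_bias_ratio: 5.0
phase_min_reads: 5
phase_max_contradiction: 0.10
common_af_threshold: 0.05
hp_stutter_rates:
  -2: 0.06
  -1: 0.15
  1: 0.04
hp_stutter_alpha: 1.0e-6
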