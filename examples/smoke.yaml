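# Desk-scale end-to-end smoke configuration for `vadistill run-all`.
seed: 5
outdir: runs/smoke
fixtures:
  n_speech: 8
  n_background: 8
  n_bird: 4
  n_soundscape: 1
  soundscape_duration_s: 16.0
  soundscape_rate: 16000
dataset:
  n_total: 48
  snr_low_db: 0.0
  snr_high_db: 18.0
train:
  max_epochs: 2
  students: [student4]
  methods: [soft_target]
  runs_per_method: 2
playback:
  n_per_cell: 1
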