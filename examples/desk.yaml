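# Desk-scale run configuration: small widths and short training so the whole
# noisy-student pipeline finishes in about a minute on one CPU core.
phantom:
  shape: [64, 64, 64]
  lesion_count_mean: 4.29

candidates:
  max_candidates: 300

teacher:
  blocks_per_level: 2
  roi_edge_mm: 16
  widths: [4, 8, 16, 32]

student:
  blocks_per_level: 4
  roi_edge_mm: 16
  widths: [4, 8, 16, 32]

noise:
  elastic_alpha: 2.0
  elastic_sigma: 4.0
  gamma_range: [0.8, 1.25]

training:
  iterations: 150
  teacher_batch: [16, 16]
  student_batch: [8, 8, 8, 8]
  learning_rate: 0.002
  pseudo_cap_per_exam: 100

ns:
  ts: 0.90
  lam: 1.0
  iterations: 1
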