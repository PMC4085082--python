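# Default configuration for the hierarchical heartbeat classifier.
#
# Every constant a user might legitimately edit lives here rather than in
# code: the beat-window geometry, the AAMI symbol map, and the inter-patient
# record split of the MIT-BIH arrhythmia database.

sampling_rate: 360          # Hz; the MIT-BIH arrhythmia database rate
window_len: 200             # samples per beat window
pre_samples: 100            # samples taken before the R fiducial (R itself + 99 after)

# Stage-1 SVM ensemble defaults (selected by cross-validation on DS1).
n_matrices: 15              # ensemble size M
projection_dim: 50          # random signals per matrix (feature dimension d)
svm_C: 1.0
svm_delta: 1.3              # RBF kernel coefficient gamma
lead_config: A

# Stage-2 RR-ratio rule.
sveb_threshold: 0.8
sveb_se_target: 80.0        # percent; threshold selection aims for Se >= this
threshold_grid:
  start: 0.70
  stop: 0.90
  step: 0.01

# MIT-BIH symbol -> AAMI class. Codes not listed here and not in
# non_beat_symbols map to Q (unknown).
symbol_map:
  N: N
  L: N
  R: N
  e: N
  j: N
  A: S
  a: S
  J: S
  S: S
  V: V
  E: V
  F: F
  "/": Q
  f: Q
  Q: Q

# Annotation codes that are not beats (rhythm changes, artifacts, waveform
# marks); they are rejected before segmentation, not mapped to a class.
non_beat_symbols: ["+", "~", "|", "\"", "[", "]", "!", "x", "(", ")", "p",
                   "t", "u", "`", "'", "^", "s", "T", "*", "D", "=", "@"]

# Inter-patient division of the 44 non-paced MIT-BIH recordings.
excluded_records: [102, 104, 107, 217]    # paced recordings
ds1_records: [101, 106, 108, 109, 112, 114, 115, 116, 118, 119, 122, 124,
              201, 203, 205, 207, 208, 209, 215, 220, 223, 230]
ds2_records: [100, 103, 105, 111, 113, 117, 121, 123, 200, 202, 210, 212,
              213, 214, 219, 221, 222, 228, 231, 232, 233, 234]
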