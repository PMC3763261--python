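# Published 4-parameter fits to the USA first-hospital-admission cumulative
# incidence data (rates per year; f_s is the admission lifetime risk).
usa_males:
  m: 16
  m1: 15
  k1: 0.11653
  k2: 0.028465
  f_s: 0.0015737
  r: 1.0
usa_females:
  m: 16
  m1: 15
  k1: 0.09859
  k2: 0.035728
  f_s: 0.0016428
  r: 1.0
usa_males_females:
  m: 16
  m1: 15
  k1: 0.10757
  k2: 0.029959
  f_s: 0.0016363
  r: 1.0
# 3-parameter (single-rate) fit to the male data, m = 10 equal-rate steps.
usa_males_3param:
  m: 10
  m1: 9
  k1: 0.08172
  k2: 0.08172
  f_s: 0.00137
  r: 1.0
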