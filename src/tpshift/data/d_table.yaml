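format: tpshift-gap-table/1
levels:
- -0.11261079701234238
- 0.8060752927111957
- 1.1623884266673976
- 1.5213037140445718
- 2.233448053309779
- 2.913511932075954
- 3.093292516653768
- 3.6751715395460085
- 4.60906682573298
- 4.938482361046402
- 5.51024446461068
- 6.307672860539286
- 6.546205819803925
- 7.4516138196034545
- 8.129906561076822
- 8.764491827121132
- 9.411113479045353
- 9.900216134425996
- 10.244559879314842
- 10.922455982163466
- 11.752870683823769
d:
- 800.0
- 525.0
- 800.0
- 475.0
- 500.0
- 175.0
- 80.0
- 65.0
- 65.0
- 58.0
- 58.0
- 52.0
- 52.0
- 46.0
- 40.0
- 42.0
- 44.0
- 42.0
- 36.0
- 38.0
- 30.0
meta:
  seed: 0
  n_per_level: 100
  length: 600
  criterion: outside events / predicted events <= 5% at the selected d
  generation_levels:
    '0.0':
      d: 800.0
      rate: 0.0
      rate_per_sequence: 0.0
      measured_x: -0.11261079701234238
    '1.0':
      d: 525.0
      rate: 0.0
      rate_per_sequence: 0.0
      measured_x: 0.8060752927111957
    '2.0':
      d: 800.0
      rate: 0.0
      rate_per_sequence: 0.0
      measured_x: 1.1623884266673976
    '3.0':
      d: 475.0
      rate: 0.0
      rate_per_sequence: 0.0
      measured_x: 1.5213037140445718
    '4.0':
      d: 500.0
      rate: 0.0
      rate_per_sequence: 0.0
      measured_x: 2.233448053309779
    '5.0':
      d: 175.0
      rate: 0.045454545454545456
      rate_per_sequence: 0.04
      measured_x: 2.913511932075954
    '6.0':
      d: 80.0
      rate: 0.04950495049504951
      rate_per_sequence: 0.05
      measured_x: 3.093292516653768
    '7.0':
      d: 65.0
      rate: 0.047619047619047616
      rate_per_sequence: 0.05
      measured_x: 3.6751715395460085
    '8.0':
      d: 65.0
      rate: 0.038461538461538464
      rate_per_sequence: 0.04
      measured_x: 4.60906682573298
    '9.0':
      d: 58.0
      rate: 0.04716981132075472
      rate_per_sequence: 0.05
      measured_x: 4.938482361046402
    '10.0':
      d: 58.0
      rate: 0.047619047619047616
      rate_per_sequence: 0.05
      measured_x: 5.51024446461068
    '11.0':
      d: 52.0
      rate: 0.04672897196261682
      rate_per_sequence: 0.05
      measured_x: 6.307672860539286
    '12.0':
      d: 52.0
      rate: 0.04716981132075472
      rate_per_sequence: 0.05
      measured_x: 6.546205819803925
    '13.0':
      d: 46.0
      rate: 0.047619047619047616
      rate_per_sequence: 0.05
      measured_x: 7.4516138196034545
    '14.0':
      d: 40.0
      rate: 0.02830188679245283
      rate_per_sequence: 0.03
      measured_x: 8.129906561076822
    '15.0':
      d: 42.0
      rate: 0.04716981132075472
      rate_per_sequence: 0.05
      measured_x: 8.764491827121132
    '16.0':
      d: 44.0
      rate: 0.02912621359223301
      rate_per_sequence: 0.03
      measured_x: 9.411113479045353
    '17.0':
      d: 42.0
      rate: 0.028846153846153848
      rate_per_sequence: 0.03
      measured_x: 9.900216134425996
    '18.0':
      d: 36.0
      rate: 0.04716981132075472
      rate_per_sequence: 0.05
      measured_x: 10.244559879314842
    '19.0':
      d: 38.0
      rate: 0.019417475728155338
      rate_per_sequence: 0.02
      measured_x: 10.922455982163466
    '20.0':
      d: 30.0
      rate: 0.038461538461538464
      rate_per_sequence: 0.04
      measured_x: 11.752870683823769
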