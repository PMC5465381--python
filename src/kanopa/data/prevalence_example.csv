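feature_code,prevalence_pct
A1,2
A2,2
A3,64
A5,
A6,36
A7,33
A8,17
A9,8
A10,29
A11,29
A12,17
A13,6
A14,6
A15,22
A20,
A21,3
A22,1
A23,0
A24,4
A25,42
A26,42
A29,49
A30,47
A39,79
A52,35
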