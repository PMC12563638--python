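subject,accuracy,channel
S1,64,AF3
S2,60,PZ
S3,66,T7
S4,52,PZ
S5,66,AF4
S6,68,T8
S7,76,T8
S8,62,PZ
S9,34,T7
S10,76,AF4
S11,60,T7
S12,80,PZ
S13,68,AF4
S14,78,T7
S15,54,AF4
S16,72,AF4
S17,62,T7
S18,80,PZ
S19,58,AF4
S20,76,PZ
S21,64,T8
S22,62,T7
S23,64,PZ
S24,50,PZ
S25,68,T7
S26,58,AF4
S27,52,T7
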