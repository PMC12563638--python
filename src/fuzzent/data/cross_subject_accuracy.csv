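subject,C1,C2,C3,C4,C5,C6
S1,74,64,66,60,62,64
S2,64,60,62,64,54,66
S3,54,66,58,62,54,58
S4,66,52,54,46,84,64
S5,56,66,68,70,54,58
S6,56,68,60,56,66,58
S7,68,76,58,66,54,62
S8,52,62,58,54,56,62
S9,28,34,52,52,42,36
S10,68,76,52,58,54,66
S11,50,60,58,62,56,54
S12,66,80,62,66,94,62
S13,80,68,60,68,54,72
S14,58,78,62,62,58,58
S15,58,54,50,58,52,58
S16,60,72,60,48,56,70
S17,64,62,56,54,54,62
S18,72,80,70,70,72,72
S19,52,58,64,72,46,54
S20,74,76,64,78,78,74
S21,68,64,58,58,68,58
S22,60,62,66,68,74,68
S23,54,64,66,66,60,60
S24,60,50,64,64,54,60
S25,58,68,60,70,64,62
S26,56,58,62,60,62,58
S27,54,52,56,56,52,54
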