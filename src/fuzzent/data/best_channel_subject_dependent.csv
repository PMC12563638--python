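subject,loocv_accuracy,loocv_channel,kfold10_accuracy,kfold10_channel
S1,84,T7,86,T7
S2,98,T7,98,T7
S3,68,T8,68,T8
S4,92,T7,96,T7
S5,70,T7,68,AF3
S6,74,T8,64,PZ
S7,84,AF3,82,T7
S8,68,PZ,70,PZ
S9,98,T7,98,T7
S10,82,AF4,78,AF4
S11,82,AF4,76,AF4
S12,94,PZ,92,PZ
S13,98,T8,98,T8
S14,80,T7,80,T7
S15,88,AF4,88,AF4
S16,76,AF4,82,AF4
S17,82,PZ,80,PZ
S18,88,T8,86,AF3
S19,66,T8,68,AF3
S20,72,PZ,66,PZ
S21,86,T8,82,T8
S22,90,PZ,90,T7
S23,62,PZ,66,PZ
S24,72,T7,74,T7
S25,98,PZ,98,PZ
S26,90,T8,90,T8
S27,92,PZ,90,AF3
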