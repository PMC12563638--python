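subject,kfold10.C2.T7-PZ,kfold10.C2.T7-T8,kfold10.C2.PZ-T8,kfold10.C6.T7-PZ,kfold10.C6.T7-T8,kfold10.C6.PZ-T8,losocv.C2.T7-PZ,losocv.C2.T7-T8,losocv.C2.PZ-T8,losocv.C6.T7-PZ,losocv.C6.T7-T8,losocv.C6.PZ-T8
S1,76,72,70,68,56,60,50,58,48,48,54,54
S2,94,98,96,96,98,98,54,52,62,50,54,52
S3,58,56,58,74,72,62,50,34,50,52,46,50
S4,80,70,84,84,78,78,40,36,42,62,62,54
S5,62,74,70,64,64,68,46,72,56,58,50,52
S6,54,42,58,54,52,60,52,44,50,60,58,54
S7,80,78,74,74,66,64,50,42,52,64,56,76
S8,82,70,54,74,54,54,38,50,52,48,62,60
S9,98,86,98,98,92,98,20,26,60,20,18,20
S10,82,68,86,68,74,82,60,72,54,62,66,72
S11,64,78,76,56,72,70,58,54,54,56,58,48
S12,96,52,96,84,64,86,48,62,46,68,64,60
S13,94,98,96,98,98,98,56,62,50,74,38,62
S14,62,70,68,68,56,72,42,32,50,46,48,32
S15,68,58,72,78,86,90,46,46,50,50,54,52
S16,66,80,72,68,74,68,54,52,56,56,60,64
S17,60,40,42,68,56,68,56,60,64,60,62,56
S18,84,70,84,82,74,82,46,34,36,52,60,72
S19,52,58,40,52,66,54,54,50,48,50,56,50
S20,78,56,78,72,60,76,56,40,52,56,36,60
S21,76,82,86,86,78,84,34,50,50,62,56,62
S22,74,72,72,86,74,84,62,42,52,56,48,46
S23,54,68,70,76,64,70,58,58,58,52,42,52
S24,70,74,70,76,60,68,54,42,46,60,42,56
S25,94,94,94,98,98,98,50,44,50,72,42,56
S26,82,70,86,80,60,68,20,34,32,24,42,18
S27,94,84,82,94,84,94,50,54,52,54,48,50
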