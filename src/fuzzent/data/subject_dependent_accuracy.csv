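subject,scheme,C1,C2,C3,C4,C5,C6
S1,loocv,60,72,80,74,72,84
S2,loocv,98,98,94,92,98,98
S3,loocv,70,72,66,72,76,68
S4,loocv,88,86,86,88,84,92
S5,loocv,74,76,74,70,72,70
S6,loocv,68,68,54,62,68,74
S7,loocv,86,88,84,88,86,84
S8,loocv,72,74,66,74,76,68
S9,loocv,98,98,98,98,98,98
S10,loocv,80,80,78,80,82,82
S11,loocv,66,78,72,68,72,82
S12,loocv,96,96,96,96,96,94
S13,loocv,98,98,98,98,98,98
S14,loocv,80,86,78,82,80,80
S15,loocv,80,78,74,82,82,88
S16,loocv,62,74,70,76,64,76
S17,loocv,58,44,58,60,60,82
S18,loocv,92,94,90,94,94,88
S19,loocv,60,52,56,58,62,66
S20,loocv,78,78,72,72,80,72
S21,loocv,82,82,84,82,84,86
S22,loocv,86,86,88,86,88,90
S23,loocv,60,62,64,66,60,62
S24,loocv,70,68,66,70,74,72
S25,loocv,98,94,94,98,98,98
S26,loocv,94,94,96,96,96,90
S27,loocv,86,88,88,82,90,92
S1,kfold10,62,74,80,72,72,86
S2,kfold10,98,98,96,92,98,98
S3,kfold10,58,74,64,72,74,68
S4,kfold10,88,84,86,86,84,96
S5,kfold10,74,76,70,70,74,68
S6,kfold10,66,68,60,60,66,64
S7,kfold10,88,88,82,88,86,82
S8,kfold10,74,76,66,78,76,70
S9,kfold10,98,98,98,98,98,98
S10,kfold10,82,80,80,82,80,78
S11,kfold10,68,78,68,72,72,76
S12,kfold10,96,94,96,96,96,92
S13,kfold10,98,98,98,98,98,98
S14,kfold10,84,82,78,80,80,80
S15,kfold10,80,78,80,82,82,88
S16,kfold10,64,70,72,80,66,82
S17,kfold10,60,54,56,58,58,80
S18,kfold10,94,92,90,94,92,86
S19,kfold10,60,58,66,60,62,68
S20,kfold10,78,78,72,74,80,66
S21,kfold10,82,80,84,82,84,82
S22,kfold10,86,86,90,86,88,90
S23,kfold10,56,58,66,66,56,66
S24,kfold10,66,70,64,68,78,74
S25,kfold10,98,94,94,96,98,98
S26,kfold10,92,94,94,94,96,90
S27,kfold10,84,92,86,86,88,90
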