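group,n_snps,averaged_cM,cM_per_marker,female_cM,female_cM_per_marker,male_cM,male_cM_per_marker,salmon_chrom,w_name,fm_ratio
Calb01,253,75.96,0.30,91.07,0.36,63.67,0.25,Ssa01,W02,1.43
Calb02,228,83.57,0.37,101.33,0.44,69.58,0.31,Ssa01,W03,1.46
Calb03,220,78.51,0.36,84.40,0.38,87.95,0.40,Ssa21,W32,0.96
Calb04,214,58.45,0.27,66.69,0.31,50.05,0.23,Ssa10,W15,1.33
Calb05,190,66.93,0.35,63.63,0.33,71.66,0.38,Ssa12,W18,0.89
Calb06,187,53.16,0.28,70.69,0.38,37.88,0.20,Ssa13,W20,1.87
Calb07,181,71.53,0.40,68.13,0.38,88.06,0.49,Ssa04,W06,0.77
Calb08,173,52.28,0.30,56.37,0.33,45.30,0.26,Ssa10,W14,1.24
Calb09,170,79.41,0.47,73.03,0.43,91.75,0.54,Ssa07,W10,0.80
Calb10,165,62.43,0.38,60.45,0.37,65.05,0.39,Ssa01,W01,0.93
Calb11,164,65.01,0.40,64.04,0.39,66.05,0.40,Ssa11,W16,0.97
Calb12,164,51.09,0.31,70.15,0.43,30.22,0.18,Ssa22,W33,2.32
Calb13,162,69.34,0.43,71.26,0.44,63.49,0.39,Ssa29,W40,1.12
Calb14,157,65.11,0.41,61.78,0.39,72.14,0.46,Ssa13,W19,0.86
Calb15,156,64.90,0.42,63.19,0.41,71.73,0.46,Ssa16,W24,0.88
Calb16,154,56.17,0.36,55.30,0.36,65.75,0.43,Ssa20,W31,0.84
Calb17,151,65.53,0.43,69.40,0.46,61.63,0.41,Ssa23,W34,1.13
Calb18,149,61.50,0.41,65.22,0.44,62.38,0.42,Ssa09,W11,1.05
Calb19,147,62.15,0.42,68.25,0.46,55.50,0.38,Ssa14,W21,1.23
Calb20,144,66.36,0.46,79.08,0.55,56.52,0.39,Ssa27,W37,1.40
Calb21,143,71.78,0.50,69.37,0.49,83.01,0.58,Ssa25,W36,0.84
Calb22,137,71.12,0.52,74.56,0.54,67.96,0.50,Ssa03,W04,1.10
Calb23,127,64.80,0.51,68.96,0.54,69.78,0.55,Ssa06,W09,0.99
Calb24,127,52.57,0.41,58.54,0.46,54.23,0.43,Ssa15,W22,1.08
Calb25,124,57.74,0.47,61.62,0.50,60.81,0.49,Ssa24,W35,1.01
Calb26,123,64.59,0.53,70.67,0.57,62.12,0.51,Ssa19,W29,1.14
Calb27,118,46.03,0.39,61.06,0.52,30.24,0.26,Ssa18,W27,2.02
Calb28,115,59.05,0.51,63.68,0.55,59.73,0.52,Ssa15,W23,1.07
Calb29,114,62.40,0.55,61.31,0.54,70.58,0.62,Ssa09,W12,0.87
Calb30,112,62.75,0.56,68.12,0.61,63.96,0.57,Ssa05,W08,1.07
Calb31,111,53.35,0.48,63.62,0.57,42.48,0.38,Ssa20,W30,1.50
Calb32,104,56.67,0.54,63.47,0.61,53.94,0.52,Ssa18,W28,1.18
Calb33,97,67.73,0.70,70.46,0.73,66.40,0.68,Ssa09,W13,1.06
Calb34,79,61.12,0.77,71.34,0.90,62.97,0.80,Ssa03,W05,1.13
Calb35,56,36.88,0.66,55.57,0.99,21.14,0.38,Ssa28,W38,2.63
Calb36,45,24.18,0.54,15.92,0.35,30.75,0.68,Ssa17,W26,0.52
Calb37,37,27.48,0.74,34.82,0.94,21.51,0.58,Ssa11,W17,1.62
Calb38,34,11.86,0.35,0.00,0.00,24.01,0.71,Ssa16,W25,0.00
Calb39,32,17.17,0.54,0.00,0.00,33.66,1.05,Ssa04,W07,0.00
Calb40,31,15.20,0.49,23.55,0.76,7.41,0.24,Ssa28,W39,3.18
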