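id,alpha_neutral_pct,log_kow,log_dlipw,ic10_median,ec10_eralpha,ec10_pparg,ec10_ahr,ec_ir15_are,ec10_mmp,ec10_noi,emax_eralpha,emax_pparg,sigma_sr_score
TCBPA,29,6.36,6.10,7.84e-05,3.44e-06,1.55e-05,,,1.48e-05,3.22e-04,33,32,1.83
TBBPA,5,5.91,5.24,9.28e-05,,8.48e-08,,,2.83e-05,,0,52,1.22
TMBPF,95,4.37,4.53,1.27e-05,,3.29e-07,,,,4.28e-06,0,18,1.10
BPPH,99,6.67,6.85,8.02e-06,,5.55e-07,9.54e-06,,1.96e-06,,0,12,1.28
BPG,100,6.01,6.19,7.84e-06,9.02e-07,1.17e-07,,,3.12e-06,,19,22,2.04
BADGE,100,3.62,3.78,3.85e-05,,,,,,3.81e-05,,,0.03
BPP,100,6.09,6.27,1.91e-05,4.78e-07,,,,1.78e-06,,13,,2.00
Pergafast,0.089,4.11,3.27,1.91e-05,,6.71e-07,2.29e-05,,,1.25e-05,,16,1.99
BTUM,0.0007,4.82,3.99,3.10e-05,,2.56e-07,,,,6.48e-05,,47,1.02
BPT,96,3.29,3.42,9.51e-05,7.27e-07,9.61e-07,,,1.83e-05,,80,20,3.00
BPF,99,2.71,2.85,4.09e-04,9.95e-07,,,,1.65e-04,,60,,1.14
BPZ,99,4.64,4.80,5.28e-05,4.43e-08,,8.04e-05,,2.21e-05,3.05e-05,21,,1.13
BzPB,99,3.30,3.45,1.32e-04,3.02e-06,2.04e-06,,1.94e-05,2.44e-05,,53,16,3.40
Bz,71,2.06,2.07,3.73e-04,1.06e-06,,6.20e-05,,,,32,,1.04
BPAP,95,5.06,5.22,3.31e-05,1.94e-07,,,,,5.12e-05,24,,1.05
BPAF,96,4.72,4.87,2.28e-05,2.44e-08,,,,5.32e-06,1.62e-05,40,,1.82
BP-MIBK,100,4.47,4.63,3.26e-05,1.43e-08,,,,1.14e-05,,30,,1.10
BPB,99,3.72,3.87,3.62e-05,1.35e-07,,,,1.64e-05,2.80e-05,24,,1.78
BPA,100,4.25,3.65,7.00e-05,3.70e-07,,2.64e-04,,2.80e-05,5.08e-05,38,,1.54
BPE,98,4.05,4.20,7.91e-05,4.01e-07,,6.19e-05,,3.21e-05,1.14e-04,52,,1.17
BPS-MPE,68,4.28,4.30,1.12e-04,,2.35e-07,,,5.59e-06,2.47e-04,,25,2.01
BPS-MAE,80,2.85,2.91,1.90e-04,1.41e-05,5.57e-07,,,7.85e-05,2.52e-05,28,22,3.59
D8,61,2.87,2.83,3.37e-04,1.12e-05,,,1.22e-03,5.20e-05,1.91e-04,18,,2.12
BPS,39,1.97,1.77,5.61e-04,1.43e-06,,,,1.17e-04,,66,,2.00
"2,4-BPS",43,1.90,1.72,4.63e-04,1.98e-05,,,,5.90e-05,,19,,2.00
t-TMCD,100,1.30,1.43,8.94e-03,3.03e-03,,,,1.85e-02,4.15e-03,,,0.02
r-TMCD,100,1.30,1.43,8.29e-03,1.29e-02,,,,,5.99e-03,,,0.01
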