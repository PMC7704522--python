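subject,rr_normoxia,rr_sem_normoxia,rr_hypoxia,rr_sem_hypoxia,vt_normoxia,vt_sem_normoxia,vt_hypoxia,vt_sem_hypoxia,ve_normoxia,ve_sem_normoxia,ve_hypoxia,ve_sem_hypoxia,delta_spo2,chemoreflex_reported
01,9.53,0.10,13.04,0.08,1.05,0.02,1.33,0.01,9.33,0.12,16.86,0.11,17.30,43.53
02,17.11,0.05,17.95,0.13,0.80,0.00,0.88,0.01,13.64,0.06,15.67,0.15,18.51,11.11
03,14.13,0.11,12.55,0.16,0.87,0.01,1.13,0.02,11.62,0.09,12.48,0.14,16.53,5.25
04,16.30,0.09,16.02,0.09,0.73,0.01,0.83,0.01,11.64,0.05,12.77,0.10,16.40,6.91
05,19.12,0.08,20.26,0.08,0.69,0.01,0.73,0.01,12.53,0.07,14.13,0.08,16.86,9.48
06,19.13,0.08,17.36,0.12,0.73,0.01,0.76,0.01,13.66,0.05,12.50,0.09,15.29,-7.57
07,18.89,0.09,14.09,0.13,0.74,0.01,1.04,0.02,13.17,0.08,13.52,0.20,16.89,2.05
08,18.29,0.07,18.30,0.09,0.62,0.00,0.77,0.00,11.13,0.03,13.64,0.05,19.03,13.20
09,14.15,0.08,13.19,0.08,0.72,0.00,1.07,0.01,10.02,0.06,13.94,0.08,17.74,22.11
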