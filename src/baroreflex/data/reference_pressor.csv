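subject,first_condition,mean_normoxia,sem_normoxia,n_normoxia,mean_hypoxia,sem_hypoxia,n_hypoxia,p_reported,t_reported
01,hypoxia,17.6,1.2,20,21.8,1.4,20,0.026,2.31
02,normoxia,25.7,2.7,20,23.2,2.9,17,0.531,0.633
03,hypoxia,27.8,1.1,20,31.0,2.4,20,0.232,1.214
04,normoxia,19.4,1.7,19,29.7,2.3,18,0.001,3.576
05,normoxia,18.1,1.6,19,24.1,2.2,20,0.033,2.21
06,hypoxia,30.0,1.7,20,26.0,2.0,20,0.1396,1.509
07,normoxia,17.1,1.8,20,13.0,1.4,20,0.069,1.872
08,hypoxia,30.3,1.3,20,22.2,1.1,20,<0.001,4.714
09,hypoxia,19.1,1.2,20,12.5,1.9,20,0.006,2.943
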