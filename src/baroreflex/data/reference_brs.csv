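subject,first_condition,mean_normoxia,sem_normoxia,n_normoxia,mean_hypoxia,sem_hypoxia,n_hypoxia,p_reported,t_reported
01,hypoxia,19.6,2.1,17,18.3,1.4,19,0.603,0.525
02,normoxia,14.9,1.4,16,9.5,1.4,17,0.011,2.689
03,hypoxia,18.9,1.9,18,11.4,1.2,17,0.002,3.307
04,normoxia,14.4,1.2,19,11.1,2.1,17,0.159,1.439
05,normoxia,29.0,2.0,14,19.6,1.9,16,0.002,3.381
06,hypoxia,14.7,1.2,16,10.1,0.9,17,0.017,2.533
07,normoxia,28.6,3.3,16,16.8,2.6,8,0.028,2.35
08,hypoxia,14.4,0.8,20,8.3,0.8,20,<0.001,5.399
09,hypoxia,24.9,1.6,19,21.1,1.8,17,0.122,1.585
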