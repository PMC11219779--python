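name,nominal,ci_low,ci_high,level
k_rep,1.0,0.2,5.0,0.95
k_p53,0.1,0.02,0.5,0.95
d_p53,0.2,0.04,1.0,0.95
k_tx,0.05,0.01,0.25,0.95
d_mRNA,0.2,0.04,1.0,0.95
k_tl,0.5,0.1,2.5,0.95
d_Bax,0.1,0.02,0.5,0.95
k_bind,0.01,0.002,0.05,0.95
k_disp,0.001,0.0002,0.005,0.95
k_act,0.0025,0.0005,0.0125,0.95
d_casp,0.12,0.024,0.6,0.95
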