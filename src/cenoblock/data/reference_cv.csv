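variant_id,gj_ps_per_pf,cv_cm_s
WT,1000,8.0
N1463K,1000,3.0
N1463Y,1000,3.7
M1766R,1000,3.6
WT,2000,14.9
N1463K,2000,11.8
N1463Y,2000,12.4
M1766R,2000,12.4
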