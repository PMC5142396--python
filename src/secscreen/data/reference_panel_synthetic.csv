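sp_id,mean_activity_U_per_mL,sd_activity_U_per_mL
NprE,6.0,0.4
YpjP,2.5,0.3
YwmC,1.2,0.25
AmyE,1.0,0.25
EmptyVector,0.05,0.05
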