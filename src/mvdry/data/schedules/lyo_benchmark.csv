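setpoint_C,ramp_C_per_min,hold_min,vacuum_mTorr
-50,0,30,40
-15,1,1645,40
30,0.05,300,40
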