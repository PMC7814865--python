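setpoint_C,ramp_C_per_min,hold_min,vacuum_mTorr
-40,1,20,500
-35,1,1000,500
0,1,30,200
10,1,10,200
15,1,10,200
25,1,10,200
30,1,420,200
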