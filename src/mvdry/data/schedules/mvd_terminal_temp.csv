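duration_min,n_magnetrons,power_per_magnetron_W,vacuum_lo_mTorr,vacuum_hi_mTorr
190,2,200,50,60
80,2,300,50,60
55,2,450,50,60
65,3,400,50,60
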