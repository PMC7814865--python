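duration_min,n_magnetrons,power_per_magnetron_W,vacuum_lo_mTorr,vacuum_hi_mTorr
30,4,50,50,80
60,4,100,50,80
120,4,200,50,80
90,4,400,50,80
60,4,200,50,80
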