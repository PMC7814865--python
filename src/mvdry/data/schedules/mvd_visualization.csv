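duration_min,n_magnetrons,power_per_magnetron_W,vacuum_lo_mTorr,vacuum_hi_mTorr
60,1,400,50,80
120,2,400,50,80
60,3,400,50,80
60,2,400,50,80
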