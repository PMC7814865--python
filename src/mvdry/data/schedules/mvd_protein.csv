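duration_min,n_magnetrons,power_per_magnetron_W,vacuum_lo_mTorr,vacuum_hi_mTorr
240,2,200,50,60
240,3,200,50,60
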