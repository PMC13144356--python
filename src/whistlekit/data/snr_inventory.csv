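snr_class,n_total,n_repeated
high,206,116
medium,1004,477
low,3718,422
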