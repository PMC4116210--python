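site,n_2010,n_2011,n_2012,n_2013,ccl_mean_cm,ccl_sd_cm
Gulf Shores AL,0,13,10,14,94.4,3.8
St Joseph Peninsula FL,4,0,10,6,,
Eglin AFB FL,0,0,2,0,96.0,6.3
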