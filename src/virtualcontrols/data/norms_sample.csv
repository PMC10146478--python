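# age_range=120,240
percentile,a,b,c
25,7.5e-05,-0.066583333333333328,15.6701
50,-0.00021944444444444444,0.042383333333333334,7.3618
75,0,0,9.5261
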