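bin_low_m,bin_high_m,ciit,msi
0.0,2.5,208,231
2.5,5.0,124,145
5.0,7.5,93,101
7.5,10.0,66,52
10.0,12.5,58,38
12.5,inf,25,7
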