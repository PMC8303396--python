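label,proportion,nnd_mean,nnd_sd
green,0.204,,1.248
red,0.160,,1.548
blue,0.133,,1.729
violet,0.094,,2.292
double,0.409,,0.948
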