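# Apparent maximal sodium-dependent transport rates vmax_Na(app) from Hill
# fits to the sodium-titration columns of the uptake grid, versus the fixed
# aspartate concentration. Values as published; SE from the Hill fits.
asp_uM,vmax_per_min,se_per_min
0.05,3.7,0.1
0.1,8.6,0.1
0.5,28.5,0.15
1,34.9,1.0
5,40.6,1.3
10,51.4,2.7
50,54.6,1.9
100,72.34,10.5
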