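# Initial rates of L-aspartate uptake by purified Glt_Tk in proteoliposomes
# (mixed right-side-out/inside-out orientation). Mean of three biological
# replicates (two technical replicates each); rates in min^-1 per transporter.
# External choline chloride balanced the ionic strength at each [Na+]
# (299, 295, 290, 275, 250, 200, 100, 0 mM for the 1..300 mM rows).
# Cells not determined (1 mM Na+ with [Asp] < 1 uM) are omitted.
na_mM,asp_uM,rate_per_min,sem_per_min,n_rep
1,1,0.03,0.026,3
1,5,0.51,0.3,3
1,10,0.25,0.3,3
1,50,2.85,1.2,3
1,100,10.93,4.4,3
5,0.05,0.05,0.016,3
5,0.1,0.06,0.021,3
5,0.5,0.59,0.1,3
5,1,0.96,0.2,3
5,5,3.62,0.7,3
5,10,6.48,0.9,3
5,50,16.59,2.8,3
5,100,21.62,3.2,3
10,0.05,0.21,0.055,3
10,0.1,0.28,0.1,3
10,0.5,2.16,0.4,3
10,1,3.75,0.6,3
10,5,8.19,1.2,3
10,10,12.60,1.9,3
10,50,25.08,5.0,3
10,100,30.51,4.1,3
25,0.05,0.95,0.2,3
25,0.1,1.46,0.5,3
25,0.5,8.53,1.2,3
25,1,11.56,1.7,3
25,5,19.09,2.0,3
25,10,26.39,3.0,3
25,50,40.58,6.4,3
25,100,43.59,6.9,3
50,0.05,1.88,0.4,3
50,0.1,3.34,1.0,3
50,0.5,16.79,2.6,3
50,1,21.26,2.3,3
50,5,31.28,3.5,3
50,10,39.30,4.9,3
50,50,43.69,8.3,3
50,100,50.21,4.4,3
100,0.05,2.75,0.5,3
100,0.1,4.79,1.5,3
100,0.5,23.46,2.5,3
100,1,30.47,3.3,3
100,5,38.90,3.5,3
100,10,52.16,7.7,3
100,50,53.52,7.9,3
100,100,68.13,3.5,3
200,0.05,3.06,0.6,3
200,0.1,4.83,1.5,3
200,0.5,31.27,6.4,3
200,1,32.55,3.8,3
200,5,37.29,4.0,3
200,10,49.80,9.0,3
200,50,51.90,6.7,3
200,100,65.40,7.5,3
300,0.05,2.93,0.7,3
300,0.1,4.96,1.6,3
300,0.5,27.72,5.3,3
300,1,28.95,4.0,3
300,5,40.12,5.4,3
300,10,46.98,7.9,3
300,50,52.69,8.5,3
300,100,61.77,2.9,3
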