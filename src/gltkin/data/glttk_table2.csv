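# Apparent aspartate-saturation parameters vmax_Asp(app) and K_M_Asp(app)
# from Michaelis-Menten fits to the aspartate-titration rows of the uptake
# grid, at each fixed [Na+]. Values as published; SE from the fits.
na_mM,vmax_per_min,vmax_se,km_uM,km_se
5,29.2,0.58,36,1.9
10,34.8,1.5,16.8,2.4
25,44.7,2.9,5.5,1.5
50,45.5,2.3,1.2,0.3
100,52.1,2.6,0.70,0.16
200,54.2,4.1,0.58,0.23
300,53.7,3.1,0.70,0.22
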