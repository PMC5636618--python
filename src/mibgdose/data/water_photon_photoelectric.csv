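# Photoelectric mass attenuation coefficient of liquid water, transcribed from
# standard published photon cross-section tables; above ~300 keV the
# photoelectric contribution is negligible next to incoherent scattering
# (which this package evaluates analytically from the Klein-Nishina formula).
# columns: energy_kev, mu_pe_cm2_g
energy_kev,mu_pe_cm2_g
10.0,4.742
15.0,1.334
20.0,0.5389
30.0,0.1512
40.0,0.0600
50.0,0.0298
60.0,0.0167
80.0,0.00661
100.0,0.00329
150.0,0.000940
200.0,0.000389
300.0,0.000110
400.0,0.000046
500.0,0.000024
600.0,0.000014
800.0,0.0000064
1000.0,0.0000035
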