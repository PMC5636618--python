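# Mass energy-absorption coefficient of liquid water, transcribed from
# standard published photon attenuation tables. Used only by the deterministic
# chord-length reference model (scripts/make_sphere_reference.py), not by the
# Monte Carlo transport itself.
# columns: energy_kev, mu_en_cm2_g
energy_kev,mu_en_cm2_g
10.0,4.944
15.0,1.374
20.0,0.5503
30.0,0.1557
40.0,0.06947
50.0,0.04223
60.0,0.03190
80.0,0.02597
100.0,0.02546
150.0,0.02764
200.0,0.02967
300.0,0.03192
400.0,0.03279
500.0,0.03299
600.0,0.03284
800.0,0.03206
1000.0,0.03103
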