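# Collision (electronic) mass stopping power of liquid water for electrons,
# transcribed from standard published stopping-power tables; values below
# 10 keV follow a smooth log-log continuation (electrons there have sub-3 um
# residual range and always deposit locally at the scale of this package).
# columns: energy_kev, stopping_mev_cm2_g
energy_kev,stopping_mev_cm2_g
1.0,126.3
1.5,93.0
2.0,74.6
3.0,54.7
4.0,44.2
5.0,37.5
6.0,32.9
8.0,26.4
10.0,22.56
15.0,16.47
20.0,13.17
30.0,9.653
40.0,7.777
50.0,6.603
60.0,5.797
80.0,4.757
100.0,4.115
150.0,3.238
200.0,2.793
300.0,2.355
400.0,2.148
500.0,2.034
600.0,1.963
700.0,1.913
800.0,1.886
1000.0,1.849
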