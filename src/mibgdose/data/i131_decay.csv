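# Iodine-131 decay scheme, transcribed from standard published nuclear decay
# data compilations (MIRD/ICRP-style radionuclide tables).
# half_life_hours: 192.6048
# z_daughter: 54
#
# columns:
#   kind      beta | photon | electron
#   energy_kev  for beta rows: the branch endpoint (maximum) energy;
#               for photon/electron rows: the discrete line energy
#   intensity  probability (beta branch) or expected yield per decay (lines)
#
# Truncation policy: beta branches with intensity >= 0.1% and discrete lines
# with yield >= 0.5% are kept; Auger and low-energy conversion electrons below
# 10 keV are lumped into a single locally-deposited 3.4 keV electron line.
kind,energy_kev,intensity
beta,247.9,0.0208
beta,303.9,0.00651
beta,333.8,0.0723
beta,606.3,0.894
beta,806.9,0.00396
photon,29.46,0.0139
photon,29.78,0.0257
photon,33.60,0.0089
photon,80.185,0.0262
photon,284.305,0.0612
photon,364.489,0.815
photon,636.989,0.0716
photon,722.911,0.0177
electron,3.43,0.0510
electron,45.62,0.0349
electron,74.90,0.0085
electron,329.93,0.0155
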