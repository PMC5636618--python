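"""Physical constants and unit conversion factors used across the package.

All energies are carried in keV, times in hours (biodistribution) or seconds
(transport/DCE), masses in grams, activities in MBq and doses in Gy; every
conversion between these systems goes through the factors below.
"""

# energy
KEV_TO_J = 1.602176634e-16

# electron rest energy
MEC2_KEV = 510.99895

# classical electron radius (cm) and its square
R_E_CM = 2.8179403262e-13
R_E_CM2 = R_E_CM ** 2

# electrons per gram of water
N_E_WATER_PER_G = 3.3428e23

# fine-structure constant
ALPHA_FS = 7.2973525693e-3

# 1 MBq.h expressed in Bq.s (1e6 Bq x 3600 s)
MBQ_H_TO_BQ_S = 3.6e9
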