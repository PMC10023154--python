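"""Unit conventions and conversion constants.

Internal mechanics computations use a self-consistent unit system:
stresses and energy densities in kPa, lengths in micrometres, forces in
millinewtons.  With areas expressed in mm**2 the identity
1 kPa = 1 mN/mm**2 makes force bookkeeping exact.  Pressures cross the
API boundary in mmHg (the unit of the test protocols) and pulse wave
velocities in m/s (SI).
"""

MMHG_TO_KPA = 0.133322
KPA_TO_MMHG = 1.0 / MMHG_TO_KPA

KPA_TO_PA = 1.0e3
MPA_TO_KPA = 1.0e3

UM_TO_M = 1.0e-6
UM2_TO_MM2 = 1.0e-6

#: default blood mass density, kg/m^3
RHO_BLOOD = 1050.0


def mmhg_to_kpa(p):
    return p * MMHG_TO_KPA


def kpa_to_mmhg(p):
    return p * KPA_TO_MMHG
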