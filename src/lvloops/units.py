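"""Unit conversion constants.

Interfaces use clinical units (mm, cm^2, mL, mmHg); all work/force
integrals are evaluated in SI (m, m^2, m^3, Pa, N, J). Conversions are
centralized here so no factor appears twice.
"""

MMHG_TO_PA = 133.322
ML_TO_M3 = 1e-6
MM_TO_M = 1e-3
CM2_TO_M2 = 1e-4
MM2_TO_CM2 = 1e-2
J_TO_MJ = 1e3

#: Myocardial tissue density, g/mL (standard literature value).
MYOCARDIAL_DENSITY = 1.05
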