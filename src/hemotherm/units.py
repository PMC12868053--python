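"""Unit conversion constants.

The package works in strict SI internally (Pa, m3, m3/s, W, K).  Clinical
units (mmHg, mL, mL/min) appear only at I/O boundaries; the exact
conversion constants live here.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

ML_TO_M3 = 1.0e-6
M3_TO_ML = 1.0e6

ML_MIN_TO_M3_S = 1.0e-6 / 60.0
M3_S_TO_ML_MIN = 60.0e6

# Derived composite conversions for RLC elements specified in mmHg-mL units.
R_MMHG_S_ML_TO_SI = MMHG_TO_PA / ML_TO_M3          # Pa s / m3 per (mmHg s / mL)
L_MMHG_S2_ML_TO_SI = MMHG_TO_PA / ML_TO_M3         # Pa s2 / m3 per (mmHg s2 / mL)
C_ML_MMHG_TO_SI = ML_TO_M3 / MMHG_TO_PA            # m3 / Pa per (mL / mmHg)
B_MMHG_S2_ML2_TO_SI = MMHG_TO_PA / ML_TO_M3**2     # Pa s2 / m6 per (mmHg s2 / mL2)
E_MMHG_ML_TO_SI = MMHG_TO_PA / ML_TO_M3            # Pa / m3 per (mmHg / mL)
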