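"""Unit conversion constants.

Interfaces speak mmHg, mL/min, uL and mm (the units of the imaging and
clinical inputs); all physics is SI internally. Conversions are centralized
here so no magic factor appears twice.
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

MM_TO_M = 1e-3
M_TO_MM = 1e3

#: m^3/s -> mL/min  (1 m^3 = 1e6 mL, 1 s = 1/60 min)
M3S_TO_MLMIN = 1e6 * 60.0
MLMIN_TO_M3S = 1.0 / M3S_TO_MLMIN

#: uL -> m^3
UL_TO_M3 = 1e-9
M3_TO_UL = 1e9
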