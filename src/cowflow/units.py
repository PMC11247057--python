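"""Unit conventions and conversion constants.

All geometry is held in cm and all internal solver arithmetic runs in CGS
(cm, g, s, dyn/cm^2).  Constitutive tables are quoted in mixed clinical
units (Pa, mmHg, Pa.s/cm^3), so the conversions below are applied once on
ingest and once on report; nothing in between ever mixes systems.
"""

# 1 Pa = 10 dyn/cm^2
PA_TO_DYN_CM2 = 10.0
# 1 mmHg = 133.322 Pa
MMHG_TO_PA = 133.322
MMHG_TO_DYN_CM2 = MMHG_TO_PA * PA_TO_DYN_CM2  # 1333.22

# Resistances quoted in Pa.s/cm^3 -> dyn.s/cm^5
PA_S_CM3_TO_CGS = PA_TO_DYN_CM2
# Compliances quoted in cm^3/Pa -> cm^5/dyn
CM3_PA_TO_CGS = 1.0 / PA_TO_DYN_CM2
# Wall elasticity coefficient beta quoted in Pa.cm -> dyn/cm
PA_CM_TO_CGS = PA_TO_DYN_CM2


def mmhg_to_dyn(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_DYN_CM2


def dyn_to_mmhg(p_dyn: float) -> float:
    return p_dyn / MMHG_TO_DYN_CM2


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA
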