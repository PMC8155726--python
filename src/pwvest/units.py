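"""Unit conversions between SI and clinical units.

All internal computation is in SI (Pa, m, s, m^3). Published quantities are
exported in clinical units: pressures in mmHg, flows in mL/s, impedances in
mmHg·s/mL, compliances in mL/mmHg.
"""

MMHG_PA = 133.322  # 1 mmHg in Pa
ML_M3 = 1e-6       # 1 mL in m^3

BLOOD_DENSITY = 1050.0  # kg/m^3


def pa_to_mmhg(p):
    return p / MMHG_PA


def mmhg_to_pa(p):
    return p * MMHG_PA


def m3s_to_mls(q):
    return q / ML_M3


def zsi_to_clinical(z):
    """Pa·s/m^3 -> mmHg·s/mL."""
    return z * ML_M3 / MMHG_PA


def zclinical_to_si(z):
    return z * MMHG_PA / ML_M3


def csi_to_clinical(c):
    """m^3/Pa -> mL/mmHg."""
    return c * MMHG_PA / ML_M3


def cclinical_to_si(c):
    return c * ML_M3 / MMHG_PA
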