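"""Unit conventions and conversion constants.

All interfaces exchange pressures in mmHg; resistances, capacitances and
tensions are kept in CGS (dyn, cm, s).  The single conversion constant below
is the only place where the two systems meet:

* resistance  R : dyn s / cm^5
* capacitance C : cm^5 / dyn
* flow        Q : cm^3 / s,  Q = dP[mmHg] * MMHG_TO_DYN_CM2 / R
* tension     T : dyn / cm
"""

MMHG_TO_DYN_CM2: float = 1333.22
"""1 mmHg expressed in dyn/cm^2."""

UM_TO_CM: float = 1e-4
"""1 micrometer in cm."""


def mmhg_to_cgs(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG_TO_DYN_CM2


def cgs_to_mmhg(p_dyn_cm2: float) -> float:
    """Convert a pressure from dyn/cm^2 to mmHg."""
    return p_dyn_cm2 / MMHG_TO_DYN_CM2
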