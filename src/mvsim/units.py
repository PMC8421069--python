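"""Unit conventions used throughout the package.

Internally everything is expressed in micrometre / millisecond / Pascal units:

* length      -- um
* time        -- ms
* volume      -- um^3  (1 nl = 1e6 um^3)
* flow rate   -- um^3/ms
* pressure    -- Pa (mmHg accepted at the interfaces, 1 mmHg = 133.322 Pa)
* viscosity   -- Pa*s
"""

MMHG_TO_PA = 133.322
NL_TO_UM3 = 1.0e6

#: conventional dynamic plasma viscosity [Pa*s]
MU_PLASMA = 1.2e-3

#: default red blood cell volume [um^3] (mouse)
RBC_VOLUME = 49.0


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def nl_to_um3(v_nl: float) -> float:
    return v_nl * NL_TO_UM3


def um3_to_nl(v_um3: float) -> float:
    return v_um3 / NL_TO_UM3
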