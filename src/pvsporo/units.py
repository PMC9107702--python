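"""Unit helpers.

All internal quantities are SI (m, s, kg, Pa).  Geometry specifications are
written in micrometres and pressures in mmHg because that is how the
physiological literature reports them; convert at the boundary.
"""

MMHG = 133.322  # Pa per mmHg
UM = 1e-6       # m per micrometre


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG


def um_to_m(x_um: float) -> float:
    return x_um * UM
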