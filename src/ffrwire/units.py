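"""Unit conversions.

Everything inside the package is strict SI (Pa, m, s, kg). Millimetres of
mercury appear only at I/O boundaries.
"""

MMHG_PA: float = 133.322  # 1 mmHg in Pa


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_PA
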