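"""Unit conversions between laboratory units and internal SI.

All quantities are stored internally in SI (m, s, m^2 s^-1, m^3 s^-1).
Microfluidics conventions mix micrometres, millimetres per second,
microlitres per minute and cm^2 s^-1; these helpers convert at the API
boundary so a single canonical system is used everywhere else.
"""

M3_S_PER_UL_MIN = 1e-9 / 60.0


def ul_min_to_m3_s(q: float) -> float:
    """Volumetric flow rate, microlitres/minute -> m^3/s."""
    return q * M3_S_PER_UL_MIN


def m3_s_to_ul_min(q: float) -> float:
    return q / M3_S_PER_UL_MIN


def um_to_m(x: float) -> float:
    return x * 1e-6


def m_to_um(x: float) -> float:
    return x * 1e6


def mm_s_to_m_s(v: float) -> float:
    return v * 1e-3


def m_s_to_mm_s(v: float) -> float:
    return v * 1e3


def cm_to_m(x: float) -> float:
    return x * 1e-2


def cm2_s_to_m2_s(d: float) -> float:
    """Diffusivity, cm^2/s -> m^2/s."""
    return d * 1e-4


def m2_s_to_cm2_s(d: float) -> float:
    return d * 1e4
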