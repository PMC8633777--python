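"""Unit conventions.

Everything internal is expressed in millimetres, seconds and kilopascals.
This makes hydraulic resistance (kPa·s·mm⁻³) numerically identical to
kg·mm⁻⁴·s⁻¹, since 1 kPa = 1 kg·mm⁻¹·s⁻², and makes the perfusion
coefficient's customary unit kg⁻¹·mm·s numerically identical to
kPa⁻¹·s⁻¹.  Pressures cross the I/O boundary (config files, reports) in
mmHg and are converted exactly once.
"""

MMHG_TO_KPA: float = 0.1333224
KPA_TO_MMHG: float = 1.0 / MMHG_TO_KPA


def mmhg_to_kpa(p: float) -> float:
    return p * MMHG_TO_KPA


def kpa_to_mmhg(p: float) -> float:
    return p * KPA_TO_MMHG
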