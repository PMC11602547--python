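"""Physical constants and small electrochemical helpers.

Unit conventions used throughout the package:

=============  =========
quantity       unit
=============  =========
potential      mV
current        pA
conductance    nS
resistance     MΩ
capacitance    pF
time (sweeps)  ms
time (epochs)  s
concentration  mM
temperature    K
=============  =========

These are mutually consistent: nS·mV = pA and pF/nS = ms, so membrane
equations can be written without conversion factors; the one exception is
resistance, where 1/R[MΩ] = 1000/R nS.
"""

GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1
FARADAY = 96485.33212331  # C mol^-1

#: default recording temperature (room temperature), K
ROOM_TEMPERATURE_K = 295.0

#: pipette K+ concentration of the standard internal solution, mM
#: (130 K-gluconate + 2 K-Lucifer-yellow)
DEFAULT_K_IN_MM = 132.0

#: bath K+ concentration of HEPES-buffered aCSF, mM
DEFAULT_K_OUT_MM = 2.5


def thermal_voltage_mv(temperature_k: float = ROOM_TEMPERATURE_K) -> float:
    """RT/F in millivolts (~25.4 mV at room temperature)."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k} K")
    return GAS_CONSTANT * temperature_k / FARADAY * 1000.0


def megaohm_to_nanosiemens(r_mohm: float) -> float:
    """Convert a resistance in MΩ to a conductance in nS."""
    if r_mohm <= 0:
        raise ValueError(f"resistance must be positive, got {r_mohm} MΩ")
    return 1000.0 / r_mohm
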