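"""Physical constants used throughout the package.

Internal unit discipline: SI throughout (g, Bq, m^3, K, kPa, hours for
sampling clocks, days for radioactive chase periods). Nanogram- and
milligram-scale quantities appear only at the reporting boundary.
"""

#: Disintegrations per minute in one becquerel (definitional).
DPM_PER_BQ = 60.0

#: Universal gas constant, J K^-1 mol^-1.
GAS_CONSTANT = 8.314

#: Standard atomic masses (IUPAC conventional), g mol^-1.
ATOMIC_MASS_C = 12.011
ATOMIC_MASS_O = 15.999

#: Molar mass of CO2, g mol^-1, as conventionally rounded.
CO2_MOLAR_MASS = 44.01

#: Mass fraction of carbon in CO2 (12.011 / 44.01, conventionally rounded).
CARBON_MASS_FRACTION_CO2 = 0.27292

#: Molar mass of phosphorus, mg mmol^-1 (equivalently g mol^-1).
P_MOLAR_MASS = 30.974

#: Half-life of 33P, days.
P33_HALF_LIFE_DAYS = 25.38

#: Natural abundance of 15N, atom percent. Used as the background when no
#: unlabelled control plants are available.
N15_NATURAL_ABUNDANCE_ATOM_PCT = 0.3663
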