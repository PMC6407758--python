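"""Physical constants (CODATA 2018, SI units).

k_B and h are exact by the 2019 SI redefinition; the molar gas constant is
their exact product with Avogadro's number. Stated to at least nine
significant digits so that Eyring rate constants are bit-reproducible.
"""

BOLTZMANN = 1.380649e-23
"""Boltzmann constant k_B, J/K (exact)."""

PLANCK = 6.62607015e-34
"""Planck constant h, J*s (exact)."""

AVOGADRO = 6.02214076e23
"""Avogadro constant N_A, 1/mol (exact)."""

GAS_CONSTANT = BOLTZMANN * AVOGADRO
"""Molar gas constant R = N_A * k_B = 8.31446262 J/(mol*K)."""

STANDARD_TEMPERATURE = 298.15
"""Default temperature for barrier -> rate conversion, K."""
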