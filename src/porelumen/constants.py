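"""Package-wide unit conventions and physical constants.

Internal units are fixed everywhere: length in angstrom (A), time in
picoseconds (ps), charge in elementary charges (e), temperature in kelvin.
Electrical quantities are converted only at reporting boundaries:
voltage in millivolts (mV), current in picoamperes (pA), conductivity in
mS/cm.
"""

# Boltzmann constant in eV/K; with charges in e and fields in V/A the
# thermal energy k_B*T carries units of e*V, so q*E*D/(k_B*T) is in A/ps.
KB_EV = 8.617333262e-5

#: 1 e/ps expressed in pA (e = 1.602176634e-19 C, 1 ps = 1e-12 s).
E_PER_PS_TO_PA = 1.602176634e5

#: 1 e/(V*A*ps) expressed in mS/cm (= 1.602176634e3 S/m * 10).
SIGMA_INTERNAL_TO_MS_PER_CM = 1.602176634e4

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 298.0
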