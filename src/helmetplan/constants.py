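"""Physical constants (SI units)."""

C0 = 299792458.0           # speed of light in vacuum, m/s
EPS0 = 8.8541878128e-12    # vacuum permittivity, F/m
MU0 = 1.25663706212e-6     # vacuum permeability, H/m
ETA0 = 376.730313668       # free-space impedance, Ohm

# Pennes perfusion-sink blood properties: rho_b * c_b, J/m^3/K, and arterial
# temperature, degC.
RHO_CP_BLOOD = 3.6e6
T_BLOOD = 37.0
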