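"""Physical constants (SI) and package-wide defaults.

Units policy: concentrations in mol/L (M) at API boundaries, potentials in V,
depths in Angstrom, temperatures in K.  Conversions to SI happen inside the
electrostatics and transport routines.
"""

FARADAY = 96485.33212  # C mol^-1
GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F m^-1
AVOGADRO = 6.02214076e23  # mol^-1
KW = 1.0e-14  # ionic product of water, 25 C

T_DEFAULT = 298.15  # K
EPS_R_WATER = 78.4  # relative permittivity of water, 25 C

# Solubility product of BaSO4, aqueous, 25 C.  The titration-medium value is
# not known precisely; every report that uses it echoes it as an assumption.
KSP_BASO4 = 1.08e-10  # M^2

SHEAR_PLANE_DEFAULT = 2.0e-10  # m (2 Angstrom), configurable

# Vesicle geometry defaults (extruded POPC LUVs)
VESICLE_DIAMETER = 200e-9  # m
AREA_PER_LIPID = 0.68e-18  # m^2 (0.68 nm^2 per POPC)
BILAYER_THICKNESS = 3.7e-9  # m

# Probe / buffer defaults
HEPES_PKA = 7.48  # 25 C
HPTS_PKA = 7.2  # apparent, intravesicular


def thermal_voltage(temperature: float = T_DEFAULT) -> float:
    """RT/F in volts (25.693 mV at 298.15 K)."""
    return GAS_CONSTANT * temperature / FARADAY
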