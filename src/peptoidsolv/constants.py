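"""Physical constants used throughout the package.

All solvent properties refer to 25 degC liquids; energies are kJ/mol,
lengths Angstrom unless a function says otherwise (the umbrella-sampling
module works in nm, matching the conventions of biased-MD tooling).
"""

#: Molecular weight of tetrahydrofuran (THF), g/mol.
MW_THF = 72.11
#: Molecular weight of water, g/mol.
MW_WATER = 18.015
#: Density of liquid THF at 25 degC, g/mL.
RHO_THF = 0.889
#: Density of liquid water at 25 degC, g/mL.
RHO_WATER = 0.997
#: Molarity of pure water, mol per litre (1000 * RHO_WATER / MW_WATER).
WATER_MOLARITY = 1000.0 * RHO_WATER / MW_WATER
#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621
#: amu/A^3 -> g/cm^3.
AMU_PER_A3_TO_G_PER_CM3 = 1.66053906892
#: Idealized backbone heavy-atom bond length, Angstrom.
BACKBONE_BOND = 1.5


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature in K."""
    return KB * temperature
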