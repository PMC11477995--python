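"""Physical constants, unit conversions, and the atomic-mass table.

CODATA 2018 exact values are used for statistical thermodynamics.  The
ideal-gas constant used in the pKa conversion defaults to the rounded
literal 8.314 J mol^-1 K^-1 (see :mod:`aqpka.engine`), which differs from
k_B * N_A by < 0.006%; both are exposed here.
"""

from __future__ import annotations

# --- CODATA 2018 (SI, exact by definition) ---
H_PLANCK = 6.62607015e-34  # J s
K_BOLTZMANN = 1.380649e-23  # J K^-1
C_LIGHT_CM = 2.99792458e10  # cm s^-1 (wavenumbers are cm^-1 throughout)
N_AVOGADRO = 6.02214076e23  # mol^-1
R_GAS = K_BOLTZMANN * N_AVOGADRO  # 8.31446261815324 J mol^-1 K^-1

# Rounded literal used when converting deprotonation free energies to pKa.
R_PKA = 8.314  # J mol^-1 K^-1
LOG10_LITERAL = 2.303  # rounded ln(10); exact ln(10) selectable in Constants

T_STANDARD = 298.15  # K
P_STANDARD = 101325.0  # Pa (1 atm gas standard state)

# Aqueous free energy of the proton at 298.15 K (experimental).
DG_PROTON_SOL = -1131.44e3  # J mol^-1

# Gas (1 atm) -> solution (1 M) standard-state term: R T ln(24.46) at 298.15 K.
GAS_TO_1M_VOLUME_RATIO = 24.46

AMU_TO_KG = 1.66053906660e-27
ANGSTROM_TO_M = 1e-10

HARTREE_TO_J_PER_MOL = 2625.4996394799e3
KCAL_TO_J = 4184.0
KJ_TO_J = 1000.0

#: Accepted energy unit tags (case-insensitive aliases) -> factor to J mol^-1.
ENERGY_UNIT_FACTORS = {
    "hartree": HARTREE_TO_J_PER_MOL,
    "au": HARTREE_TO_J_PER_MOL,
    "kj/mol": KJ_TO_J,
    "kj_mol": KJ_TO_J,
    "kcal/mol": KCAL_TO_J,
    "kcal_mol": KCAL_TO_J,
    "j/mol": 1.0,
    "j_mol": 1.0,
}

#: Standard atomic weights (amu), IUPAC 2021 conventional values.  Covers the
#: elements of the benchmark compounds plus common light/noble elements.
ATOMIC_MASSES = {
    "H": 1.008,
    "He": 4.002602,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "K": 39.0983,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.90447,
}


class UnitError(ValueError):
    """An energy value carries an unrecognized unit tag."""


def energy_to_joules_per_mol(value: float, unit: str) -> float:
    """Convert ``value`` with unit tag ``unit`` to J mol^-1."""
    try:
        return value * ENERGY_UNIT_FACTORS[unit.strip().lower()]
    except KeyError:
        raise UnitError(
            f"unknown energy unit {unit!r}; accepted: "
            f"{sorted(ENERGY_UNIT_FACTORS)}"
        ) from None


def energy_from_joules_per_mol(value_j_mol: float, unit: str) -> float:
    """Convert an internal J mol^-1 value back to ``unit``."""
    try:
        return value_j_mol / ENERGY_UNIT_FACTORS[unit.strip().lower()]
    except KeyError:
        raise UnitError(
            f"unknown energy unit {unit!r}; accepted: "
            f"{sorted(ENERGY_UNIT_FACTORS)}"
        ) from None
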