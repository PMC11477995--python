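"""Ideal-gas statistical thermochemistry with quasi-RRHO low-frequency fixes.

Gibbs free energies are assembled from the electronic energy plus ZPE,
thermal corrections, and entropy under three harmonic treatments:

* **C0** — plain rigid-rotor harmonic oscillator (RRHO).
* **C1** — Truhlar quasi-RRHO: every frequency below a threshold nu0
  (100 cm^-1 by default) is raised to nu0 before the harmonic formulas are
  applied.  This caps the low-frequency entropy divergence.
* **C2** — Grimme quasi-RRHO: per-mode entropy is a damped interpolation
  between the harmonic-oscillator entropy and the entropy of a free rotor
  with an effective moment of inertia, with a Head-Gordon style weight
  w(nu) = 1 / (1 + (nu0/nu)^4).

ZPE always uses the raw (optionally scaled) frequencies under every scheme:
frequency raising is an entropy/thermal-energy fix, and letting it move the
ZPE would shift deprotonation energetics nonphysically.  Under C1 the raised
frequencies are used for both vibrational entropy and vibrational thermal
energy by default (``c1_raise_thermal``); C2 modifies entropy only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    AMU_TO_KG,
    C_LIGHT_CM,
    GAS_TO_1M_VOLUME_RATIO,
    H_PLANCK,
    K_BOLTZMANN,
    N_AVOGADRO,
    P_STANDARD,
    R_GAS,
    T_STANDARD,
)
from .errors import ThermoInputError
from .species import RotationalData, SpeciesRecord, principal_moments


@dataclass
class ThermoOptions:
    """Knobs of the statistical-thermodynamic model.

    temperature : K, > 0 (default 298.15)
    pressure : Pa, > 0 (default 101325, the 1 atm gas standard state)
    scheme : "C0" | "C1" | "C2"
    zpe_scale : empirical ZPE frequency scale factor, 0 < s <= 1.2
    nu0 : low-frequency threshold for C1 raising / C2 interpolation (cm^-1)
    b_av : averaged rotational moment in the C2 free-rotor limit (kg m^2)
    standard_state_correction : "off" | "gas1atm_to_1M" — optional
        R T ln(24.46) term moving each species from gas 1 atm to 1 M
    c1_raise_thermal : apply C1 raising to vibrational thermal energy as
        well as entropy (the raising rule names no specific term)
    """

    temperature: float = T_STANDARD
    pressure: float = P_STANDARD
    scheme: str = "C0"
    zpe_scale: float = 1.0
    nu0: float = 100.0
    b_av: float = 1.0e-44
    standard_state_correction: str = "off"
    c1_raise_thermal: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ThermoInputError("temperature must be > 0 K")
        if self.pressure <= 0:
            raise ThermoInputError("pressure must be > 0 Pa")
        if not 0 < self.zpe_scale <= 1.2:
            raise ThermoInputError("zpe_scale must be in (0, 1.2]")
        if self.nu0 <= 0:
            raise ThermoInputError("nu0 must be > 0 cm^-1")
        if self.scheme not in ("C0", "C1", "C2"):
            raise ThermoInputError(f"unknown correction scheme {self.scheme!r}")
        if self.standard_state_correction not in ("off", "gas1atm_to_1M"):
            raise ThermoInputError(
                f"unknown standard_state_correction "
                f"{self.standard_state_correction!r}"
            )


@dataclass
class ThermoResult:
    """Decomposed thermochemistry, all energies J mol^-1, entropies J mol^-1 K^-1.

    Satisfies exactly::

        enthalpy_correction = zpe + u_trans + u_rot + u_vib + R T
        gibbs_correction    = enthalpy_correction
                              - T (s_trans + s_rot + s_vib + s_elec)
        gibbs_total         = electronic_energy + gibbs_correction
                              [+ R T ln(24.46) if standard-state shift on]
    """

    zpe: float
    u_trans: float
    u_rot: float
    u_vib: float
    s_trans: float
    s_rot: float
    s_vib: float
    s_elec: float
    enthalpy_correction: float
    gibbs_correction: float
    gibbs_total: float
    scheme: str
    temperature: float = T_STANDARD
    components: dict = field(default_factory=dict)

    @property
    def entropy_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib + self.s_elec


# ---------------------------------------------------------------------------
# Per-degree-of-freedom terms
# ---------------------------------------------------------------------------

def vibrational_mode_terms(nu: float, T: float) -> tuple[float, float, float]:
    """Harmonic-oscillator ZPE, thermal energy, and entropy of one mode.

    With the vibrational temperature Theta = h c nu / k_B:

        zpe = (1/2) N_A h c nu
        u   = R Theta / (exp(Theta/T) - 1)
        s   = R [ (Theta/T) / (exp(Theta/T) - 1) - ln(1 - exp(-Theta/T)) ]
    """
    if nu <= 0:
        raise ThermoInputError(f"non-positive wavenumber {nu} cm^-1")
    if T <= 0:
        raise ThermoInputError("temperature must be > 0 K")
    theta = H_PLANCK * C_LIGHT_CM * nu / K_BOLTZMANN
    zpe = 0.5 * N_AVOGADRO * H_PLANCK * C_LIGHT_CM * nu
    x = theta / T
    if x > 700:  # exp overflow guard; stiff-mode limit is exactly 0
        return zpe, 0.0, 0.0
    em1 = math.expm1(x)
    u = R_GAS * theta / em1
    s = R_GAS * (x / em1 - math.log1p(-math.exp(-x)))
    return zpe, u, s


def translational_terms(mass_kg: float, T: float, P: float) -> tuple[float, float]:
    """Translational thermal energy (3/2 R T) and Sackur–Tetrode entropy.

    ``mass_kg`` is the mass of one molecule in kg.
    """
    if mass_kg <= 0:
        raise ThermoInputError("molecular mass must be > 0")
    u = 1.5 * R_GAS * T
    q = (2 * math.pi * mass_kg * K_BOLTZMANN * T / H_PLANCK**2) ** 1.5 * (
        K_BOLTZMANN * T / P
    )
    s = R_GAS * (math.log(q) + 2.5)
    return u, s


def rotational_terms(rot: RotationalData, T: float) -> tuple[float, float]:
    """Rigid-rotor thermal energy and entropy.

    monatomic: (0, 0).  linear: q = T / (sigma Theta_rot), u = R T,
    s = R (ln q + 1).  nonlinear: q = (sqrt(pi)/sigma) sqrt(T^3 /
    (Theta_A Theta_B Theta_C)), u = 3/2 R T, s = R (ln q + 3/2).
    """
    if rot.linearity == "monatomic":
        return 0.0, 0.0
    sigma = rot.symmetry_number
    if rot.linearity == "linear":
        i_rot = rot.principal_moments[2]  # the two nonzero moments are equal
        if i_rot <= 0:
            raise ThermoInputError("linear rotor with zero moment of inertia")
        theta = H_PLANCK**2 / (8 * math.pi**2 * i_rot * K_BOLTZMANN)
        q = T / (sigma * theta)
        return R_GAS * T, R_GAS * (math.log(q) + 1.0)
    if any(m <= 0 for m in rot.principal_moments):
        raise ThermoInputError(
            "nonlinear rotor requires three positive principal moments"
        )
    thetas = [
        H_PLANCK**2 / (8 * math.pi**2 * m * K_BOLTZMANN)
        for m in rot.principal_moments
    ]
    q = (math.sqrt(math.pi) / sigma) * math.sqrt(
        T**3 / (thetas[0] * thetas[1] * thetas[2])
    )
    return 1.5 * R_GAS * T, R_GAS * (math.log(q) + 1.5)


def raised_frequencies(freqs: list[float], nu0: float = 100.0) -> list[float]:
    """Truhlar raising: element-wise max(nu, nu0); order preserved."""
    if any(nu <= 0 for nu in freqs):
        raise ThermoInputError("raised_frequencies requires all-positive input")
    return [max(nu, nu0) for nu in freqs]


def free_rotor_mode_entropy(nu: float, T: float, b_av: float = 1.0e-44) -> float:
    """Entropy of a one-dimensional free rotor standing in for mode ``nu``.

    The effective moment mu = h / (8 pi^2 c nu) is damped against the
    averaged molecular moment b_av: mu' = mu b_av / (mu + b_av), and

        S_FR = R [ 1/2 + ln( sqrt(8 pi^3 mu' k_B T / h^2) ) ]
    """
    if nu <= 0:
        raise ThermoInputError(f"non-positive wavenumber {nu} cm^-1")
    mu = H_PLANCK / (8 * math.pi**2 * C_LIGHT_CM * nu)
    mu_eff = mu * b_av / (mu + b_av)
    arg = 8 * math.pi**3 * mu_eff * K_BOLTZMANN * T / H_PLANCK**2
    return R_GAS * (0.5 + math.log(math.sqrt(arg)))


def grimme_mode_entropy(
    nu: float, T: float, nu0: float = 100.0, b_av: float = 1.0e-44
) -> float:
    """C2 per-mode entropy: damped harmonic/free-rotor interpolation.

    w = 1 / (1 + (nu0/nu)^4); result = w S_HO + (1 - w) S_FR.
    """
    if nu <= 0:
        raise ThermoInputError(f"non-positive wavenumber {nu} cm^-1")
    w = 1.0 / (1.0 + (nu0 / nu) ** 4)
    _, _, s_ho = vibrational_mode_terms(nu, T)
    s_fr = free_rotor_mode_entropy(nu, T, b_av)
    return w * s_ho + (1.0 - w) * s_fr


# ---------------------------------------------------------------------------
# Full Gibbs free energy
# ---------------------------------------------------------------------------

def _vibrational_totals(
    freqs: list[float], options: ThermoOptions
) -> tuple[float, float, float]:
    """(zpe, u_vib, s_vib) under the selected correction scheme."""
    T = options.temperature
    zpe = sum(
        vibrational_mode_terms(nu * options.zpe_scale, T)[0] for nu in freqs
    )
    if options.scheme == "C0":
        work = freqs
        u = sum(vibrational_mode_terms(nu, T)[1] for nu in work)
        s = sum(vibrational_mode_terms(nu, T)[2] for nu in work)
    elif options.scheme == "C1":
        work = raised_frequencies(freqs, options.nu0)
        u_src = work if options.c1_raise_thermal else freqs
        u = sum(vibrational_mode_terms(nu, T)[1] for nu in u_src)
        s = sum(vibrational_mode_terms(nu, T)[2] for nu in work)
    else:  # C2
        u = sum(vibrational_mode_terms(nu, T)[1] for nu in freqs)
        s = sum(grimme_mode_entropy(nu, T, options.nu0, options.b_av) for nu in freqs)
    return zpe, u, s


def gibbs_free_energy(
    record: SpeciesRecord, options: ThermoOptions | None = None
) -> ThermoResult:
    """Assemble G = E_elec + ZPE + thermal corrections + R T - T S.

    The record must carry an electronic energy plus harmonic frequencies
    (none for a single atom) and a geometry from which rotational constants
    can be derived.
    """
    options = options or ThermoOptions()
    T = options.temperature

    if record.electronic_energy is None:
        raise ThermoInputError(f"{record.label}: electronic_energy required")
    if not record.atoms:
        raise ThermoInputError(f"{record.label}: geometry required")
    if record.n_atoms > 1 and not record.frequencies:
        raise ThermoInputError(
            f"{record.label}: polyatomic species needs harmonic frequencies"
        )
    if any(nu <= 0 for nu in record.frequencies):
        raise ThermoInputError(
            f"{record.label}: imaginary modes present; strip them first"
        )

    mass_kg = record.total_mass_amu() * AMU_TO_KG
    u_trans, s_trans = translational_terms(mass_kg, T, options.pressure)

    rot = principal_moments(record.atoms, record.symmetry_number, record.linearity)
    u_rot, s_rot = rotational_terms(rot, T)

    if record.frequencies:
        zpe, u_vib, s_vib = _vibrational_totals(record.frequencies, options)
    else:
        zpe = u_vib = s_vib = 0.0

    s_elec = R_GAS * math.log(record.multiplicity)

    enthalpy_correction = zpe + u_trans + u_rot + u_vib + R_GAS * T
    s_total = s_trans + s_rot + s_vib + s_elec
    gibbs_correction = enthalpy_correction - T * s_total
    gibbs_total = record.electronic_energy + gibbs_correction
    ss_term = 0.0
    if options.standard_state_correction == "gas1atm_to_1M":
        ss_term = R_GAS * T * math.log(GAS_TO_1M_VOLUME_RATIO)
        gibbs_total += ss_term

    return ThermoResult(
        zpe=zpe,
        u_trans=u_trans,
        u_rot=u_rot,
        u_vib=u_vib,
        s_trans=s_trans,
        s_rot=s_rot,
        s_vib=s_vib,
        s_elec=s_elec,
        enthalpy_correction=enthalpy_correction,
        gibbs_correction=gibbs_correction,
        gibbs_total=gibbs_total,
        scheme=options.scheme,
        temperature=T,
        components={
            "electronic_energy": record.electronic_energy,
            "standard_state_term": ss_term,
            "rotor_class": rot.linearity,
            "symmetry_number": rot.symmetry_number,
        },
    )
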