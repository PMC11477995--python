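"""Deprotonation free energies and pKa via direct and thermodynamic-cycle routes.

For the acid/base pair HA / A (the conjugate base carries one fewer
elementary charge), the aqueous deprotonation free energy is

    direct:    dG_deprot(sol) = G_A(sol) - G_HA(sol) + dG_H+(sol)
    indirect:  dG_deprot(sol) = [G_A(gas) - G_HA(gas)]
                                + [dG_A(sol) - dG_HA(sol)] + dG_H+(sol)

where dG_H+(sol) is the experimental aqueous proton free energy
(-1131.44 kJ mol^-1 at 298.15 K) and the indirect route closes the
thermodynamic cycle G(sol) = G(gas) + dG(sol).  Then

    pKa = dG_deprot(sol) / (2.303 R T)

with R = 8.314 J mol^-1 K^-1 and T = 298.15 K by default.  The rounded
literal 2.303 reproduces the conversion as printed; exact ln(10) is
selectable and differs by < 0.02%.

Solvation free energies for the indirect route are tagged by protocol
P1–P6.  Protocols encode which electronic-structure method supplied the
solvation energy for each charge class (with a special rule for sulfonate-
substituted species and explicit-water requirements for P4–P6); this module
only resolves and validates those labels — it never runs a calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import DG_PROTON_SOL, LOG10_LITERAL, R_PKA, T_STANDARD
from .errors import PairModelError, ProtocolError, ThermoInputError
from .species import PROTOCOL_LABELS, SpeciesRecord
from .thermo import ThermoOptions, gibbs_free_energy


@dataclass
class Constants:
    """Conversion constants of the pKa equation; overrides are recorded in
    every result's component ledger.

    ``log_conversion`` defaults to the printed literal 2.303; pass
    ``math.log(10)`` for the exact value.
    """

    R: float = R_PKA  # J mol^-1 K^-1
    T_default: float = T_STANDARD  # K
    dG_proton_sol: float = DG_PROTON_SOL  # J mol^-1
    log_conversion: float = LOG10_LITERAL

    def denominator(self, T: float | None = None) -> float:
        return self.log_conversion * self.R * (self.T_default if T is None else T)


@dataclass
class ConjugatePairModel:
    """An acid/base conjugate pair with matched explicit-water models.

    ``water_motif_label`` records the hydrogen-bond motifs of the two
    cluster models, e.g. ``"HO-HO"`` (base motif - acid motif).
    """

    acid: SpeciesRecord
    base: SpeciesRecord
    approach: str = "direct"  # "direct" | "indirect"
    correction: str = "C0"  # C0 | C1 | C2
    protocol: str | None = None  # P1..P6, indirect only
    water_motif_label: str = ""
    allow_water_imbalance: bool = False

    def validate(self) -> None:
        if self.base.charge != self.acid.charge - 1:
            raise PairModelError(
                f"conjugate base charge must be acid charge - 1 "
                f"(acid {self.acid.label}: {self.acid.charge:+d}, "
                f"base {self.base.label}: {self.base.charge:+d})"
            )
        if (
            self.base.explicit_waters != self.acid.explicit_waters
            and not self.allow_water_imbalance
        ):
            raise PairModelError(
                f"explicit-water mismatch: acid has {self.acid.explicit_waters}, "
                f"base has {self.base.explicit_waters}; balanced cluster models "
                "are required (set allow_water_imbalance and supply a water "
                "reference record to override)"
            )
        if self.approach not in ("direct", "indirect"):
            raise PairModelError(f"unknown approach {self.approach!r}")
        if self.approach == "indirect" and self.protocol is None:
            raise PairModelError("indirect approach requires a protocol (P1..P6)")


@dataclass
class PkaResult:
    """dG_deprot(sol), pKa, and a per-term component ledger for audit."""

    dG_deprot_sol: float  # J mol^-1
    pka: float
    components: dict = field(default_factory=dict)
    approach: str = "direct"
    correction: str = "C0"
    protocol: str | None = None


def pka_from_free_energy(
    dG: float, T: float | None = None, constants: Constants | None = None
) -> float:
    """pKa = dG_deprot(sol) / (log_conversion R T); linear in dG."""
    constants = constants or Constants()
    return dG / constants.denominator(T)


def solution_free_energy_indirect(G_gas: float, dG_solv: float) -> float:
    """Close the thermodynamic cycle: G(sol) = G(gas) + dG(sol)."""
    return G_gas + dG_solv


# ---------------------------------------------------------------------------
# Protocol resolution (metadata/validation only)
# ---------------------------------------------------------------------------

_SULFONATE_TOKENS = ("SO3", "SO₃")

_P2_BY_CLASS = {
    "neutral": "M052X/6-31G(d)",
    "cation": "M052X/6-31+G(d,p)",
    "anion": "HF/6-31G(d)",
}

_EXPLICIT_METHODS = {
    "P4": "M062X/6-31G(d)",
    "P5": "M052X/cc-pVTZ",
    "P6": "ωb97xd/6-31+g(d,p)",
}

IODINE_BASIS_NOTE = " [I: ma-def2QZVP basis]"


def _charge_class(species: SpeciesRecord) -> str:
    if species.charge > 0:
        return "cation"
    if species.charge < 0:
        return "anion"
    return "neutral"


def _has_sulfonate(species: SpeciesRecord) -> bool:
    label = species.substituent.upper().replace("₃", "3").replace("⁻", "-")
    return any(tok in label for tok in _SULFONATE_TOKENS)


def resolve_protocol_method(protocol: str, species: SpeciesRecord) -> str:
    """Return the electronic-structure method label a protocol assigns to a
    species, for bookkeeping and validation.

    P1 applies one method to every species.  P2 selects by charge class,
    except that sulfonate-substituted species always take the anion method.
    P3 is the radical adaptation of P2: radical cations keep the neutral-class
    method while neutral radicals (and the sulfonate radical cation) take the
    anion-class method.  P4–P6 are explicit-water protocols with a single
    method each and require at least one explicit water in the model.
    Iodine-containing species are annotated with the heavy-atom basis.
    """
    if protocol not in PROTOCOL_LABELS:
        raise ProtocolError(f"unknown protocol {protocol!r}; expected P1..P6")

    sulfonate = _has_sulfonate(species)
    cls = _charge_class(species)

    if protocol == "P1":
        method = "M052X/6-31G(d)"
    elif protocol == "P2":
        method = _P2_BY_CLASS["anion"] if sulfonate else _P2_BY_CLASS[cls]
    elif protocol == "P3":
        if sulfonate:
            method = "HF/6-31G(d)"
        elif cls == "cation" and species.is_radical:
            method = "M052X/6-31G(d)"
        else:
            method = "HF/6-31G(d)"
    else:  # P4..P6 explicit-water protocols
        if species.explicit_waters < 1:
            raise ProtocolError(
                f"{protocol} is an explicit-water protocol but species "
                f"{species.label!r} has explicit_waters=0"
            )
        method = _EXPLICIT_METHODS[protocol]

    if species.contains_element("I") or species.substituent.strip().upper() == "I":
        method += IODINE_BASIS_NOTE
    return method


# ---------------------------------------------------------------------------
# Free-energy assembly
# ---------------------------------------------------------------------------

def _solution_g(species: SpeciesRecord, options: ThermoOptions) -> tuple[float, str]:
    """Solution-phase G: precomputed if present, else thermochemistry on the
    (solvated-calculation) electronic energy."""
    if species.free_energy_sol is not None:
        return species.free_energy_sol, "precomputed"
    try:
        return gibbs_free_energy(species, options).gibbs_total, options.scheme
    except ThermoInputError as exc:
        raise ThermoInputError(
            f"{species.label}: no solution free energy available ({exc})"
        ) from exc


def _gas_g(species: SpeciesRecord, options: ThermoOptions) -> tuple[float, str]:
    if species.free_energy_gas is not None:
        return species.free_energy_gas, "precomputed"
    try:
        return gibbs_free_energy(species, options).gibbs_total, options.scheme
    except ThermoInputError as exc:
        raise ThermoInputError(
            f"{species.label}: no gas-phase free energy available ({exc})"
        ) from exc


def _water_imbalance_term(
    pair: ConjugatePairModel,
    water_reference: SpeciesRecord | None,
    options: ThermoOptions,
    phase: str,
) -> float:
    """n_acid - n_base copies of G(H2O) added to the base side so that the
    reaction HA·(n_a)H2O -> A·(n_b)H2O + (n_a - n_b) H2O + H+ balances."""
    n_extra = pair.acid.explicit_waters - pair.base.explicit_waters
    if n_extra == 0:
        return 0.0
    if water_reference is None:
        raise PairModelError(
            "water-imbalance override requires a water reference record"
        )
    g_w = (
        _solution_g(water_reference, options)[0]
        if phase == "sol"
        else _gas_g(water_reference, options)[0]
    )
    return n_extra * g_w


def deprotonation_direct(
    pair: ConjugatePairModel,
    options: ThermoOptions | None = None,
    constants: Constants | None = None,
    water_reference: SpeciesRecord | None = None,
) -> PkaResult:
    """Direct route: dG = G_A(sol) - G_HA(sol) + dG_H+(sol).

    Both species must carry solution-phase free energies — precomputed, or
    derivable as electronic energy from a solvated calculation plus the
    thermochemical correction under ``options.scheme``.
    """
    options = options or ThermoOptions()
    constants = constants or Constants()
    pair.validate()

    g_acid, src_a = _solution_g(pair.acid, options)
    g_base, src_b = _solution_g(pair.base, options)
    water_term = _water_imbalance_term(pair, water_reference, options, "sol")

    dG = g_base - g_acid + constants.dG_proton_sol + water_term
    pka = pka_from_free_energy(dG, options.temperature, constants)
    return PkaResult(
        dG_deprot_sol=dG,
        pka=pka,
        components={
            "G_HA_sol": g_acid,
            "G_A_sol": g_base,
            "dG_proton_sol": constants.dG_proton_sol,
            "water_balance_term": water_term,
            "acid_free_energy_source": src_a,
            "base_free_energy_source": src_b,
            "temperature": options.temperature,
            "R": constants.R,
            "log_conversion": constants.log_conversion,
        },
        approach="direct",
        correction=options.scheme,
        protocol=None,
    )


def deprotonation_indirect(
    pair: ConjugatePairModel,
    options: ThermoOptions | None = None,
    constants: Constants | None = None,
    water_reference: SpeciesRecord | None = None,
) -> PkaResult:
    """Thermodynamic-cycle route:
    dG = [G_A(gas) - G_HA(gas)] + [dG_A(sol) - dG_HA(sol)] + dG_H+(sol).

    Solvation free energies are looked up under ``pair.protocol`` on both
    species; the protocol's method rules are validated against each species.
    """
    options = options or ThermoOptions()
    constants = constants or Constants()
    if pair.protocol is None:
        raise PairModelError("indirect approach requires a protocol (P1..P6)")
    pair.validate()

    methods = {}
    for species in (pair.acid, pair.base):
        methods[species.label] = resolve_protocol_method(pair.protocol, species)
        if pair.protocol not in species.solvation_energies:
            raise ProtocolError(
                f"species {species.label!r} has no solvation energy for "
                f"protocol {pair.protocol}"
            )

    g_acid_gas, src_a = _gas_g(pair.acid, options)
    g_base_gas, src_b = _gas_g(pair.base, options)
    dg_solv_acid = pair.acid.solvation_energies[pair.protocol]
    dg_solv_base = pair.base.solvation_energies[pair.protocol]
    water_term = _water_imbalance_term(pair, water_reference, options, "gas")

    dG_gas = g_base_gas - g_acid_gas + water_term
    ddG_sol = dg_solv_base - dg_solv_acid
    dG = dG_gas + ddG_sol + constants.dG_proton_sol
    pka = pka_from_free_energy(dG, options.temperature, constants)
    return PkaResult(
        dG_deprot_sol=dG,
        pka=pka,
        components={
            "G_HA_gas": g_acid_gas,
            "G_A_gas": g_base_gas,
            "dG_gas": dG_gas,
            "dG_solv_HA": dg_solv_acid,
            "dG_solv_A": dg_solv_base,
            "ddG_sol": ddG_sol,
            "dG_proton_sol": constants.dG_proton_sol,
            "water_balance_term": water_term,
            "protocol_methods": methods,
            "acid_free_energy_source": src_a,
            "base_free_energy_source": src_b,
            "temperature": options.temperature,
            "R": constants.R,
            "log_conversion": constants.log_conversion,
        },
        approach="indirect",
        correction=options.scheme,
        protocol=pair.protocol,
    )


def compute_pka(
    pair: ConjugatePairModel,
    options: ThermoOptions | None = None,
    constants: Constants | None = None,
    water_reference: SpeciesRecord | None = None,
) -> PkaResult:
    """Dispatch on ``pair.approach``."""
    if pair.approach == "indirect":
        return deprotonation_indirect(pair, options, constants, water_reference)
    return deprotonation_direct(pair, options, constants, water_reference)
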