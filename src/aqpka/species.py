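"""Species records, XYZ geometry I/O, and rotational data.

A :class:`SpeciesRecord` bundles everything a single chemical species
contributes to a pKa calculation: electronic energy, harmonic frequencies,
Cartesian geometry, charge/multiplicity, the explicit-water bookkeeping of
the cluster model (count and hydrogen-bond motif label such as ``HO``,
``NH``, ``2HO``, ``HOA90``), and optional precomputed free energies or
per-protocol solvation free energies.

Records are serialized as JSON with explicit unit tags on every energy;
internally all energies are held in J mol^-1.  The package never runs a
quantum-chemistry calculation itself — records are populated from upstream
QC outputs (an adapter producing the documented JSON schema suffices) or
from the synthetic-fixture generator.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    AMU_TO_KG,
    ANGSTROM_TO_M,
    ATOMIC_MASSES,
    energy_from_joules_per_mol,
    energy_to_joules_per_mol,
)
from .errors import ElementError, GeometryError, SchemaError, SpeciesValidationError

#: molecule is linear if the smallest principal moment is below this
#: fraction of the largest (robust to float noise on true linear rotors)
LINEARITY_RTOL = 1e-6

PROTOCOL_LABELS = ("P1", "P2", "P3", "P4", "P5", "P6")


@dataclass
class Atom:
    """One atom: element symbol, mass (amu) and Cartesian position (Å)."""

    element: str
    x: float
    y: float
    z: float
    mass: float | None = None

    def __post_init__(self) -> None:
        symbol = self.element.strip()
        if symbol.capitalize() in ATOMIC_MASSES:
            self.element = symbol.capitalize()
        else:
            raise ElementError(f"unknown element symbol {self.element!r}")
        if self.mass is None:
            self.mass = ATOMIC_MASSES[self.element]
        if self.mass <= 0:
            raise GeometryError(f"non-positive mass {self.mass} for {self.element}")


@dataclass(frozen=True)
class RotationalData:
    """Principal moments of inertia (kg m^2, ascending) and rotor class."""

    principal_moments: tuple[float, float, float]
    linearity: str  # "monatomic" | "linear" | "nonlinear"
    symmetry_number: int = 1


@dataclass
class SpeciesRecord:
    label: str
    charge: int = 0
    multiplicity: int = 1
    is_radical: bool = False
    substituent: str = ""
    role: str = ""  # "protonated" | "deprotonated" | ""
    atoms: list[Atom] = field(default_factory=list)
    frequencies: list[float] = field(default_factory=list)  # cm^-1
    electronic_energy: float | None = None  # J mol^-1
    free_energy_gas: float | None = None  # J mol^-1
    free_energy_sol: float | None = None  # J mol^-1
    solvation_energies: dict[str, float] = field(default_factory=dict)  # J mol^-1
    explicit_waters: int = 0
    water_motif: str = ""
    symmetry_number: int = 1
    linearity: str = "auto"  # "auto" | "linear" | "nonlinear"
    energy_unit: str = "j/mol"  # unit tag the record was read with

    # -- derived helpers -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def total_mass_amu(self) -> float:
        if not self.atoms:
            raise GeometryError(f"{self.label}: no atoms, mass undefined")
        return float(sum(a.mass for a in self.atoms))

    def expected_mode_count(self) -> int | None:
        """3N-6 (nonlinear), 3N-5 (linear), 0 (single atom); None if unknown."""
        n = self.n_atoms
        if n == 0:
            return None
        if n == 1:
            return 0
        rot = principal_moments(self.atoms, self.symmetry_number, self.linearity)
        return 3 * n - 5 if rot.linearity == "linear" else 3 * n - 6

    def contains_element(self, symbol: str) -> bool:
        return any(a.element == symbol for a in self.atoms)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def read_xyz(path) -> list[Atom]:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` rows)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GeometryError(f"{path}: empty XYZ file")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise GeometryError(f"{path}: first line must be the atom count") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != declared:
        raise GeometryError(
            f"{path}: header declares {declared} atoms but {len(body)} listed"
        )
    atoms = []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"{path}: malformed atom line {ln!r}")
        atoms.append(Atom(parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
    return atoms


def write_xyz(atoms: list[Atom], path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(atoms)}\n{comment}\n")
        for a in atoms:
            fh.write(f"{a.element} {a.x:.10f} {a.y:.10f} {a.z:.10f}\n")


def principal_moments(
    atoms: list[Atom],
    symmetry_number: int = 1,
    linearity: str = "auto",
) -> RotationalData:
    """Principal moments of inertia about the center of mass, in kg m^2.

    The inertia tensor is diagonalized and eigenvalues are returned in
    ascending order.  Linearity is classified by comparing the smallest
    moment to ``LINEARITY_RTOL`` times the largest unless the caller
    declares it explicitly.
    """
    if not atoms:
        raise GeometryError("empty atom list")
    if len(atoms) == 1:
        return RotationalData((0.0, 0.0, 0.0), "monatomic", symmetry_number)

    masses = np.array([a.mass for a in atoms])  # amu
    coords = np.array([[a.x, a.y, a.z] for a in atoms])  # Å
    com = masses @ coords / masses.sum()
    r = coords - com
    # inertia tensor in amu Å^2
    tensor = np.zeros((3, 3))
    r2 = (r**2).sum(axis=1)
    for k in range(3):
        tensor[k, k] = (masses * (r2 - r[:, k] ** 2)).sum()
    for i in range(3):
        for j in range(i + 1, 3):
            tensor[i, j] = tensor[j, i] = -(masses * r[:, i] * r[:, j]).sum()
    eigvals = np.linalg.eigvalsh(tensor)
    eigvals = np.clip(eigvals, 0.0, None) * AMU_TO_KG * ANGSTROM_TO_M**2

    if linearity == "auto":
        is_linear = eigvals[0] < LINEARITY_RTOL * eigvals[2]
    elif linearity in ("linear", "nonlinear"):
        is_linear = linearity == "linear"
    else:
        raise GeometryError(f"unknown linearity declaration {linearity!r}")
    return RotationalData(
        tuple(float(v) for v in eigvals),
        "linear" if is_linear else "nonlinear",
        symmetry_number,
    )


# ---------------------------------------------------------------------------
# JSON species records
# ---------------------------------------------------------------------------

#: Documented JSON schema for species records (informal JSON-Schema style).
SPECIES_SCHEMA = {
    "type": "object",
    "required": ["label", "charge", "multiplicity"],
    "properties": {
        "label": {"type": "string"},
        "substituent": {"type": "string"},
        "role": {"enum": ["protonated", "deprotonated", ""]},
        "charge": {"type": "integer"},
        "multiplicity": {"type": "integer", "minimum": 1},
        "is_radical": {"type": "boolean"},
        "atoms": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["element", "x", "y", "z"],
                "properties": {
                    "element": {"type": "string"},
                    "x": {"type": "number"},
                    "y": {"type": "number"},
                    "z": {"type": "number"},
                    "mass": {"type": "number", "exclusiveMinimum": 0},
                },
            },
        },
        "frequencies": {"type": "array", "items": {"type": "number"}},
        "electronic_energy": {"$ref": "#/$defs/energy"},
        "free_energy_gas": {"$ref": "#/$defs/energy"},
        "free_energy_sol": {"$ref": "#/$defs/energy"},
        "solvation_energies": {
            "type": "object",
            "propertyNames": {"enum": list(PROTOCOL_LABELS)},
            "additionalProperties": {"$ref": "#/$defs/energy"},
        },
        "explicit_waters": {"type": "integer", "minimum": 0},
        "water_motif": {"type": "string"},
        "symmetry_number": {"type": "integer", "minimum": 1},
        "linearity": {"enum": ["auto", "linear", "nonlinear"]},
    },
    "$defs": {
        "energy": {
            "type": "object",
            "required": ["value", "unit"],
            "properties": {
                "value": {"type": "number"},
                "unit": {
                    "enum": ["hartree", "au", "kj/mol", "kcal/mol", "j/mol"]
                },
            },
        }
    },
}


def species_schema() -> dict:
    """Return (a copy of) the species-record JSON schema."""
    return json.loads(json.dumps(SPECIES_SCHEMA))


def _parse_energy(obj, field_name: str) -> tuple[float, str]:
    if not isinstance(obj, dict) or "value" not in obj or "unit" not in obj:
        raise SchemaError(
            f"field {field_name!r} must be an object with 'value' and 'unit'"
        )
    return energy_to_joules_per_mol(float(obj["value"]), str(obj["unit"])), str(
        obj["unit"]
    )


def validate_species(record: SpeciesRecord, allow_imaginary: str = "error") -> SpeciesRecord:
    """Validate invariants; returns the (possibly imaginary-mode-stripped) record.

    Hard failures raise :class:`SpeciesValidationError`; soft inconsistencies
    (radical-flag/multiplicity mismatch, unexpected mode counts) only warn,
    since upstream QC conventions vary.
    """
    if record.multiplicity < 1:
        raise SpeciesValidationError(f"{record.label}: multiplicity must be >= 1")
    if record.symmetry_number < 1:
        raise SpeciesValidationError(f"{record.label}: symmetry_number must be >= 1")
    if record.explicit_waters < 0:
        raise SpeciesValidationError(f"{record.label}: explicit_waters must be >= 0")

    if record.is_radical != (record.multiplicity > 1):
        warnings.warn(
            f"{record.label}: is_radical={record.is_radical} but "
            f"multiplicity={record.multiplicity}; open-shell species in this "
            "benchmark are doublets",
            stacklevel=2,
        )

    imaginary = [nu for nu in record.frequencies if nu <= 0]
    if imaginary:
        if allow_imaginary == "drop":
            warnings.warn(
                f"{record.label}: dropping {len(imaginary)} imaginary mode(s): "
                f"{imaginary}",
                stacklevel=2,
            )
            record = replace(
                record, frequencies=[nu for nu in record.frequencies if nu > 0]
            )
        else:
            raise SpeciesValidationError(
                f"{record.label}: imaginary mode(s) {imaginary}; species must be "
                "an optimized minimum (pass allow_imaginary='drop' to strip them)"
            )

    if record.atoms and record.frequencies:
        expected = record.expected_mode_count()
        if expected is not None and len(record.frequencies) != expected:
            warnings.warn(
                f"{record.label}: {len(record.frequencies)} real frequencies but "
                f"{expected} expected for this geometry",
                stacklevel=2,
            )

    has_thermo_inputs = record.electronic_energy is not None and (
        record.frequencies or record.n_atoms == 1
    )
    has_precomputed = (
        record.free_energy_gas is not None or record.free_energy_sol is not None
    )
    if not has_thermo_inputs and not has_precomputed:
        if record.electronic_energy is None:
            raise SpeciesValidationError(
                f"{record.label}: record supplies neither electronic_energy+"
                "frequencies nor a precomputed free energy"
            )
    return record


def species_from_dict(data: dict, allow_imaginary: str = "error") -> SpeciesRecord:
    """Build and validate a SpeciesRecord from a parsed JSON object."""
    if not isinstance(data, dict):
        raise SchemaError("species record must be a JSON object")
    for req in ("label", "charge", "multiplicity"):
        if req not in data:
            raise SchemaError(f"missing required field {req!r}")

    atoms = []
    for i, a in enumerate(data.get("atoms", [])):
        for req in ("element", "x", "y", "z"):
            if req not in a:
                raise SchemaError(f"atoms[{i}]: missing required field {req!r}")
        atoms.append(
            Atom(a["element"], float(a["x"]), float(a["y"]), float(a["z"]),
                 a.get("mass"))
        )

    unit_tag = "j/mol"
    e_elec = None
    if data.get("electronic_energy") is not None:
        e_elec, unit_tag = _parse_energy(data["electronic_energy"], "electronic_energy")
    g_gas = g_sol = None
    if data.get("free_energy_gas") is not None:
        g_gas, unit_tag = _parse_energy(data["free_energy_gas"], "free_energy_gas")
    if data.get("free_energy_sol") is not None:
        g_sol, unit_tag = _parse_energy(data["free_energy_sol"], "free_energy_sol")

    solv = {}
    for proto, obj in (data.get("solvation_energies") or {}).items():
        if proto not in PROTOCOL_LABELS:
            raise SchemaError(f"unknown protocol key {proto!r} in solvation_energies")
        solv[proto], _ = _parse_energy(obj, f"solvation_energies[{proto}]")

    record = SpeciesRecord(
        label=str(data["label"]),
        substituent=str(data.get("substituent", "")),
        role=str(data.get("role", "")),
        charge=int(data["charge"]),
        multiplicity=int(data["multiplicity"]),
        is_radical=bool(data.get("is_radical", False)),
        atoms=atoms,
        frequencies=[float(v) for v in data.get("frequencies", [])],
        electronic_energy=e_elec,
        free_energy_gas=g_gas,
        free_energy_sol=g_sol,
        solvation_energies=solv,
        explicit_waters=int(data.get("explicit_waters", 0)),
        water_motif=str(data.get("water_motif", "")),
        symmetry_number=int(data.get("symmetry_number", 1)),
        linearity=str(data.get("linearity", "auto")),
        energy_unit=unit_tag,
    )
    return validate_species(record, allow_imaginary=allow_imaginary)


def species_to_dict(record: SpeciesRecord) -> dict:
    """Serialize to the JSON schema, converting energies back to the record's
    original unit tag."""
    unit = record.energy_unit

    def _energy(value):
        if value is None:
            return None
        return {"value": energy_from_joules_per_mol(value, unit), "unit": unit}

    data = {
        "label": record.label,
        "substituent": record.substituent,
        "role": record.role,
        "charge": record.charge,
        "multiplicity": record.multiplicity,
        "is_radical": record.is_radical,
        "atoms": [
            {"element": a.element, "x": a.x, "y": a.y, "z": a.z, "mass": a.mass}
            for a in record.atoms
        ],
        "frequencies": list(record.frequencies),
        "explicit_waters": record.explicit_waters,
        "water_motif": record.water_motif,
        "symmetry_number": record.symmetry_number,
        "linearity": record.linearity,
    }
    if record.electronic_energy is not None:
        data["electronic_energy"] = _energy(record.electronic_energy)
    if record.free_energy_gas is not None:
        data["free_energy_gas"] = _energy(record.free_energy_gas)
    if record.free_energy_sol is not None:
        data["free_energy_sol"] = _energy(record.free_energy_sol)
    if record.solvation_energies:
        data["solvation_energies"] = {
            proto: _energy(v) for proto, v in sorted(record.solvation_energies.items())
        }
    return data


def read_species_record(path, allow_imaginary: str = "error") -> SpeciesRecord:
    """Read and validate a species record from a JSON file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    return species_from_dict(data, allow_imaginary=allow_imaginary)


def write_species_record(record: SpeciesRecord, path) -> None:
    """Write a species record as JSON; round-trips through
    :func:`read_species_record` within float round-off."""
    with open(path, "w") as fh:
        json.dump(species_to_dict(record), fh, indent=2)
        fh.write("\n")


def records_close(a: SpeciesRecord, b: SpeciesRecord, rtol: float = 1e-12) -> bool:
    """Field-for-field equality of two records within float round-off."""

    def close(x, y):
        if x is None or y is None:
            return x is y
        return math.isclose(x, y, rel_tol=rtol, abs_tol=1e-9)

    return (
        a.label == b.label
        and a.substituent == b.substituent
        and a.role == b.role
        and a.charge == b.charge
        and a.multiplicity == b.multiplicity
        and a.is_radical == b.is_radical
        and a.explicit_waters == b.explicit_waters
        and a.water_motif == b.water_motif
        and a.symmetry_number == b.symmetry_number
        and a.linearity == b.linearity
        and len(a.atoms) == len(b.atoms)
        and all(
            p.element == q.element
            and close(p.x, q.x) and close(p.y, q.y) and close(p.z, q.z)
            and close(p.mass, q.mass)
            for p, q in zip(a.atoms, b.atoms)
        )
        and len(a.frequencies) == len(b.frequencies)
        and all(close(p, q) for p, q in zip(a.frequencies, b.frequencies))
        and close(a.electronic_energy, b.electronic_energy)
        and close(a.free_energy_gas, b.free_energy_gas)
        and close(a.free_energy_sol, b.free_energy_sol)
        and set(a.solvation_energies) == set(b.solvation_energies)
        and all(
            close(a.solvation_energies[k], b.solvation_energies[k])
            for k in a.solvation_energies
        )
    )
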