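"""Synthetic species records, conjugate pairs, and benchmark sets.

Every pipeline stage is testable without a quantum-chemistry run: the
generator emits physically plausible species records (random non-colinear
geometries, positive harmonic spectra with a controlled number of
low-frequency modes, electronic energies in the range of medium-sized
organics), conjugate pairs whose ground-truth pKa is known exactly by
construction, and noisy benchmark sets whose realized RMSE is computed by
independent summation.

The pair generator back-solves a single linear unknown — the conjugate
base's electronic energy — so that the full thermochemistry + deprotonation
pipeline returns the requested pKa, and simultaneously emits a consistent
thermodynamic-cycle decomposition (gas free energies plus per-protocol
solvation energies satisfying G(sol) = G(gas) + dG(sol)), making the
direct/indirect cycle identity testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmark import load_experimental_table
from .constants import HARTREE_TO_J_PER_MOL
from .engine import Constants, ConjugatePairModel
from .errors import FixtureSpecError
from .species import PROTOCOL_LABELS, Atom, SpeciesRecord, validate_species
from .thermo import ThermoOptions, gibbs_free_energy

_ELEMENTS = ("C", "N", "O", "H")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic species record.

    ``n_low_modes`` of the 3N-6 (3N-5 linear) modes are drawn below
    100 cm^-1, the regime where the harmonic-correction schemes differ;
    the rest are drawn from ``freq_range`` (floored at 100 cm^-1).
    """

    seed: int
    n_atoms: int = 8
    freq_range: tuple[float, float] = (200.0, 3500.0)
    n_low_modes: int = 0
    charge: int = 0
    multiplicity: int = 1
    explicit_waters: int = 0
    label: str = ""
    substituent: str = "H"
    role: str = ""

    def n_modes(self) -> int:
        if self.n_atoms < 1:
            raise FixtureSpecError("n_atoms must be >= 1")
        if self.n_atoms == 1:
            return 0
        if self.n_atoms == 2:
            return 1
        return 3 * self.n_atoms - 6

    def validate(self) -> None:
        n = self.n_modes()
        if self.n_low_modes < 0 or self.n_low_modes > n:
            raise FixtureSpecError(
                f"n_low_modes={self.n_low_modes} impossible for "
                f"{self.n_atoms} atoms ({n} modes)"
            )
        if self.freq_range[0] <= 0 or self.freq_range[1] < self.freq_range[0]:
            raise FixtureSpecError(f"bad freq_range {self.freq_range}")


def _random_geometry(rng: np.random.Generator, n_atoms: int) -> list[Atom]:
    """Random coordinates in a ~4 Å box; resampled until non-colinear for
    N >= 3 so the species is a well-defined nonlinear rotor."""
    while True:
        coords = rng.uniform(-2.0, 2.0, size=(n_atoms, 3))
        elements = [
            _ELEMENTS[i] for i in rng.integers(0, len(_ELEMENTS), size=n_atoms)
        ]
        if n_atoms < 3:
            break
        centered = coords - coords.mean(axis=0)
        if np.linalg.matrix_rank(np.round(centered, 6)) >= 2:
            break
    return [Atom(el, *xyz) for el, xyz in zip(elements, coords)]


def generate_species(spec: FixtureSpec) -> SpeciesRecord:
    """Deterministic (per seed) synthetic species record passing validation."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    atoms = _random_geometry(rng, spec.n_atoms)

    n_modes = spec.n_modes()
    n_regular = n_modes - spec.n_low_modes
    low = np.sort(rng.uniform(5.0, 99.0, size=spec.n_low_modes))
    lo, hi = spec.freq_range
    regular = np.sort(rng.uniform(max(lo, 100.5), max(hi, 101.0), size=n_regular))
    freqs = [float(v) for v in np.concatenate([low, regular])]

    e_elec = float(rng.uniform(-400.0, -100.0)) * HARTREE_TO_J_PER_MOL

    record = SpeciesRecord(
        label=spec.label or f"synthetic-{spec.seed}",
        substituent=spec.substituent,
        role=spec.role,
        charge=spec.charge,
        multiplicity=spec.multiplicity,
        is_radical=spec.multiplicity > 1,
        atoms=atoms,
        frequencies=freqs,
        electronic_energy=e_elec,
        explicit_waters=spec.explicit_waters,
        water_motif="HO" if spec.explicit_waters else "",
        energy_unit="hartree",
    )
    return validate_species(record)


def generate_pair_with_known_pka(
    seed: int,
    target_pka: float,
    options: ThermoOptions | None = None,
    constants: Constants | None = None,
    protocol: str = "P6",
) -> ConjugatePairModel:
    """Conjugate pair whose pipeline pKa equals ``target_pka`` by construction.

    The acid is a radical cation (charge +1, doublet) with one explicit
    water, the base the matching neutral radical.  After computing both
    species' thermochemistry under ``options``, the base electronic energy is
    back-solved from

        G_A(sol) = dG_target - dG_H+(sol) + G_HA(sol),
        dG_target = target_pka * log_conversion * R * T.

    Both records also carry gas free energies and per-protocol solvation
    energies consistent with the cycle G(sol) = G(gas) + dG(sol), so the
    direct and indirect routes agree on the same pair.
    """
    if not np.isfinite(target_pka):
        raise FixtureSpecError("target pKa must be finite")
    options = options or ThermoOptions()
    constants = constants or Constants()
    rng = np.random.default_rng(seed)

    acid = generate_species(
        FixtureSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_atoms=7,
            n_low_modes=2,
            charge=1,
            multiplicity=2,
            explicit_waters=1,
            label=f"pair{seed}-acid",
            role="protonated",
        )
    )
    base = generate_species(
        FixtureSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_atoms=6,
            n_low_modes=2,
            charge=0,
            multiplicity=2,
            explicit_waters=1,
            label=f"pair{seed}-base",
            role="deprotonated",
        )
    )

    g_acid_sol = gibbs_free_energy(acid, options).gibbs_total
    dg_target = target_pka * constants.denominator(options.temperature)
    g_base_sol_needed = dg_target - constants.dG_proton_sol + g_acid_sol
    base_correction = (
        gibbs_free_energy(base, options).gibbs_total - base.electronic_energy
    )
    base.electronic_energy = g_base_sol_needed - base_correction

    # consistent thermodynamic-cycle decomposition (typical aqueous
    # solvation magnitudes: strong for the cation, weak for the neutral)
    dg_solv_acid = float(rng.uniform(-280e3, -240e3))
    dg_solv_base = float(rng.uniform(-40e3, -10e3))
    for species, dg_solv in ((acid, dg_solv_acid), (base, dg_solv_base)):
        g_sol = gibbs_free_energy(species, options).gibbs_total
        species.free_energy_gas = g_sol - dg_solv
        species.solvation_energies = {p: dg_solv for p in PROTOCOL_LABELS}

    return ConjugatePairModel(
        acid=acid,
        base=base,
        approach="direct",
        correction=options.scheme,
        protocol=protocol,
        water_motif_label="HO-HO",
    )


def generate_benchmark_set(
    seed: int, sigma: float
) -> tuple[dict[tuple[str, str], float], float]:
    """Calculated pKa values = experimental averages + N(0, sigma) noise.

    Returns the results mapping and the realized RMSE computed by plain
    independent summation (generator bookkeeping, not the benchmark module).
    """
    if sigma < 0:
        raise FixtureSpecError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    results: dict[tuple[str, str], float] = {}
    sq_sum = 0.0
    n = 0
    for entry in load_experimental_table():
        noise = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
        results[(entry.substituent, entry.system)] = entry.averaged + noise
        sq_sum += noise * noise
        n += 1
    return results, (sq_sum / n) ** 0.5


def generate_noise_vectors(
    seed: int, sigma: float, n: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Large paired (calc, exp) vectors with N(0, sigma) deviations, plus the
    realized RMSE by independent summation; for convergence checks."""
    if sigma < 0:
        raise FixtureSpecError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    exp = rng.uniform(-2.0, 14.0, size=n)
    noise = rng.normal(0.0, sigma, size=n)
    calc = exp + noise
    realized = float(np.sqrt((noise**2).sum() / n))
    return calc, exp, realized


__all__ = [
    "FixtureSpec",
    "generate_species",
    "generate_pair_with_known_pka",
    "generate_benchmark_set",
    "generate_noise_vectors",
]
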