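# aqpka

Aqueous pKa prediction from quantum-chemistry outputs, built around the
deprotonation chemistry of para-substituted aniline radical cations
(R-PhNH₂•⁺ → R-PhNH• + H⁺) and anilinium ions (R-PhNH₃⁺ → R-PhNH₂ + H⁺).
It is aimed at computational and environmental chemists who already run
electronic-structure calculations (optimized geometries, harmonic
frequencies, implicit/explicit-solvent energies) and need the
post-processing half of a pKa workflow: statistical thermochemistry,
thermodynamic-cycle bookkeeping, and benchmark statistics. The package
never launches a QC calculation itself.

## The model

For a conjugate pair HA / A in water,

```
pKa = ΔG_deprot(sol) / (2.303 R T),            R = 8.314 J mol⁻¹ K⁻¹, T = 298.15 K

direct:    ΔG_deprot(sol) = G_A(sol) − G_HA(sol) + ΔG_H⁺(sol)
indirect:  ΔG_deprot(sol) = [G_A(gas) − G_HA(gas)] + [ΔG_A(sol) − ΔG_HA(sol)] + ΔG_H⁺(sol)
```

with the experimental aqueous proton free energy
ΔG_H⁺(sol) = −1131.44 kJ mol⁻¹. Free energies are assembled from electronic
energies by ideal-gas statistical thermochemistry under three harmonic
treatments: **C0** (rigid-rotor harmonic oscillator), **C1** (Truhlar
quasi-RRHO: frequencies below 100 cm⁻¹ raised to 100 cm⁻¹), and **C2**
(Grimme quasi-RRHO: per-mode harmonic/free-rotor entropy interpolation).
Explicit-water cluster models are tracked by count and hydrogen-bond motif
(HO, NH, 2HO, HOA90, …), and solvation energies for the indirect route are
tagged by protocol P1–P6 recording which method produced them (by charge
class, radical character, and a sulfonate special case). Calculated values
are scored against an embedded experimental dataset (10 substituents × 2
systems) with per-compound ΔpKa, RMSE, RMSE_aver ± RMSE_std, and
calculated-vs-experimental regression (slope, intercept, r²). See
`docs/methods.md` for the full model description.

## Worked example

Species records are JSON files with explicit unit tags (schema via
`aqpka.species_schema()`). With a solvated free energy of −1500 kJ mol⁻¹
for the radical-cation model and −330 kJ mol⁻¹ for its conjugate base
(one explicit water each, HO motifs):

```
$ pka compute --pair demo/pair.json
{
  "acid": "H-PhNH2 radical cation + H2O",
  "base": "H-PhNH radical + H2O",
  "components": {
    "G_A_sol": -330000.0,
    "G_HA_sol": -1500000.0,
    "dG_proton_sol": -1131440.0,
    "R": 8.314,
    "log_conversion": 2.303,
    "temperature": 298.15,
    ...
  },
  "dG_deprot_sol_J_mol": 38560.0,
  "pKa": 6.7545785016521664,
  ...
}
```

Reading the output: ΔG_deprot(sol) = −330 − (−1500) − 1131.44 =
38.56 kJ mol⁻¹, and 38560 / (2.303 × 8.314 × 298.15) gives pKa ≈ 6.75 — a
moderately acidic radical cation, plausible for the aniline family whose
literature values span roughly 4–12. The `components` block is a complete
audit ledger: the entries always sum to `dG_deprot_sol_J_mol`.

The same machinery is available as a library:

```python
from aqpka import ThermoOptions, deprotonation_direct, generate_pair_with_known_pka

options = ThermoOptions(scheme="C1")           # Truhlar quasi-RRHO
pair = generate_pair_with_known_pka(seed=3, target_pka=7.30, options=options)
print(deprotonation_direct(pair, options).pka) # 7.300000000002601
```

Other subcommands: `pka thermo` (Gibbs free energy with full component
breakdown for one species record), `pka benchmark` (score a directory of
results against the embedded experimental table, grouped by
approach/correction/protocol), `pka fixtures` (write synthetic species,
pair manifests, and benchmark sets with known ground truth).

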