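# Methods

## Problem and model

`aqpka` computes aqueous acid-dissociation constants from quantum-chemistry
(QC) outputs for deprotonation reactions of the form HA → A + H⁺, with the
para-substituted aniline radical cation (R-PhNH₂•⁺ → R-PhNH• + H⁺) and
anilinium (R-PhNH₃⁺ → R-PhNH₂ + H⁺) families as the reference application.
The package post-processes QC results; it never launches an
electronic-structure calculation.

The central relation is

    pKa = ΔG_deprot(sol) / (2.303 · R · T)

with R = 8.314 J mol⁻¹ K⁻¹ and T = 298.15 K. ΔG_deprot(sol) is assembled by
either of two routes:

* **direct** — both species' free energies are computed in the solvent model:
  ΔG = G_A(sol) − G_HA(sol) + ΔG_H⁺(sol);
* **indirect (thermodynamic cycle)** — gas-phase free energies plus
  separately computed solvation free energies:
  ΔG = [G_A(gas) − G_HA(gas)] + [ΔG_A(sol) − ΔG_HA(sol)] + ΔG_H⁺(sol),
  which closes the cycle G(sol) = G(gas) + ΔG(sol).

ΔG_H⁺(sol) = −1131.44 kJ mol⁻¹ is the experimental aqueous proton free
energy at 298.15 K; all proton thermochemistry is folded into this single
constant. When the two routes are fed a consistent decomposition
(G(sol) = G(gas) + ΔG(sol) per species) they agree identically — this cycle
identity is a core invariant of the test suite.

## Statistical thermochemistry

Gibbs free energies are built from ideal-gas partition functions:
Sackur–Tetrode translational entropy, rigid-rotor rotational terms from the
principal moments of inertia (diagonalized inertia tensor about the center
of mass), harmonic vibrational terms per mode, and R·ln(multiplicity)
electronic entropy. Three harmonic treatments are provided:

* **C0 (RRHO)** — plain harmonic formulas on the raw frequencies. The
  per-mode entropy diverges as ν → 0, making C0 fragile for the floppy
  explicit-water clusters this pipeline targets.
* **C1 (Truhlar quasi-RRHO)** — every frequency below ν₀ = 100 cm⁻¹ is
  raised to ν₀ before the harmonic formulas are applied, capping each
  low mode's entropy at the 100 cm⁻¹ value (≈ 14.45 J mol⁻¹ K⁻¹ at 298 K).
* **C2 (Grimme quasi-RRHO)** — per-mode entropy is the damped interpolation
  w·S_HO + (1−w)·S_FR with w = 1/(1+(ν₀/ν)⁴), where S_FR is the entropy of
  a one-dimensional free rotor with effective moment
  μ′ = μ·B_av/(μ+B_av), μ = h/(8π²cν), B_av = 10⁻⁴⁴ kg m².

Two scope decisions were genuinely open and are fixed as follows:

* ZPE always uses the raw (optionally scaled) frequencies under every
  scheme. Frequency raising is a fix for the entropy (and thermal-energy)
  divergence; letting it inflate the ZPE would shift deprotonation
  energetics nonphysically.
* Under C1 the raised frequencies feed both vibrational entropy and
  vibrational thermal energy (`c1_raise_thermal=True`); the raising rule
  names no specific term, and applying it to all thermal vibrational terms
  is the consistent reading. A flag restores entropy-only raising. C2
  modifies entropy only, matching the interpolation scheme's original scope.

A numerical note on the C2 high-frequency limit: the interpolation
converges to the harmonic entropy *absolutely* (the residual
(1−w)(S_FR−S_HO) is ~10⁻⁶ J mol⁻¹ K⁻¹ at 3000 cm⁻¹) but not *relatively*,
because S_HO decays exponentially with ν while the residual decays only
polynomially — S_FR is in fact negative for stiff modes. This is a property
of the interpolation formula itself, not of this implementation.

### Parameters

| parameter | default | meaning |
|---|---|---|
| temperature | 298.15 K | all free energies and the pKa conversion |
| pressure | 101325 Pa | gas standard state (1 atm) for Sackur–Tetrode |
| ν₀ | 100 cm⁻¹ | C1 raising threshold / C2 interpolation midpoint |
| B_av | 10⁻⁴⁴ kg m² | averaged moment damping the C2 free rotor |
| zpe_scale | 1.0 | empirical ZPE frequency scale factor (method-specific; exposed, not preset) |
| symmetry number σ | 1 | user-supplied; never inferred from geometry |
| log_conversion | 2.303 | rounded ln 10 as printed in the source relation; exact ln 10 selectable (< 0.02% difference) |
| standard_state_correction | off | optional R·T·ln(24.46) gas(1 atm)→1 M shift per species; off because the deprotonation equations and the adopted proton constant are used as stated, with no such term |

Physical constants are CODATA 2018 exact values; only the pKa denominator
uses the rounded literal R = 8.314 J mol⁻¹ K⁻¹ for reproducibility of the
printed arithmetic.

### Numerical choices

* Linearity: a molecule is linear if the smallest principal moment is below
  10⁻⁶ × the largest (robust to float noise on exactly linear fixtures);
  callers can declare linearity explicitly.
* Stiff modes: for Θ/T > 700 the vibrational U and S underflow and are set
  to exactly 0 (the closed forms are < 10⁻³⁰⁰ there).
* Imaginary frequencies are hard errors by default — species are expected to
  be optimized minima; `allow_imaginary="drop"` strips them with a warning.
* Energies are converted to J mol⁻¹ on input (accepted tags: Hartree with
  1 Eh = 2625.4996394799 kJ mol⁻¹, kcal mol⁻¹ with 1 kcal = 4.184 kJ,
  kJ mol⁻¹, J mol⁻¹) and converted back to the original tag on write, so
  records round-trip.

## Explicit-water bookkeeping and protocols

Cluster models with discrete water molecules are tracked by count
(`explicit_waters`) and hydrogen-bond motif label (`HO`, `NH`, `2HO`,
`NHHO`, `HOA90`, …: water as H-donor to the amino group, as electron-pair
acceptor, or perpendicular to the ring plane). Conjugate pairs must be
water-balanced; an explicit override adds n·G(H₂O) terms from a
user-supplied water record when counts differ, since an unbalanced cycle is
otherwise ill-defined.

Solvation free energies for the indirect route are tagged by protocol
P1–P6, which record the method that produced them: P1 one method for all
species (M052X/6-31G(d)); P2 by charge class (M052X/6-31G(d) neutral,
M052X/6-31+G(d,p) cation, HF/6-31G(d) anion) with sulfonate-substituted
species always routed to the anion method; P3 the radical adaptation
(M052X/6-31G(d) for radical cations, HF/6-31G(d) for neutral radicals and
the sulfonate radical cation — species outside those classes also take
HF/6-31G(d), the anion-class method P3 imitates); P4–P6 single-method
explicit-water protocols (M062X/6-31G(d), M052X/cc-pVTZ,
ωb97xd/6-31+g(d,p)) requiring ≥ 1 explicit water. Iodine-containing species
are annotated with the heavy-atom basis (ma-def2QZVP). These labels
validate and document inputs; they never trigger a computation.

## Benchmark statistics

The embedded experimental table holds literature pKa values for ten
para-substituents (H, C₄H₉, CF₃, CH₃, OCH₃, CN, COCH₃, I, NH₂, SO₃⁻) in
both systems — 10 single-valued radical-cation entries and 10 anilinium
entries carrying 18 raw values. Entries with multiple literature values are
averaged arithmetically (applied whenever ≥ 2 values exist; the raw list is
retained). Reported statistics: per-compound Δ = |calc − exp|, RMSE,
RMSE_aver ± RMSE_std across combinations (sample n−1 standard deviation by
default, population variant selectable), and OLS of calculated (y) on
experimental (x) pKa with slope, intercept, and r² (squared Pearson
correlation). The mean of the ten anilinium per-compound averages is 3.97
and the mean over all 18 raw values is 3.68; both are exposed since the
conventional "≈ 3.9" figure matches neither exactly.

## Synthetic fixtures

The generator emulates the *structure* of QC outputs, not aniline physics:
random non-colinear geometries of C/N/O/H atoms, positive harmonic spectra
with a controlled count of sub-100 cm⁻¹ modes (the regime where C0/C1/C2
differ), electronic energies in the −400…−100 Hartree range, and charge /
multiplicity / explicit-water metadata matching the radical-cation
deprotonation pattern (+1 doublet acid, neutral doublet base, one water
each).

`generate_pair_with_known_pka` back-solves the single linear unknown — the
base's electronic energy — so the full pipeline returns the requested pKa
exactly, and simultaneously emits gas free energies and per-protocol
solvation energies consistent with G(sol) = G(gas) + ΔG(sol) (solvation
magnitudes drawn from typical aqueous ranges: −280…−240 kJ mol⁻¹ for the
cation, −40…−10 kJ mol⁻¹ for the neutral). Benchmark fixtures add N(0, σ)
noise to the experimental averages and report the realized RMSE by
independent summation.

Passing tests on these fixtures therefore demonstrate the correctness of
the thermochemistry, cycle algebra, and statistics — they do not
demonstrate predictive accuracy for real anilines, which depends entirely
on the quality of the upstream QC free energies. Reproducing the published
accuracy figures for specific QC method combinations would require those
authors' QC outputs, which are not redistributable here.

## Problem sizes

Synthetic checks use 30–100 conjugate pairs per property, 100 random
targets per correction scheme for parameter recovery, and 10⁴-point noise
sets for RMSE convergence — sizes at which every asserted identity is
already at float precision and the full suite runs in seconds.

## Known limitations

* No anharmonic corrections, hindered-rotor treatment, or isotope effects.
* Symmetry numbers are never perceived from geometry (default σ = 1).
* The proton solvation constant is a 298 K value; changing the temperature
  is supported but logged with that caveat, and no temperature-dependent
  proton term is provided.
* Gaussian/ORCA log parsing is out of scope; populate records via the JSON
  schema or the `species_from_dict` adapter hook.
* Multi-site microspeciation and proton-exchange schemes against reference
  acids are out of scope.
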