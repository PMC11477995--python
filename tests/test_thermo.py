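"""Statistical thermochemistry: closed forms, scheme relations, invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from aqpka import (
    Atom,
    SpeciesRecord,
    ThermoOptions,
    gibbs_free_energy,
    grimme_mode_entropy,
    principal_moments,
    raised_frequencies,
    rotational_terms,
    translational_terms,
    vibrational_mode_terms,
)
from aqpka.constants import AMU_TO_KG, R_GAS
from aqpka.errors import ThermoInputError
from aqpka.fixtures import FixtureSpec, generate_species
from aqpka.species import RotationalData
from aqpka.thermo import free_rotor_mode_entropy

T0 = 298.15


class TestVibrationalMode:
    def test_stiff_mode_limit(self):
        _, u, s = vibrational_mode_terms(1.0e6, T0)
        assert u == pytest.approx(0.0, abs=1e-30)
        assert s == pytest.approx(0.0, abs=1e-30)

    def test_hand_value_at_100_wavenumbers(self):
        # Theta = 143.88 K; closed form gives 14.4529 J/mol/K
        _, _, s = vibrational_mode_terms(100.0, T0)
        assert s == pytest.approx(14.452864283551149, rel=1e-12)
        assert s == pytest.approx(14.45, abs=5e-3)

    def test_entropy_strictly_decreasing_in_frequency(self):
        grid = np.linspace(5.0, 4000.0, 200)
        entropies = [vibrational_mode_terms(nu, T0)[2] for nu in grid]
        assert all(a > b for a, b in zip(entropies, entropies[1:]))

    def test_domain_error(self):
        with pytest.raises(ThermoInputError):
            vibrational_mode_terms(-5.0, T0)
        with pytest.raises(ThermoInputError):
            vibrational_mode_terms(0.0, T0)

    @settings(derandomize=True, max_examples=50)
    @given(nu=st.floats(1.0, 5000.0), T=st.floats(100.0, 1000.0))
    def test_matches_brute_force_oracle(self, nu, T):
        zpe, u, s = vibrational_mode_terms(nu, T)
        assert zpe == pytest.approx(oracles.mode_zpe(nu), rel=1e-12)
        assert u == pytest.approx(oracles.mode_u(nu, T), rel=1e-9)
        assert s == pytest.approx(oracles.mode_s(nu, T), rel=1e-9, abs=1e-15)


class TestTranslational:
    def test_argon_sackur_tetrode(self):
        # frozen from the independent closed-form evaluation at 1 atm
        _, s = translational_terms(39.948 * AMU_TO_KG, T0, 101325.0)
        assert s == pytest.approx(154.73621657529839, rel=1e-10)

    def test_u_is_three_halves_rt(self):
        m = 20.0 * AMU_TO_KG
        u1, _ = translational_terms(m, T0, 101325.0)
        u2, _ = translational_terms(m, 2 * T0, 101325.0)
        assert u2 == pytest.approx(2 * u1, rel=1e-12)
        assert u1 == pytest.approx(1.5 * R_GAS * T0, rel=1e-12)

    def test_pressure_doubling_term(self):
        m = 20.0 * AMU_TO_KG
        _, s1 = translational_terms(m, T0, 101325.0)
        _, s2 = translational_terms(m, T0, 2 * 101325.0)
        assert s2 - s1 == pytest.approx(-R_GAS * math.log(2), rel=1e-12)

    def test_nonpositive_mass(self):
        with pytest.raises(ThermoInputError):
            translational_terms(0.0, T0, 101325.0)


class TestRotational:
    def test_monatomic_zero(self):
        rot = RotationalData((0.0, 0.0, 0.0), "monatomic")
        assert rotational_terms(rot, T0) == (0.0, 0.0)

    def test_symmetry_number_term(self):
        moments = (1e-47, 2e-47, 3e-47)
        s1 = rotational_terms(RotationalData(moments, "nonlinear", 1), T0)[1]
        s2 = rotational_terms(RotationalData(moments, "nonlinear", 2), T0)[1]
        assert s1 - s2 == pytest.approx(R_GAS * math.log(2), rel=1e-12)

    def test_linear_rotor_closed_form(self):
        i_mom = 8.3027e-48
        rot = RotationalData((0.0, i_mom, i_mom), "linear", 1)
        u, s = rotational_terms(rot, T0)
        assert u == pytest.approx(R_GAS * T0, rel=1e-12)
        assert s == pytest.approx(oracles.rot_s_linear(i_mom, 1, T0), rel=1e-10)

    def test_nonlinear_matches_oracle(self):
        moments = (2.3e-47, 3.1e-47, 4.0e-47)
        u, s = rotational_terms(RotationalData(moments, "nonlinear", 3), T0)
        assert u == pytest.approx(1.5 * R_GAS * T0, rel=1e-12)
        assert s == pytest.approx(oracles.rot_s_nonlinear(moments, 3, T0), rel=1e-10)

    def test_zero_moment_nonlinear_rejected(self):
        rot = RotationalData((0.0, 1e-47, 1e-47), "nonlinear")
        with pytest.raises(ThermoInputError):
            rotational_terms(rot, T0)


class TestRaisedFrequencies:
    def test_raising_rule(self):
        assert raised_frequencies([50.0, 120.0, 99.9], 100.0) == [100.0, 120.0, 100.0]

    def test_noop_above_threshold(self):
        freqs = [150.0, 300.0]
        assert raised_frequencies(freqs, 100.0) == freqs

    def test_boundary_not_raised(self):
        assert raised_frequencies([100.0], 100.0) == [100.0]

    def test_input_unmodified(self):
        freqs = [50.0, 200.0]
        raised_frequencies(freqs, 100.0)
        assert freqs == [50.0, 200.0]

    def test_rejects_nonpositive(self):
        with pytest.raises(ThermoInputError):
            raised_frequencies([-1.0, 50.0], 100.0)


class TestGrimmeInterpolation:
    def test_midpoint_weight_at_threshold(self):
        nu0 = 100.0
        s = grimme_mode_entropy(nu0, T0, nu0)
        s_ho = vibrational_mode_terms(nu0, T0)[2]
        s_fr = free_rotor_mode_entropy(nu0, T0)
        assert s == pytest.approx(0.5 * s_ho + 0.5 * s_fr, rel=1e-12)

    def test_high_frequency_harmonic_limit(self):
        # the interpolation reaches the harmonic limit absolutely: the
        # residual (1-w)(S_FR - S_HO) is ~2.7e-6 J/mol/K at 3000 cm^-1,
        # negligible against any molecular entropy (S_HO itself decays
        # exponentially, so a *relative* comparison is ill-posed here)
        s = grimme_mode_entropy(3000.0, T0)
        s_ho = vibrational_mode_terms(3000.0, T0)[2]
        assert s == pytest.approx(s_ho, abs=5e-6)
        w = 1.0 / (1.0 + (100.0 / 3000.0) ** 4)
        assert 1.0 - w == pytest.approx(1.23e-6, rel=1e-2)

    def test_low_frequency_free_rotor_limit(self):
        s = grimme_mode_entropy(10.0, T0)
        s_fr = oracles.free_rotor_s(10.0, T0, 1.0e-44)
        assert s == pytest.approx(s_fr, rel=1e-4)

    def test_domain_error(self):
        with pytest.raises(ThermoInputError):
            grimme_mode_entropy(0.0, T0)


def _manual_total(record, options):
    rot = principal_moments(record.atoms, record.symmetry_number, record.linearity)
    return oracles.gibbs_by_hand(
        record.electronic_energy,
        record.frequencies,
        record.total_mass_amu() * AMU_TO_KG,
        rot.principal_moments,
        rot.linearity,
        record.symmetry_number,
        record.multiplicity,
        options.temperature,
        options.pressure,
        scheme=options.scheme,
        nu0=options.nu0,
        b_av=options.b_av,
        zpe_scale=options.zpe_scale,
    )


class TestGibbsFreeEnergy:
    def test_monatomic_correction(self):
        rec = SpeciesRecord(
            label="Ar", charge=0, multiplicity=1,
            atoms=[Atom("Ar", 0, 0, 0)], electronic_energy=0.0,
        )
        result = gibbs_free_energy(rec, ThermoOptions())
        expected = 1.5 * R_GAS * T0 + R_GAS * T0 - T0 * result.s_trans
        assert result.gibbs_correction == pytest.approx(expected, rel=1e-12)
        assert result.s_trans == pytest.approx(
            oracles.sackur_tetrode(39.948 * AMU_TO_KG, T0, 101325.0), rel=1e-10
        )
        assert result.u_rot == 0.0 and result.s_vib == 0.0

    def test_c0_equals_c1_above_threshold(self, diatomic_record):
        r0 = gibbs_free_energy(diatomic_record, ThermoOptions(scheme="C0"))
        r1 = gibbs_free_energy(diatomic_record, ThermoOptions(scheme="C1"))
        # all frequencies >= 100 cm^-1: schemes must coincide bit-for-bit
        assert r0.gibbs_total == r1.gibbs_total
        assert r0.s_vib == r1.s_vib
        assert r0.u_vib == r1.u_vib

    def test_diatomic_term_by_term_oracle(self, diatomic_record):
        options = ThermoOptions()
        result = gibbs_free_energy(diatomic_record, options)
        assert result.gibbs_total == pytest.approx(
            _manual_total(diatomic_record, options), rel=1e-9
        )

    @pytest.mark.parametrize("scheme", ["C0", "C1", "C2"])
    def test_random_fixtures_match_hand_sum(self, scheme):
        options = ThermoOptions(scheme=scheme)
        for seed in range(25):
            rec = generate_species(
                FixtureSpec(seed=seed, n_atoms=3 + seed % 5, n_low_modes=seed % 3,
                            multiplicity=1 + seed % 2)
            )
            result = gibbs_free_energy(rec, options)
            assert result.gibbs_total == pytest.approx(
                _manual_total(rec, options), rel=1e-9
            )

    @pytest.mark.parametrize("scheme", ["C0", "C1", "C2"])
    def test_result_identity_and_nonnegative_entropy(self, scheme):
        options = ThermoOptions(scheme=scheme)
        for seed in (3, 17):
            rec = generate_species(
                FixtureSpec(seed=seed, n_atoms=4, n_low_modes=1, multiplicity=2)
            )
            r = gibbs_free_energy(rec, options)
            recon = (
                r.zpe + r.u_trans + r.u_rot + r.u_vib + R_GAS * options.temperature
                - options.temperature * (r.s_trans + r.s_rot + r.s_vib + r.s_elec)
            )
            assert r.gibbs_correction == pytest.approx(recon, rel=1e-14)
            assert r.enthalpy_correction == pytest.approx(
                r.zpe + r.u_trans + r.u_rot + r.u_vib
                + R_GAS * options.temperature, rel=1e-14
            )
            assert min(r.s_trans, r.s_rot, r.s_vib, r.s_elec) >= 0.0

    def test_additive_in_electronic_energy(self, diatomic_record):
        options = ThermoOptions(scheme="C2")
        g0 = gibbs_free_energy(diatomic_record, options).gibbs_total
        shifted = replace(diatomic_record,
                          electronic_energy=diatomic_record.electronic_energy + 12345.0)
        g1 = gibbs_free_energy(shifted, options).gibbs_total
        assert g1 - g0 == pytest.approx(12345.0, abs=1e-6)

    def test_zpe_scale_moves_only_zpe(self, diatomic_record):
        r1 = gibbs_free_energy(diatomic_record, ThermoOptions(zpe_scale=1.0))
        r2 = gibbs_free_energy(diatomic_record, ThermoOptions(zpe_scale=0.97))
        assert r2.zpe == pytest.approx(0.97 * r1.zpe, rel=1e-12)
        assert r2.s_vib == r1.s_vib
        assert r2.u_vib == r1.u_vib

    def test_standard_state_shift(self, diatomic_record):
        g_off = gibbs_free_energy(diatomic_record, ThermoOptions()).gibbs_total
        g_on = gibbs_free_energy(
            diatomic_record,
            ThermoOptions(standard_state_correction="gas1atm_to_1M"),
        ).gibbs_total
        assert g_on - g_off == pytest.approx(
            R_GAS * T0 * math.log(24.46), rel=1e-12
        )

    def test_polyatomic_without_frequencies_rejected(self, diatomic_record):
        diatomic_record.frequencies = []
        with pytest.raises(ThermoInputError, match="frequencies"):
            gibbs_free_energy(diatomic_record, ThermoOptions())


class TestLowFrequencyBehaviour:
    """C0 diverges as nu -> 0+ while C1/C2 stay bounded."""

    def test_c1_caps_entropy_at_threshold_value(self):
        s_cap = vibrational_mode_terms(100.0, T0)[2]
        for nu in (0.5, 5.0, 50.0, 99.0):
            raised = raised_frequencies([nu], 100.0)[0]
            assert vibrational_mode_terms(raised, T0)[2] == pytest.approx(
                s_cap, rel=1e-12
            )

    def test_c0_exceeds_quasi_schemes_at_low_frequency(self):
        nu = 1.0
        s_c0 = vibrational_mode_terms(nu, T0)[2]
        s_c2 = grimme_mode_entropy(nu, T0)
        s_c1 = vibrational_mode_terms(raised_frequencies([nu])[0], T0)[2]
        assert s_c0 > s_c1 and s_c0 > s_c2

    def test_c2_approaches_c0_at_high_frequency(self):
        # absolute convergence with a shrinking residual
        residuals = []
        for nu in (2000.0, 3000.0, 4000.0):
            s_c0 = vibrational_mode_terms(nu, T0)[2]
            s_c2 = grimme_mode_entropy(nu, T0)
            residuals.append(abs(s_c2 - s_c0))
        assert all(r < 5e-6 for r in residuals)
        assert residuals[0] > residuals[1] > residuals[2]

    @settings(derandomize=True, max_examples=30)
    @given(nu=st.floats(0.01, 99.0))
    def test_c1_c2_bounded_below_threshold(self, nu):
        s_bound = vibrational_mode_terms(100.0, T0)[2]
        s_c1 = vibrational_mode_terms(max(nu, 100.0), T0)[2]
        s_c2 = grimme_mode_entropy(nu, T0)
        s_fr_cap = oracles.free_rotor_s(100.0, T0, 1.0e-44)
        assert s_c1 == pytest.approx(s_bound, rel=1e-12)
        # C2 is bounded by the free-rotor branch, which grows only
        # logarithmically; check it stays finite and modest
        assert math.isfinite(s_c2)
        assert s_c2 < 120.0
        assert s_fr_cap < 60.0
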