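"""Steady-state transport model: ionization, sorption, flux, distribution."""

import math

import numpy as np
import pytest

import probeloc as pl
from probeloc.transport import RT_OVER_F_MV, _species_states

from conftest import bare_compound


def _aqueous(name="aq", pH=7.0, E=0.0, lipid=0.0):
    return pl.CompartmentParams(
        name=name,
        volume_L=1e-12,
        pH=pH,
        membrane_potential_mV=E,
        lipid_fraction=lipid,
        water_fraction=1.0 - lipid,
    )


class TestIonizationFractions:
    def test_permanent_cation_is_single_species(self):
        assert pl.ionization_fractions((), pH=7.4) == [(1, 1.0)]

    def test_midpoint_splits_evenly(self):
        species = dict(pl.ionization_fractions((7.0,), pH=7.0))
        assert species[1] == pytest.approx(0.5)
        assert species[2] == pytest.approx(0.5)

    def test_basic_group_protonated_in_acidic_lysosome(self):
        # pKa 8 at pH 5: protonated (+2) fraction = 1/(1+10^(5-8))
        species = dict(pl.ionization_fractions((8.0,), pH=5.0))
        assert species[2] == pytest.approx(1.0 / (1.0 + 10 ** (5.0 - 8.0)))

    def test_fractions_sum_to_one(self):
        for pkas in [(), (6.5,), (6.5, 9.0)]:
            fracs = [f for _, f in pl.ionization_fractions(pkas, pH=7.2)]
            assert sum(fracs) == pytest.approx(1.0)

    def test_more_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            pl.ionization_fractions((5.0, 6.0, 7.0), pH=7.0)


class TestActivityCoefficient:
    def test_pure_aqueous_is_unity(self):
        assert pl.activity_coefficient(3.0, _aqueous()) == pytest.approx(1.0)

    def test_low_logp_limit_is_inverse_water_fraction(self):
        comp = _aqueous(lipid=0.05)
        assert pl.activity_coefficient(-30.0, comp) == pytest.approx(1.0 / 0.95)

    def test_direct_evaluation(self):
        # water 0.95, lipid 0.05, logP 3 -> 1/(0.95 + 50)
        comp = _aqueous(lipid=0.05)
        assert pl.activity_coefficient(3.0, comp) == pytest.approx(1.0 / 50.95)


class TestMembraneFlux:
    def test_nernst_equilibrium_gives_zero_flux(self):
        compound = bare_compound(3.0)
        inner = _aqueous("in", E=-120.0)
        outer = _aqueous("out")
        sp_in = _species_states(compound, inner, -120.0)
        sp_out = _species_states(compound, outer, -120.0)
        n = sp_in[0].nernst_n
        c_eq = 1e-6 * math.exp(-n)
        assert pl.membrane_flux(1e-6, c_eq, sp_out, sp_in) == pytest.approx(0.0, abs=1e-25)

    def test_small_n_matches_fick(self):
        compound = bare_compound(2.0)
        e_tiny = 1e-6 * RT_OVER_F_MV  # N = 1e-6
        inner = _aqueous("in", E=e_tiny)
        outer = _aqueous("out")
        sp_in = _species_states(compound, inner, e_tiny)
        sp_out = _species_states(compound, outer, e_tiny)
        got = pl.membrane_flux(2e-6, 1e-6, sp_out, sp_in)
        p = sp_in[0].permeability_cm_s
        fick = p * (2e-6 - 1e-6)
        assert got == pytest.approx(fick, rel=1e-9)

    def test_flux_linear_in_area_and_decreasing_in_inner_concentration(self):
        compound = bare_compound(3.0)
        inner, outer = _aqueous("in", E=-90.0), _aqueous("out")
        sp_in = _species_states(compound, inner, -90.0)
        sp_out = _species_states(compound, outer, -90.0)
        j1 = pl.membrane_flux(1e-6, 1e-7, sp_out, sp_in, area_cm2=1.0)
        j2 = pl.membrane_flux(1e-6, 1e-7, sp_out, sp_in, area_cm2=2.0)
        assert j2 == pytest.approx(2 * j1)
        cs = np.linspace(0, 1e-3, 7)
        fluxes = [pl.membrane_flux(1e-6, c, sp_out, sp_in) for c in cs]
        assert all(a > b for a, b in zip(fluxes, fluxes[1:]))


class TestSteadyState:
    def test_nernst_accumulation_of_monocation(self):
        # z=+1, E=-160 mV, no sorption: c_in/c_out = e^{160/26.73} ~ 4e2
        compound = bare_compound(0.0)
        inner = _aqueous("in", E=-160.0)
        outer = _aqueous("out")
        c_in = pl.steady_state_concentration(inner, outer, 1e-6, compound)
        assert c_in / 1e-6 == pytest.approx(math.exp(160.0 / RT_OVER_F_MV), rel=1e-8)

    def test_no_gradient_means_equal_concentrations(self):
        compound = bare_compound(2.0)
        comp = _aqueous("both", pH=7.0, E=0.0)
        c_in = pl.steady_state_concentration(comp, comp, 5e-7, compound)
        assert c_in == pytest.approx(5e-7, rel=1e-10)

    def test_root_finder_matches_closed_form_on_random_draws(self):
        # single-species oracle: c_in = (g_out/g_in) c_out e^{-N}
        rng = np.random.default_rng(42)
        for _ in range(100):
            compound = bare_compound(float(rng.uniform(-2, 6)))
            e_mv = float(rng.uniform(-200, 50))
            inner = _aqueous("in", pH=rng.uniform(4, 9), E=e_mv,
                             lipid=float(rng.uniform(0, 0.2)))
            outer = _aqueous("out", pH=rng.uniform(4, 9),
                             lipid=float(rng.uniform(0, 0.2)))
            c_out = float(rng.uniform(1e-9, 1e-3))
            g_in = pl.activity_coefficient(compound.logp, inner)
            g_out = pl.activity_coefficient(compound.logp, outer)
            n = 1.0 * e_mv / RT_OVER_F_MV
            expected = (g_out / g_in) * c_out * math.exp(-n)
            got = pl.steady_state_concentration(inner, outer, c_out, compound)
            assert got == pytest.approx(expected, rel=1e-8)


class TestFractionalMasses:
    def test_fractions_on_simplex(self, cell):
        res = pl.fractional_masses(bare_compound(4.0), cell)
        total = res.frac_mito + res.frac_lyso + res.frac_membranes
        assert total == pytest.approx(1.0, abs=1e-9)
        assert min(res.frac_mito, res.frac_lyso, res.frac_membranes) >= 0

    def test_permanent_cations_exclude_lysosomes(self, cell):
        # ion trapping needs a protonatable group; permanent cations don't
        # accumulate in the (slightly positive-inside) acidic lysosome
        for logp in (2.0, 4.0, 6.0):
            res = pl.fractional_masses(bare_compound(logp), cell)
            assert res.frac_lyso < 0.01

    def test_depolarizing_mitochondria_releases_cations(self, cell):
        depolarized = dict(cell)
        m = cell["mitochondria"]
        depolarized["mitochondria"] = pl.CompartmentParams(
            name=m.name, volume_L=m.volume_L, pH=m.pH,
            membrane_potential_mV=0.0, lipid_fraction=m.lipid_fraction,
            water_fraction=m.water_fraction, membrane_area_cm2=m.membrane_area_cm2,
        )
        base = pl.fractional_masses(bare_compound(3.0), cell)
        depol = pl.fractional_masses(bare_compound(3.0), depolarized)
        assert depol.frac_mito < base.frac_mito

    def test_ion_trapping_of_protonatable_base(self, cell):
        mono = pl.fractional_masses(bare_compound(3.0), cell)
        base = pl.fractional_masses(bare_compound(3.0, extra_pkas=(9.0,)), cell)
        assert base.frac_lyso > mono.frac_lyso
        lyso_gain = (
            base.concentrations["lysosome"] / mono.concentrations["lysosome"]
        )
        assert lyso_gain > 1.0

    def test_missing_compartment_rejected(self, cell):
        broken = {k: v for k, v in cell.items() if k != "lysosome"}
        with pytest.raises(KeyError):
            pl.fractional_masses(bare_compound(3.0), broken)


class TestPredictLibrary:
    def test_exclusion_bookkeeping(self, full_library, full_predictions):
        predictions, exclusions = full_predictions
        n_two = sum(c.n_extra_ionizable >= 2 for c in full_library)
        assert len(exclusions) == n_two
        assert len(predictions) + len(exclusions) == len(full_library)

    def test_no_extra_groups_means_no_exclusions(self):
        lib = pl.generate_library(2, 4, seed=3, extra_head_fraction=0,
                                  extra_aldehyde_fraction=0)
        predictions, exclusions = pl.predict_library(lib)
        assert len(exclusions) == 0 and len(predictions) == 8

    def test_all_fractions_on_simplex(self, full_predictions):
        predictions, _ = full_predictions
        sums = predictions[["frac_mito", "frac_lyso", "frac_membranes"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-7)
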