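"""Hepatocyte kinetic model: network structure, rate laws, conservation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hepatosim import cell_kinetics as ck
from hepatosim.cell_kinetics import (
    IDX,
    SPECIES,
    ActivityConversionSpec,
    EnzymeProfile,
    basal_state,
    build_network,
    cell_rhs,
    convert_specific_activity,
    reaction_rates,
    simulate_cell,
)

NET = build_network()


class TestNetworkStructure:
    def test_gst_consumes_napqi_and_gsh_producing_conjugate(self):
        j = NET.reaction_index("gst")
        col = {SPECIES[i]: NET.N[i, j] for i in np.nonzero(NET.N[:, j])[0]}
        assert col == {"NAPQI": -1, "GSH": -1, "APAPGS": +1}

    def test_gpx_redox_stoichiometry(self):
        j = NET.reaction_index("gpx")
        col = {SPECIES[i]: NET.N[i, j] for i in np.nonzero(NET.N[:, j])[0]}
        assert col == {"H2O2": -1, "GSH": -2, "GSSG": +1}

    def test_gsr_returns_two_gsh_per_gssg(self):
        j = NET.reaction_index("gsr")
        assert NET.N[IDX["GSSG"], j] == -1
        assert NET.N[IDX["GSH"], j] == +2

    def test_apap_moiety_in_left_null_space_of_transformations(self):
        # the APAP-carrying moiety is conserved by every chemical
        # transformation; only transport/export columns move it
        prod = NET.moiety_vector @ NET.N[:, NET.transform_mask]
        assert np.all(prod == 0)

    def test_every_reaction_references_declared_species(self):
        for rxn in NET.reactions:
            for sp in rxn.stoich:
                assert sp in SPECIES
            assert rxn.law in {"mm", "mm2", "passive", "binding",
                               "zero_order", "linear"}


class TestReactionRates:
    def test_zero_concentrations_give_zero_flux_except_synthesis(self, profile):
        v = reaction_rates(np.zeros(len(SPECIES)), profile)
        j_gss = NET.reaction_index("gss")
        nonzero = np.nonzero(v)[0]
        assert list(nonzero) == [j_gss]   # zero-order GSH synthesis only

    def test_cyp_saturation_limit_sums_vmax_with_zonation(self, profile):
        c = np.zeros(len(SPECIES))
        c[IDX["APAP_cyt"]] = 1e9
        zone = 1.3
        v = reaction_rates(c, profile, zone_factor=zone)
        total = sum(v[NET.reaction_index(r)] for r in ("cyp3a4", "cyp2e1", "cyp_minor"))
        expected = (zone * profile.vmax_cyp3a4 + profile.vmax_cyp2e1
                    + profile.vmax_cyp_minor)
        assert total == pytest.approx(expected, rel=1e-4)

    def test_ugt_half_saturation(self, profile):
        c = np.zeros(len(SPECIES))
        c[IDX["APAP_cyt"]] = profile.km_ugt
        v = reaction_rates(c, profile)
        assert v[NET.reaction_index("ugt")] == pytest.approx(profile.vmax_ugt / 2)

    def test_zone_factor_multiplies_only_cyp3a4(self, profile):
        c = np.full(len(SPECIES), 100.0)
        v1 = reaction_rates(c, profile, zone_factor=1.0)
        v2 = reaction_rates(c, profile, zone_factor=1.3)
        j = NET.reaction_index("cyp3a4")
        assert v2[j] == pytest.approx(1.3 * v1[j])
        mask = np.ones(len(v1), bool)
        mask[j] = False
        np.testing.assert_allclose(v1[mask], v2[mask])

    def test_negative_concentration_rejected(self, profile):
        c = np.zeros(len(SPECIES))
        c[0] = -1.0
        with pytest.raises(ValueError):
            reaction_rates(c, profile)

    @pytest.mark.parametrize("reaction,species", [
        ("ugt", "APAP_cyt"), ("sult", "APAP_cyt"), ("cyp2e1", "APAP_cyt"),
        ("nqo1", "NAPQI"), ("ggt", "GSH"), ("sod", "ROS"), ("gsr", "GSSG"),
    ])
    def test_michaelis_menten_flux_nondecreasing_in_substrate(
            self, profile, reaction, species):
        j = NET.reaction_index(reaction)
        grid = np.geomspace(1e-3, 1e6, 40)
        vals = []
        for s in grid:
            c = np.zeros(len(SPECIES))
            c[IDX[species]] = s
            vals.append(reaction_rates(c, profile)[j])
        assert np.all(np.diff(vals) >= -1e-12)


class TestCellRhs:
    def test_dead_cell_derivatives_all_zero(self, profile, rng):
        c = rng.uniform(0, 5000, len(SPECIES))
        d = cell_rhs(c, profile, alive=False)
        assert np.all(d == 0)

    def test_dimension_mismatch_rejected(self, profile):
        with pytest.raises(ValueError):
            cell_rhs(np.zeros(5), profile)

    def test_only_gssg_nonzero_drives_gsh_at_twice_gsr_flux(self, profile):
        c = np.zeros(len(SPECIES))
        c[IDX["GSSG"]] = 100.0
        d = cell_rhs(c, profile)
        v_gsr = reaction_rates(c, profile)[NET.reaction_index("gsr")]
        assert v_gsr > 0
        # GSH gains 2 per GSR turnover on top of the basal zero-order synthesis
        assert d[IDX["GSH"]] == pytest.approx(2 * v_gsr + profile.vmax_gss)

    def test_closed_cell_conserves_apap_moiety_over_1000_min(self, profile):
        # no membrane transport or export: the APAP-derived moiety total is a
        # strict invariant; quadrature over a solved trajectory checks drift
        closed = profile.with_updates(
            p_apap=0.0, p_napqi=0.0, vmax_uptake=0.0,
            vmax_mrp2=0.0, vmax_mrp34=0.0,
        )
        c0 = basal_state(closed)
        c0[IDX["APAP_cyt"]] = 3000.0
        w = NET.moiety_vector

        sol = solve_ivp(
            lambda t, c: cell_rhs(c, closed), (0, 1000.0), c0,
            method="LSODA", rtol=1e-9, atol=1e-10, t_eval=np.linspace(0, 1000, 50),
        )
        assert sol.success
        moiety = w @ sol.y
        drift = np.abs(moiety - moiety[0]).max() / moiety[0]
        assert drift < 1e-6

    def test_rhs_equals_stoichiometry_times_rates(self, profile, rng):
        for _ in range(10):
            c = rng.uniform(0, 2000, len(SPECIES))
            d = cell_rhs(c, profile, zone_factor=1.3, vol_ratio=5.0)
            v = reaction_rates(c, profile, zone_factor=1.3)
            expected = NET.N @ v
            expected[ck.N_INTRACELLULAR:] *= 5.0
            np.testing.assert_allclose(d, expected, rtol=1e-12, atol=1e-12)


class TestActivityConversion:
    def test_zero_activity_gives_zero_vmax(self):
        assert convert_specific_activity(0.0, 100.0) == 0.0

    def test_worked_unit_conversion(self):
        # 2 nmol/nmol/min on 0.1 nmol/mg microsomal content:
        # enzyme conc = 0.1 nmol/mg * 0.22 * 30 g/L = 660 nmol/L
        # Vmax = 2 * 0.660 umol/L/min = 1.32
        got = convert_specific_activity(2.0, 100.0, ActivityConversionSpec())
        assert got == pytest.approx(2.0 * 100.0 * 0.22 * 30.0 * 1e-3)
        assert got == pytest.approx(1.32)

    def test_linearity_in_content(self):
        assert convert_specific_activity(3.0, 50.0) * 2 == pytest.approx(
            convert_specific_activity(3.0, 100.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            convert_specific_activity(-1.0, 10.0)

    def test_conversion_spec_requires_positive_constants(self):
        with pytest.raises(ValueError):
            ActivityConversionSpec(total_cell_protein=0.0)


class TestEnzymeProfile:
    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            EnzymeProfile(vmax_ugt=-1.0)

    def test_km_must_be_positive_where_vmax_positive(self):
        with pytest.raises(ValueError):
            EnzymeProfile(vmax_ugt=1.0, km_ugt=0.0)

    def test_array_round_trip(self, profile):
        arr = profile.as_array()
        back = EnzymeProfile.from_array(arr)
        assert back == profile


class TestSimulateCell:
    def test_basal_state_is_a_fixed_point(self, profile, basal):
        traj = simulate_cell(basal, profile, exposure=0.0, duration=100.0)
        assert traj.success
        drift = np.abs(traj.concentrations - traj.concentrations[0]).max()
        assert drift < 1e-6 * profile.basal_gsh

    def test_sustained_overdose_h2o2_rises_after_gsh_collapse(self, profile, basal):
        traj = simulate_cell(basal, profile, exposure=6000.0, duration=1440.0,
                             n_out=400)
        assert traj.success
        gsh, h2o2 = traj["GSH"], traj["H2O2"]
        assert gsh[-1] < 0.1 * profile.basal_gsh
        # after the glutathione collapse H2O2 climbs monotonically
        i_collapse = np.nonzero(gsh < 0.1 * profile.basal_gsh)[0][0]
        tail = h2o2[i_collapse:]
        assert np.all(np.diff(tail) > -1e-6)
        assert tail[-1] > 100.0

    def test_subthreshold_exposure_leaves_gsh_buffered(self, profile, basal):
        traj = simulate_cell(basal, profile, exposure=1000.0, duration=1440.0)
        assert traj["GSH"][-1] > 0.3 * profile.basal_gsh
        assert traj["H2O2"].max() < 10.0

    def test_linear_regime_trajectory_scales_with_exposure(self, profile):
        # far below every Km the kinetics are linear in the drug species, so
        # halving the exposure halves the whole drug trajectory
        c0 = np.zeros(len(SPECIES))   # no GSH dynamics: isolate drug linearity
        c0[IDX["GSH"]] = profile.basal_gsh
        t1 = simulate_cell(c0, profile, exposure=1.0, duration=60.0,
                           rtol=1e-10, atol=1e-13)
        t2 = simulate_cell(c0, profile, exposure=0.5, duration=60.0,
                           rtol=1e-10, atol=1e-13)
        apap1, apap2 = t1["APAP_cyt"], t2["APAP_cyt"]
        mask = apap1 > 1e-4
        np.testing.assert_allclose(apap2[mask] / apap1[mask], 0.5, rtol=0.02)

    def test_nonnegativity_within_solver_tolerance(self, profile, basal):
        traj = simulate_cell(basal, profile, exposure=8000.0, duration=1440.0,
                             rtol=1e-6, atol=1e-8)
        assert traj.concentrations.min() > -1e-6

    def test_duration_must_be_positive(self, profile, basal):
        with pytest.raises(ValueError):
            simulate_cell(basal, profile, exposure=0.0, duration=0.0)
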