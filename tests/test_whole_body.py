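"""Whole-body PBPK model and the coupled co-simulation loop."""

import numpy as np
import pytest

from hepatosim.injury import InjuryParameters
from hepatosim.whole_body import (
    URINARY_CLEARANCE,
    BodyState,
    CompartmentSpec,
    DoseRegimen,
    compartment_rhs,
    default_compartments,
    gut_rhs,
    liver_rhs,
    lobule_to_liver_scale,
    make_pbpk_rhs,
    simulate,
)
from hepatosim.sinusoid_transport import SinusoidGeometry

COMPS = default_compartments()


class TestCompartmentTable:
    def test_reference_adult_values(self):
        expect = {
            "adipose": (0.56, 28.0, 0.25),
            "liver": (1.3, 1.82, 0.774),
            "wpt": (3.5, 5.68, 0.774),
            "ppt": (1.63, 35.0, 0.66),
            "blood": (6.4, 5.7, 0.774),
            "plasma": (6.4, 3.4, 0.774),
        }
        for name, (f, v, pc) in expect.items():
            c = COMPS[name]
            assert (c.flow, c.volume, c.pc) == (f, v, pc)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            CompartmentSpec("x", flow=1.0, volume=-1.0, pc=0.5)


class TestDoseRegimen:
    def test_oral_bolus_fraction_reaches_gut(self):
        r = DoseRegimen.single_oral(393.0, 73.0)
        # 393 mg/kg x 73 kg = 28,689 mg; 90% enters the gut
        assert r.administered_mg == pytest.approx(28_689.0)
        assert r.bolus_gut_amount(393.0) == pytest.approx(25_820.1)

    def test_gut_decays_exponentially_between_boluses(self):
        r = DoseRegimen.single_oral(100.0)
        state = BodyState.zero()
        state.q_gut = 1000.0
        assert gut_rhs(state, r, t=10.0) == pytest.approx(-0.025 * 1000.0)
        # analytic half-life ln 2 / k_gut ~ 27.7 min
        assert np.log(2) / r.k_gut == pytest.approx(27.73, abs=0.01)

    def test_zero_dose_keeps_gut_empty(self):
        r = DoseRegimen(doses=())
        s = BodyState.zero()
        assert gut_rhs(s, r, 0.0) == 0.0

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseRegimen(doses=((0.0, -5.0),))


class TestCompartmentRhs:
    def test_flow_equilibrium_is_fixed_point(self):
        spec = COMPS["adipose"]
        C_b = 3.0
        assert compartment_rhs(C_b * spec.pc, C_b, spec) == pytest.approx(0.0)

    def test_initial_uptake_rate(self):
        spec = COMPS["wpt"]
        assert compartment_rhs(0.0, 2.0, spec) == pytest.approx(
            spec.flow * 2.0 / spec.volume)

    def test_whole_body_flow_equilibrium_is_stationary(self):
        # C_i = C_b * PC_i with absorption and all elimination disabled
        rhs = make_pbpk_rhs(COMPS, DoseRegimen(doses=()), urinary_clearance=0.0)
        C_b = 5.0
        y = np.zeros(8)
        y[4] = C_b
        for i, name in enumerate(("adipose", "liver", "wpt", "ppt")):
            y[i] = C_b * COMPS[name].pc
        d = rhs(y, 0.0)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_tissue_exchange_conserves_mass_against_sinks(self):
        rhs = make_pbpk_rhs(COMPS, DoseRegimen(doses=()))
        rng = np.random.default_rng(0)
        V = np.array([COMPS[n].volume for n in ("adipose", "liver", "wpt", "ppt")])
        for _ in range(5):
            y = rng.uniform(0, 10, 8)
            elim = rng.uniform(0, 5)
            d = rhs(y, elim)
            d_burden = (d[:4] * V).sum() + d[4] * COMPS["blood"].volume
            # organs/blood only lose mass to urine, hepatic elimination and
            # gain it from the gut
            assert d_burden == pytest.approx(
                -URINARY_CLEARANCE * y[4] - elim + 0.025 * y[5], rel=1e-12)


class TestLiverRhs:
    def test_elimination_term_linear_in_clearance(self):
        r = DoseRegimen(doses=())
        scale = lobule_to_liver_scale(SinusoidGeometry(), COMPS["liver"])
        base = liver_rhs(1.0, 1.0, 0.0, 0.0, COMPS["liver"], r, scale)
        one = liver_rhs(1.0, 1.0, 0.0, 1e-8, COMPS["liver"], r, scale)
        two = liver_rhs(1.0, 1.0, 0.0, 2e-8, COMPS["liver"], r, scale)
        assert (base - two) == pytest.approx(2 * (base - one), rel=1e-9)

    def test_dead_lobule_reduces_to_flow_through(self):
        r = DoseRegimen(doses=())
        scale = lobule_to_liver_scale(SinusoidGeometry(), COMPS["liver"])
        spec = COMPS["liver"]
        d = liver_rhs(0.5, 1.0, 100.0, 0.0, spec, r, scale)
        expected = (spec.flow * (1.0 - 0.5 / spec.pc) + 0.025 * 100.0) / spec.volume
        assert d == pytest.approx(expected)

    def test_lobule_scale_maps_one_lobule_to_parenchyma(self):
        g = SinusoidGeometry()
        scale = lobule_to_liver_scale(g, COMPS["liver"])
        lobule_cell_vol = 384 * g.cell_volume
        assert scale == pytest.approx(0.8 * 1.82 / lobule_cell_vol)


class TestSimulate:
    def test_zero_dose_stays_at_rest(self):
        res = simulate(DoseRegimen(doses=()), duration=20.0, seed=0)
        assert res.final_viability == 1.0
        assert res.plasma.max() == 0.0
        assert res.metabolized[-1] == 0.0

    def test_plasma_curve_unimodal(self, calibrated):
        res = simulate(DoseRegimen.single_oral(100.0),
                       profile=calibrated.profile, injury=calibrated.injury,
                       duration=600.0, seed=0)
        i_max = int(np.argmax(res.plasma))
        rising = np.diff(res.plasma[: i_max + 1])
        falling = np.diff(res.plasma[i_max:])
        assert np.all(rising >= -1e-9)
        assert np.all(falling <= 1e-9)

    def test_dose_linearity_below_saturation(self, calibrated):
        r1 = simulate(DoseRegimen.single_oral(5.0), profile=calibrated.profile,
                      injury=calibrated.injury, duration=300.0, seed=0)
        r2 = simulate(DoseRegimen.single_oral(10.0), profile=calibrated.profile,
                      injury=calibrated.injury, duration=300.0, seed=0)
        assert r2.cmax == pytest.approx(2 * r1.cmax, rel=0.02)

    def test_mass_balance_within_tolerance(self, calibrated):
        res = simulate(DoseRegimen.single_oral(200.0),
                       profile=calibrated.profile, injury=calibrated.injury,
                       duration=400.0, seed=0)
        assert res.mass_balance_error < 1e-3

    def test_fixed_seed_bitwise_reproducible(self, calibrated):
        kw = dict(profile=calibrated.profile, injury=calibrated.injury,
                  duration=120.0, seed=11)
        a = simulate(DoseRegimen.single_oral(380.0), **kw)
        b = simulate(DoseRegimen.single_oral(380.0), **kw)
        np.testing.assert_array_equal(a.plasma, b.plasma)
        np.testing.assert_array_equal(a.viability, b.viability)
        assert a.events.equals(b.events)

    def test_cell_death_increases_exposure(self, calibrated):
        # paired comparison at a toxic dose: enabling necrosis removes
        # metabolising cells and weakly increases the plasma AUC
        no_death = InjuryParameters(h2o2_crit=1e12, hazard_scale=0.0)
        kw = dict(profile=calibrated.profile, duration=2000.0, seed=2)
        with_death = simulate(DoseRegimen.single_oral(420.0),
                              injury=calibrated.injury, **kw)
        without = simulate(DoseRegimen.single_oral(420.0),
                           injury=no_death, **kw)
        assert with_death.final_viability < 1.0
        auc_with = np.trapezoid(with_death.plasma, with_death.times)
        auc_without = np.trapezoid(without.plasma, without.times)
        assert auc_with >= auc_without

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate(DoseRegimen.single_oral(10.0), duration=0.0)
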