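import numpy as np
import pytest

from hgtrace.exposure import FOOD_GROUPS
from hgtrace.foodweb import consumption_matrix, mass_balance_residuals, trophic_levels
from hgtrace.synth import (
    SynthError,
    WebGenSpec,
    calibrate_to_background,
    calibrate_uptake,
    generate_consumer_profiles,
    generate_foodweb,
    generate_observations,
)
from hgtrace.tracer import ContaminantState, run_to_equilibrium
from hgtrace.validation import mo_ratio, nmb

from conftest import make_group, make_web


class TestGenerateFoodweb:
    def test_same_seed_is_deterministic(self):
        a = generate_foodweb(WebGenSpec(seed=7))
        b = generate_foodweb(WebGenSpec(seed=7))
        assert a.names == b.names
        np.testing.assert_array_equal(a.diet, b.diet)
        np.testing.assert_array_equal(a.biomass, b.biomass)
        c = generate_foodweb(WebGenSpec(seed=8))
        assert not np.array_equal(a.diet, c.diet)

    def test_chain_web_has_integer_trophic_levels(self):
        web = generate_foodweb(WebGenSpec(n_groups=5, n_producers=1, chain=True, seed=0))
        tl = trophic_levels(web)
        # detritus, producer, then a strict chain of three consumers
        np.testing.assert_allclose(tl, [1.0, 1.0, 2.0, 3.0, 4.0])

    @pytest.mark.parametrize("seed", range(0, 100, 1))
    def test_emitted_webs_balance_and_satisfy_invariants(self, seed):
        n = 6 + seed % 24
        web = generate_foodweb(WebGenSpec(n_groups=n, seed=seed))
        # FoodWebModel/FunctionalGroup invariants are enforced on build;
        # check the balance and the consumption identity on top
        resid = mass_balance_residuals(web)
        scale = np.maximum(web.biomass * web.production_rate, 1.0)
        assert np.max(np.abs(resid) / scale) < 1e-9
        q = consumption_matrix(web)
        np.testing.assert_allclose(
            q.sum(axis=1), web.biomass * web.consumption_rate, rtol=1e-12
        )

    def test_default_web_names_the_expected_guilds(self):
        web = generate_foodweb(WebGenSpec(seed=0))
        assert web.n_groups == 29
        for name in ("detritus", "copepods", "euphausiids", "shrimp",
                     "herring", "cod", "mackerel"):
            assert name in web.names
        flagged = {g.name for g in web.groups if g.direct_uptake}
        assert flagged == {
            "phytoplankton_diatoms", "phytoplankton_flagellates",
            "copepods", "euphausiids",
        }

    def test_infeasible_spec_rejected(self):
        with pytest.raises(SynthError):
            WebGenSpec(n_groups=2, n_producers=1)  # no room for a consumer
        with pytest.raises(SynthError):
            WebGenSpec(connectance=0.0)


class TestCalibrateUptake:
    def one_group_model(self):
        g = make_group("phyto", "producer", B=3.0, PB=10.0, EE=0.0,
                       direct_uptake=True)
        return make_web([g], [[0.0]])

    def test_single_group_closed_form(self):
        """For one compartment the solved clearance is u = 1000*c*e/C_w."""
        model = self.one_group_model()
        params = calibrate_uptake(model, {"phyto": 20.0}, excretion_rate=0.1,
                                  water_concentration=0.57)
        assert params.uptake_rates[0] == pytest.approx(
            1000.0 * 20.0 * 0.1 / 0.57, rel=1e-9
        )

    def test_zero_target_gives_zero_rate(self):
        model = self.one_group_model()
        params = calibrate_uptake(model, {"phyto": 0.0})
        assert params.uptake_rates[0] == 0.0

    def test_round_trip_recovers_targets(self):
        """Calibrating to an equilibrium reached under known rates recovers
        those concentrations within 1%."""
        web = generate_foodweb(WebGenSpec(n_groups=5, seed=3))
        from hgtrace.tracer import TracerParams

        u0 = np.where(web.direct_uptake_mask, 2.5, 0.0)
        ref = run_to_equilibrium(
            web, TracerParams(uptake_rates=u0),
            init=ContaminantState(0.0, 0.57, np.zeros(web.n_groups)),
        )
        targets = {
            name: float(c)
            for name, c, flagged in zip(
                web.names, ref.body_concentrations(web), web.direct_uptake_mask
            )
            if flagged
        }
        params = calibrate_uptake(web, targets)
        state = run_to_equilibrium(
            web, params, init=ContaminantState(0.0, 0.57, np.zeros(web.n_groups))
        )
        conc = state.body_concentrations(web)
        for i in np.flatnonzero(web.direct_uptake_mask):
            assert conc[i] == pytest.approx(targets[web.names[i]], rel=0.01)

    def test_missing_target_is_named(self):
        model = self.one_group_model()
        with pytest.raises(SynthError, match="phyto"):
            calibrate_uptake(model, {})

    def test_background_calibration_hits_the_requested_ceiling(self):
        web = generate_foodweb(WebGenSpec(seed=5))
        params = calibrate_to_background(web, max_commercial_muscle_mg_kg=0.15)
        state = run_to_equilibrium(web, params)
        conc = state.body_concentrations(web)
        fm = np.array([g.muscle_fraction for g in web.groups])
        commercial = np.array([g.commercial for g in web.groups])
        muscle_mg = conc * fm / 1e3
        assert muscle_mg[commercial].max() == pytest.approx(0.15, rel=1e-9)


class TestGenerateObservations:
    def test_no_bias_no_noise_gives_unit_mo_ratio(self):
        recs = generate_observations({"cod": 50.0, "herring": 20.0})
        for r in recs:
            assert mo_ratio(r) == pytest.approx(1.0)

    def test_unit_bias_no_noise_gives_unit_nmb(self):
        recs = generate_observations({"cod": 50.0, "herring": 20.0}, bias=1.0)
        pairs = [(r.modelled, o) for r in recs for o in r.observed]
        assert nmb(pairs) == pytest.approx(1.0, rel=1e-12)

    def test_same_seed_reproduces(self):
        a = generate_observations({"cod": 50.0}, noise_cv=0.3, seed=11)
        b = generate_observations({"cod": 50.0}, noise_cv=0.3, seed=11)
        assert a[0].observed == b[0].observed

    def test_noisy_bias_recovered_on_average(self):
        vals = []
        for seed in range(20):
            recs = generate_observations(
                {"cod": 50.0}, bias=0.5, noise_cv=0.2, n_studies=100, seed=seed
            )
            pairs = [(r.modelled, o) for r in recs for o in r.observed]
            vals.append(nmb(pairs))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


class TestConsumerProfiles:
    def test_four_labels_two_regimes_reproducible(self):
        a = generate_consumer_profiles(seed=2)
        b = generate_consumer_profiles(seed=2)
        assert a == b
        labels = {p.label for p in a}
        assert labels == {"men", "women", "children", "pregnant women"}
        assert len(a) == 8

    def test_recommended_intake_dominates_survey_intake(self):
        profiles = generate_consumer_profiles(seed=4)
        by_key = {(p.label, p.regime): p for p in profiles}
        for label in ("men", "women", "children", "pregnant women"):
            nhs = by_key[(label, "NHS")]
            ndns = by_key[(label, "NDNS")]
            for g in FOOD_GROUPS:
                assert nhs.weekly_intake_kg[g] >= ndns.weekly_intake_kg[g]
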