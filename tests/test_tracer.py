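import numpy as np
import pytest

from hgtrace.foodweb import consumption_matrix
from hgtrace.scenarios import ExposureScenario, build_preset
from hgtrace.tracer import (
    ContaminantState,
    EquilibriumError,
    TracerError,
    TracerParams,
    dynamics_rhs,
    run_scenario,
    run_to_equilibrium,
    timeseries_frame,
)

from conftest import make_group, make_web


def single_producer_web(B=3.0):
    g = make_group("phyto", "producer", B=B, PB=10.0, EE=0.0, direct_uptake=True)
    return make_web([g], [[0.0]])


def params_for(model, u=None, e=0.10, routing=False):
    rates = np.zeros(model.n_groups)
    if u is not None:
        for name, val in u.items():
            rates[model.index(name)] = val
    return TracerParams(uptake_rates=rates, excretion_rate=e,
                        detritus_routing=routing)


class TestDynamicsRhs:
    def test_origin_with_no_influx_is_stationary(self, chain3_web):
        p = params_for(chain3_web, u={"zoo": 1.0})
        state = ContaminantState(0.0, 0.0, np.zeros(3))
        dw, dpools = dynamics_rhs(state, chain3_web, p, 0.0)
        assert dw == 0.0
        np.testing.assert_array_equal(dpools, 0.0)

    def test_direct_uptake_flux_is_u_times_conc_times_biomass(self):
        web = single_producer_web(B=3.0)
        p = params_for(web, u={"phyto": 1.0}, e=0.0)
        state = ContaminantState(0.0, 2.0, np.zeros(1))
        _, dpools = dynamics_rhs(state, web, p, 0.0)
        assert dpools[0] == pytest.approx(6.0)  # u*C_w*B = 1*2*3 per km^2

    def test_closed_web_derivatives_sum_to_influx(self, chain3_web):
        p = params_for(chain3_web, u={"zoo": 2.0})
        state = ContaminantState(0.0, 0.57, np.array([10.0, 5.0, 1.0]))
        for influx in (0.0, 123.0):
            dw, dpools = dynamics_rhs(state, chain3_web, p, influx)
            total = dw + dpools.sum() * chain3_web.area
            assert total == pytest.approx(influx, abs=1e-6 * max(influx, 1.0))

    def test_dimension_mismatch_rejected(self, chain3_web):
        p = params_for(chain3_web)
        with pytest.raises(TracerError):
            dynamics_rhs(ContaminantState(0.0, 0.5, np.zeros(2)), chain3_web, p)

    def test_uptake_restricted_to_flagged_groups(self, chain3_web):
        with pytest.raises(TracerError, match="fish"):
            dynamics_rhs(
                ContaminantState(0.0, 0.5, np.zeros(3)),
                chain3_web,
                params_for(chain3_web, u={"fish": 1.0}),
            )


class TestEquilibrium:
    def test_single_compartment_closed_form(self):
        """Clamped equilibrium of one direct-uptake group is u*C_w*B/e."""
        web = single_producer_web(B=3.0)
        p = params_for(web, u={"phyto": 2.0}, e=0.10)
        state = run_to_equilibrium(
            web, p, init=ContaminantState(0.0, 0.57, np.zeros(1))
        )
        assert state.pools[0] == pytest.approx(2.0 * 0.57 * 3.0 / 0.10, rel=1e-10)

    def test_zero_sources_give_zero_state(self, chain3_web):
        p = params_for(chain3_web, u={"zoo": 1.0})
        state = run_to_equilibrium(
            chain3_web, p, init=ContaminantState(0.0, 0.0, np.zeros(3))
        )
        np.testing.assert_array_equal(state.pools, 0.0)

    def test_equilibrium_is_linear_in_water_concentration(self, chain3_web):
        p = params_for(chain3_web, u={"phyto": 0.5, "zoo": 1.0})
        s1 = run_to_equilibrium(
            chain3_web, p, init=ContaminantState(0.0, 0.57, np.zeros(3))
        )
        s2 = run_to_equilibrium(
            chain3_web, p, init=ContaminantState(0.0, 1.14, np.zeros(3))
        )
        np.testing.assert_allclose(
            s2.body_concentrations(chain3_web),
            2.0 * s1.body_concentrations(chain3_web),
            rtol=1e-9,
        )

    def test_unclamped_mode_converges_without_influx(self, chain3_web):
        p = params_for(chain3_web, u={"zoo": 1.0})
        state = run_to_equilibrium(
            chain3_web, p, background_influx_t_per_yr=0.0,
            init=ContaminantState(0.0, 0.57, np.zeros(3)),
            clamp_water=False, tol=1e-10,
        )
        dw, dpools = dynamics_rhs(state, chain3_web, p, 0.0)
        rel = np.abs(dpools) / np.maximum(state.pools, 1e-300)
        assert rel.max() < 1e-8

    def test_unclamped_nonconvergence_carries_last_state(self, chain3_web):
        p = params_for(chain3_web, u={"zoo": 1.0})
        with pytest.raises(EquilibriumError) as exc:
            run_to_equilibrium(
                chain3_web, p, background_influx_t_per_yr=0.0,
                init=ContaminantState(0.0, 0.57, np.zeros(3)),
                clamp_water=False, tol=1e-10, max_horizon_yr=20.0,
            )
        assert isinstance(exc.value.last_state, ContaminantState)
        assert exc.value.last_state.time > 0


class TestScenarioRuns:
    def test_pulse_raises_water_concentration_by_mass_over_volume(self, chain3_web):
        p = params_for(chain3_web)  # no uptake: water is inert
        sc = ExposureScenario(id="X", background_influx=0.0,
                              release_events=((5.0, 9.9),))
        states = run_scenario(
            chain3_web, p, sc, horizon_yr=10.0,
            init=ContaminantState(0.0, 0.57, np.zeros(3)),
        )
        v = chain3_web.water_volume_litres
        at5 = [s for s in states if s.time == 5.0][0]
        assert at5.water_concentration == pytest.approx(0.57 + 9.9e12 / v, rel=1e-12)

    def test_zero_release_scenario_stays_at_equilibrium(self, chain3_web):
        p = params_for(chain3_web, u={"phyto": 1e-3, "zoo": 1e-3})
        sc = ExposureScenario(id="A")
        states = run_scenario(chain3_web, p, sc, horizon_yr=50.0)
        c0 = states[0].body_concentrations(chain3_web)
        cN = states[-1].body_concentrations(chain3_web)
        np.testing.assert_allclose(cN, c0, rtol=1e-3)

    def test_larger_release_gives_larger_final_burdens(self, chain3_web):
        p = params_for(chain3_web, u={"phyto": 1e-3, "zoo": 1e-3})
        finals = []
        for mass in (0.07, 9.9, 72.93):
            sc = ExposureScenario(id="X", release_events=((10.0, mass),))
            states = run_scenario(chain3_web, p, sc, horizon_yr=40.0)
            finals.append(states[-1].body_concentrations(chain3_web))
        assert np.all(finals[1] >= finals[0])
        assert np.all(finals[2] >= finals[1])
        assert finals[2].max() > finals[0].max()

    def test_source_scaling_scales_every_pool(self, chain3_web):
        """The tracer system is linear: scaling C0, influx and release by c
        scales every pool by c."""
        p = params_for(chain3_web, u={"phyto": 1e-3, "zoo": 1e-3})
        def run(c):
            sc = ExposureScenario(
                id="X", initial_water_concentration=0.57 * c,
                background_influx=0.01 * c, release_events=((10.0, 9.9 * c),),
            )
            return run_scenario(chain3_web, p, sc, horizon_yr=30.0)
        s1, s3 = run(1.0), run(3.0)
        for a, b in zip(s1, s3):
            np.testing.assert_allclose(b.pools, 3.0 * a.pools, rtol=1e-9)
            assert b.water_concentration == pytest.approx(
                3.0 * a.water_concentration, rel=1e-9
            )

    def test_mass_conservation_along_trajectory(self, chain3_web):
        p = params_for(chain3_web, u={"phyto": 1e-3, "zoo": 1e-3})
        sc = build_preset("C")
        states = run_scenario(chain3_web, p, sc, horizon_yr=80.0)
        m0 = states[0].total_mass_ug(chain3_web)
        for s in states:
            influx_cum = sc.background_influx * 1e12 * min(s.time, 50.0)
            influx_cum += (sc.post_release_influx or 0.0) * 1e12 * max(s.time - 50.0, 0.0)
            released = 9.9e12 if s.time >= 50.0 else 0.0
            expected = m0 + influx_cum + released
            assert s.total_mass_ug(chain3_web) == pytest.approx(expected, rel=1e-9)

    def test_nonnegativity_under_nonnegative_forcing(self, chain3_web):
        p = params_for(chain3_web, u={"phyto": 10.0, "zoo": 10.0}, e=0.9)
        sc = ExposureScenario(id="X", release_events=((3.0, 72.93),))
        states = run_scenario(chain3_web, p, sc, horizon_yr=20.0)
        for s in states:
            assert s.water_concentration >= 0
            assert np.all(s.pools >= 0)

    def test_negative_release_and_out_of_horizon_rejected(self, chain3_web):
        p = params_for(chain3_web)
        with pytest.raises(Exception):
            run_scenario(
                chain3_web, p,
                ExposureScenario(id="X", release_events=((5.0, -1.0),)), 10.0,
            )
        with pytest.raises(TracerError, match="horizon"):
            run_scenario(
                chain3_web, p,
                ExposureScenario(id="X", release_events=((50.0, 1.0),)), 10.0,
            )


def test_detritus_routing_moves_mortality_into_detritus_pool():
    det = make_group("detritus", "detritus", B=10.0, PB=0.0, EE=0.0)
    prod = make_group("phyto", "producer", B=10.0, PB=20.0, EE=0.5,
                      direct_uptake=True)
    web = make_web([det, prod], [[0, 0], [0, 0]])
    p_off = TracerParams(uptake_rates=np.array([0.0, 1.0]), detritus_routing=False)
    p_on = TracerParams(uptake_rates=np.array([0.0, 1.0]), detritus_routing=True)
    init = ContaminantState(0.0, 0.57, np.zeros(2))
    s_off = run_to_equilibrium(web, p_off, init=init)
    s_on = run_to_equilibrium(web, p_on, init=init)
    assert s_off.pools[0] == 0.0
    assert s_on.pools[0] > 0.0  # PB*(1-EE) flux lands in detritus


def test_timeseries_frame_is_tidy(chain3_web):
    p = params_for(chain3_web, u={"zoo": 1e-3})
    states = run_scenario(chain3_web, p, ExposureScenario(id="A"), 5.0)
    df = timeseries_frame(states, chain3_web)
    assert set(df.columns) == {
        "time_yr", "compartment", "pool_ug", "body_conc_ug_per_kg",
        "water_conc_ug_per_L",
    }
    assert set(df["compartment"]) == {"water", "phyto", "zoo", "fish"}
    assert len(df) == len(states) * 4


def test_params_yaml_round_trip(tmp_path, chain3_web):
    p = params_for(chain3_web, u={"phyto": 0.5, "zoo": 1.5}, e=0.2)
    path = tmp_path / "tracer.yaml"
    p.to_yaml(path, chain3_web)
    back = TracerParams.from_yaml(path, chain3_web)
    np.testing.assert_allclose(back.uptake_rates, p.uptake_rates)
    assert back.excretion_rate == p.excretion_rate
    assert back.detritus_routing == p.detritus_routing
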