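"""Palmer Drought Severity Index engine: water balance, CAFEC, K, recursion."""

import numpy as np
import pandas as pd
import pytest

import droughtwue as dw
from droughtwue.pdsi import (SoilWaterState, annual_mean_pdsi,
                             cafec_precipitation, run_water_balance)


def _state(ss=25.4, su=127.0, awc=152.4):
    return SoilWaterState(ss=ss, su=su, awc=awc)


class TestWaterBalanceStep:
    def test_exact_supply_balance(self):
        state, terms = dw.water_balance_step(_state(10.0, 60.0), p=30.0, pe=30.0)
        assert terms["et"] == 30.0
        assert terms["r"] == terms["ro"] == terms["l"] == 0.0
        assert state.ss == 10.0 and state.su == 60.0

    def test_palmer_two_layer_loss_arithmetic(self):
        # hand arithmetic: pl_s=25.4, pl_u=(50.8-25.4)*127/152.4=21.1667
        state, terms = dw.water_balance_step(_state(), p=0.0, pe=50.8)
        assert terms["pl"] == pytest.approx(25.4 + 21.16666667, abs=1e-6)
        assert terms["et"] == pytest.approx(46.56666667, abs=1e-6)
        assert state.ss == 0.0
        assert state.su == pytest.approx(127.0 - 21.16666667, abs=1e-6)

    def test_saturated_overflow_runs_off(self):
        state, terms = dw.water_balance_step(_state(25.4, 127.0), p=60.0, pe=50.0)
        assert terms["ro"] == pytest.approx(10.0)
        assert terms["r"] == 0.0

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            SoilWaterState(ss=30.0, su=10.0, awc=152.4)

    def test_mass_balance_over_random_forcing(self):
        rng = np.random.default_rng(3)
        state = SoilWaterState.full(152.4)
        for _ in range(500):
            p = rng.uniform(0, 120)
            pe = rng.uniform(0, 120)
            before = state.ss + state.su
            state, t = dw.water_balance_step(state, p, pe)
            # conservation: ET already contains the storage loss L
            closure = p - t["et"] - t["ro"] - (state.ss + state.su - before)
            assert abs(closure) < 1e-6
            assert 0 <= state.ss <= state.surface_capacity + 1e-9
            assert 0 <= state.su <= state.awc - state.surface_capacity + 1e-9
            assert t["et"] <= t["pe"] + 1e-9 and t["l"] <= t["pl"] + 1e-9
            assert t["r"] <= t["pr"] + 1e-9 and all(v >= 0 for v in t.values())


@pytest.fixture(scope="module")
def balance_terms():
    climate, _, _ = dw.generate_location(dw.DEFAULT_REGIMES["semi_arid_sub_humid"],
                                         10, seed=11)
    pet = dw.penman_pet(climate)
    return run_water_balance(climate.data["precip"], pet.pet)


class TestCafec:
    def test_alpha_one_when_et_equals_pe(self):
        idx = pd.period_range("2000-01", periods=24, freq="M")
        pe = pd.Series(np.full(24, 40.0), index=idx)
        p = pd.Series(np.full(24, 80.0), index=idx)  # always wet: et = pe
        terms = run_water_balance(p, pe)
        coeffs = dw.calibrate_cafec(terms)
        np.testing.assert_allclose(coeffs["alpha"].to_numpy(), 1.0)
        # full stores and p > pe forever: no loss ever, delta = 0 by convention
        np.testing.assert_allclose(coeffs["delta"].to_numpy(), 0.0)

    def test_mean_cafec_precip_equals_mean_precip(self, balance_terms):
        coeffs = dw.calibrate_cafec(balance_terms)
        phat = cafec_precipitation(balance_terms, coeffs)
        months = balance_terms.index.month
        np.testing.assert_allclose(
            phat.groupby(months).mean().to_numpy(),
            balance_terms["p"].groupby(months).mean().to_numpy(), atol=1e-9)

    def test_departure_mean_zero_and_linearity(self, balance_terms):
        coeffs = dw.calibrate_cafec(balance_terms)
        d = dw.moisture_departure(balance_terms, coeffs)
        assert d.groupby(d.index.month).mean().abs().max() < 1e-9
        bumped = balance_terms.copy()
        bumped["p"] = bumped["p"] + 5.0
        d2 = dw.moisture_departure(bumped, coeffs)
        np.testing.assert_allclose(d2.to_numpy() - d.to_numpy(), 5.0, atol=1e-9)

    def test_empty_window_rejected(self, balance_terms):
        with pytest.raises(ValueError):
            dw.calibrate_cafec(balance_terms.iloc[:6])


class TestClimaticCharacteristic:
    def test_normalisation_and_positivity(self, balance_terms):
        coeffs = dw.calibrate_cafec(balance_terms)
        d = dw.moisture_departure(balance_terms, coeffs)
        k = dw.climatic_characteristic(d, coeffs)
        assert float((k["dbar"] * k["k"]).sum()) == pytest.approx(17.67, abs=1e-9)
        assert (k["k"] > 0).all()

    def test_halving_departures_raises_k_prime(self, balance_terms):
        coeffs = dw.calibrate_cafec(balance_terms)
        d = dw.moisture_departure(balance_terms, coeffs)
        k_full = dw.climatic_characteristic(d, coeffs)
        k_half = dw.climatic_characteristic(d * 0.5, coeffs)
        assert (k_half["k_prime"].to_numpy() > k_full["k_prime"].to_numpy()).all()

    def test_z_index_sign_and_calibration_mean(self, balance_terms):
        coeffs = dw.calibrate_cafec(balance_terms)
        d = dw.moisture_departure(balance_terms, coeffs)
        k = dw.climatic_characteristic(d, coeffs)
        z = dw.z_index(d, k)
        assert np.all(np.sign(z.to_numpy()) == np.sign(d.to_numpy()))
        assert z.groupby(z.index.month).mean().abs().max() < 1e-9


class TestRecursion:
    def test_zero_z_is_fixed_point(self):
        tracks = dw.pdsi_recursion(np.zeros(60))
        assert (tracks[["x1", "x2", "x3", "pdsi"]].to_numpy() == 0).all()

    def test_constant_z_geometric_fixed_point(self):
        tracks = dw.pdsi_recursion(np.full(200, -0.927))
        assert tracks["pdsi"].iloc[-1] == pytest.approx(-3.0, abs=1e-6)
        tracks_wet = dw.pdsi_recursion(np.full(200, 0.927))
        assert tracks_wet["pdsi"].iloc[-1] == pytest.approx(3.0, abs=1e-6)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1.5, 300)
        a = dw.pdsi_recursion(z)
        b = dw.pdsi_recursion(-z)
        np.testing.assert_allclose(a["pdsi"].to_numpy(), -b["pdsi"].to_numpy(),
                                   atol=1e-10)
        np.testing.assert_allclose(a["x1"].to_numpy(), -b["x2"].to_numpy(),
                                   atol=1e-10)

    def test_track_bounds_and_membership(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 2.0, 600)
        tracks = dw.pdsi_recursion(z)
        assert (tracks["x1"].to_numpy() >= 0).all()
        assert (tracks["x2"].to_numpy() <= 0).all()
        member = np.isclose(
            tracks["pdsi"].to_numpy()[:, None],
            tracks[["x1", "x2", "x3"]].to_numpy(), atol=1e-12).any(axis=1)
        assert member.all()
        assert ((tracks["spell_prob"] >= 0) & (tracks["spell_prob"] <= 100)).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            dw.pdsi_recursion(np.array([0.1, np.nan, 0.2]))


@pytest.fixture(scope="module")
def climate():
    c, _, _ = dw.generate_location(dw.DEFAULT_REGIMES["semi_arid_sub_humid"],
                                   30, seed=23)
    return c


class TestComputePdsi:
    def test_deterministic(self, climate):
        a = dw.compute_pdsi(climate)
        b = dw.compute_pdsi(climate)
        pd.testing.assert_frame_equal(a.monthly, b.monthly)

    def test_drought_years_produce_minimum_pdsi(self, climate):
        data = climate.data.copy()
        years = data.index.year
        mask = (years >= 1992) & (years <= 1996)  # years 11..15 of 1982-2011
        data.loc[mask, "precip"] *= 0.5
        dry = dw.ClimateSeries(data, elevation=climate.elevation)
        annual = dw.compute_pdsi(dry).annual
        assert annual.idxmin() in range(1992, 1998)
        assert annual.loc[1992:1996].mean() < 0

    def test_uniform_drying_never_raises_pdsi(self, climate):
        est = dw.PalmerDroughtIndex().fit(climate)
        base = est.transform(climate).annual
        data = climate.data.copy()
        data["precip"] *= 0.8
        drier = est.transform(dw.ClimateSeries(data, elevation=climate.elevation)).annual
        assert (drier.to_numpy() <= base.to_numpy() + 1e-9).all()

    def test_short_record_warns(self):
        c, _, _ = dw.generate_location(dw.DEFAULT_REGIMES["arid"], 5, seed=2)
        with pytest.warns(UserWarning, match="10 years"):
            dw.compute_pdsi(c)

    def test_annual_mean_requires_complete_years(self, climate):
        series = dw.compute_pdsi(climate)
        trimmed = series.monthly.iloc[:-3]
        annual = annual_mean_pdsi(trimmed)
        assert 2011 not in annual.index
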