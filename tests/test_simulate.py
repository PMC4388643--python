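"""Synthetic calorimeter: closed-form limits, conservation, determinism."""

import numpy as np
import pytest

import itckinetics as ik
from itckinetics.simulate import (
    _first_order_lag,
    make_default_lsa_params,
    make_enhanced_lsa_params,
)

from .conftest import TRUE_DELTA_H, TRUE_E0, TRUE_KM


def _no_injection_params(**overrides):
    defaults = dict(
        kcat=0.234,
        km=10.0,
        e0=1.39,
        delta_h=-25040.0,
        cell=ik.CellConfig(volume=200.0, enzyme_conc=1.39),
        schedule=ik.InjectionSchedule(events=[]),
        s0=1000.0,
        duration=600.0,
        instrument_tau=0.0,
    )
    defaults.update(overrides)
    return ik.SimulationParams(**defaults)


class TestSimulateCell:
    def test_no_enzyme_gives_staircase_and_zero_power(self):
        params = make_default_lsa_params("multi_lsa", e0=0.0, noise_sd=0.0)
        traj = ik.simulate_cell(params)
        assert np.all(traj.ideal_power == 0.0)
        # S rises by ~5 μM per injection (less displacement of prior S)
        final = traj.substrate[-1]
        assert 30 * 5.0 * 0.85 < final < 30 * 5.0
        # piecewise constant: S only changes at injections
        changes = np.flatnonzero(np.diff(traj.substrate) != 0)
        assert len(changes) == 30

    def test_zero_order_limit(self):
        """S0 ≫ Km: S(t) = S0 − Vmax·t and constant power."""
        params = _no_injection_params(s0=1000.0, km=10.0, duration=600.0)
        traj = ik.simulate_cell(params)
        vmax = params.kcat * params.e0
        check_t = np.linspace(0, 500, 10)
        idx = np.searchsorted(traj.time, check_t)
        expected = params.s0 - vmax * traj.time[idx] / (1 + 10.0 / 1000.0)  # loose form
        # exact zero-order prediction, tolerance covers the Km/S0 correction
        np.testing.assert_allclose(
            traj.substrate[idx], params.s0 - vmax * traj.time[idx], rtol=7e-3
        )
        expected_power = -vmax * 200.0 * 25040.0 * 1e-6
        np.testing.assert_allclose(traj.ideal_power[idx], expected_power, rtol=2e-2)

    def test_first_order_limit(self):
        """S0 ≪ Km: exponential decay with k = kcat·E0/Km."""
        params = _no_injection_params(s0=0.5, km=TRUE_KM, e0=TRUE_E0, duration=600.0)
        traj = ik.simulate_cell(params)
        k = 0.234 * TRUE_E0 / TRUE_KM
        assert k == pytest.approx(5.737e-3, rel=1e-3)
        expected = 0.5 * np.exp(-k * traj.time)
        np.testing.assert_allclose(traj.substrate, expected, rtol=1.2e-2)

    def test_conservation_s_plus_p(self):
        params = make_default_lsa_params("multi_lsa", noise_sd=0.0)
        traj = ik.simulate_cell(params)
        err = np.abs(traj.substrate + traj.product - traj.s_total)
        assert err.max() < 1e-6

    def test_substrate_monotone_without_injections(self):
        traj = ik.simulate_cell(_no_injection_params(s0=100.0))
        assert np.all(np.diff(traj.substrate) <= 1e-12)

    def test_heat_bookkeeping(self):
        """Total heat equals ΔH·V·converted moles within 0.1% (τ=0, no noise)."""
        params = _no_injection_params(s0=50.0, km=TRUE_KM, duration=4000.0)
        traj = ik.simulate_cell(params)
        heat = np.trapezoid(traj.ideal_power, traj.time)  # μcal
        converted = traj.product[-1]  # μM, no dilution events
        expected = converted * 200.0 * (-25040.0) * 1e-6
        assert heat == pytest.approx(expected, rel=1e-3)

    def test_lag_redistributes_but_conserves_heat(self):
        params = _no_injection_params(s0=50.0, km=TRUE_KM, duration=4000.0)
        traj = ik.simulate_cell(params)
        for tau in (2.0, 6.0, 12.0):
            lagged = _first_order_lag(traj.ideal_power, params.internal_dt, tau)
            h0 = np.trapezoid(traj.ideal_power, traj.time)
            h1 = np.trapezoid(lagged, traj.time)
            assert h1 == pytest.approx(h0, rel=1e-3)


class TestRenderThermogram:
    def test_tau_zero_noise_zero_is_resampled_identity(self):
        params = make_default_lsa_params(
            "multi_lsa", instrument_tau=0.0, noise_sd=0.0, baseline_offset=0.0
        )
        traj = ik.simulate_cell(params)
        tg = ik.render_thermogram(traj, params)
        idx = np.searchsorted(traj.time, tg.time)
        np.testing.assert_array_equal(tg.power, traj.ideal_power[idx])

    def test_step_response_closed_form(self):
        """First-order lag of a step reaches 63.21% at t = τ."""
        dt, tau, p0 = 0.5, 6.0, -2.0
        x = np.full(200, p0)  # step applied at t=0, instrument starts at rest
        y = _first_order_lag(x, dt, tau)
        # input p0 held over (0, t]; at t=τ (sample 12): 1−e⁻¹ = 0.6321
        t_idx = int(tau / dt)
        assert y[t_idx] == pytest.approx(p0 * 0.6321, rel=1e-3)

    def test_seed_determinism(self):
        params = make_default_lsa_params("multi_lsa", noise_sd=0.01, seed=1234)
        tg1 = ik.render_thermogram(ik.simulate_cell(params), params)
        tg2 = ik.render_thermogram(ik.simulate_cell(params), params)
        np.testing.assert_array_equal(tg1.power, tg2.power)

    def test_different_seeds_differ(self):
        p1 = make_default_lsa_params("multi_lsa", noise_sd=0.01, seed=1)
        p2 = make_default_lsa_params("multi_lsa", noise_sd=0.01, seed=2)
        t1 = ik.render_thermogram(ik.simulate_cell(p1), p1)
        t2 = ik.render_thermogram(ik.simulate_cell(p2), p2)
        assert not np.array_equal(t1.power, t2.power)

    def test_baseline_offset_and_drift(self):
        params = make_default_lsa_params(
            "multi_lsa", e0=0.0, noise_sd=0.0, baseline_offset=2.0, baseline_drift=3.6
        )
        tg = ik.render_thermogram(ik.simulate_cell(params), params)
        np.testing.assert_allclose(tg.power, 2.0 + 3.6 * tg.time / 3600.0, rtol=1e-12)


class TestDefaultParams:
    def test_encodes_reference_estimates(self):
        params = make_default_lsa_params()
        assert params.km == TRUE_KM
        assert params.e0 == TRUE_E0
        assert params.delta_h == TRUE_DELTA_H
        assert len(params.schedule) == 30
        assert params.instrument_tau == 6.0
        assert params.noise_sd == 0.01
        assert params.sample_interval == 5.0

    def test_single_protocol(self):
        params = make_default_lsa_params("single_lsa")
        assert len(params.schedule) == 2
        assert params.schedule.events[0].volume == 5.0

    def test_enhanced_design_exceeds_saturation(self):
        params = make_enhanced_lsa_params("multi", noise_sd=0.0)
        traj = ik.simulate_cell(params)
        assert traj.substrate.max() > 5 * params.km


class TestSimulateAbsorbance:
    def test_beer_lambert_scale(self):
        """1 μM of product at ε = 36,000 gives ΔA = 0.036."""
        sim = ik.AbsorbanceSimulation(
            kcat=3382.0, km=65.0, e0=1e-4, assay=ik.ABTS_ASSAY,
            substrate_concs=(500.0,), duration=40.0,
        )
        (trace,) = ik.simulate_absorbance(sim)
        # invert: product = A/(ε·l)
        product = trace.absorbance / (36000.0 * 1.0) * 1e6
        assert trace.absorbance[0] == 0.0
        rate0 = 3382.0 * 1e-4 * 500.0 / (65.0 + 500.0)
        assert (product[5] - product[0]) / trace.time[5] == pytest.approx(rate0, rel=0.02)
        assert ik.ABTS_ASSAY.extinction_coefficient == 36000.0
        assert ik.DMP_ASSAY.extinction_coefficient == 49600.0

    def test_zero_enzyme_flat_trace(self):
        sim = ik.AbsorbanceSimulation(
            kcat=3382.0, km=65.0, e0=0.0, assay=ik.ABTS_ASSAY,
            substrate_concs=(100.0,), a0=0.05,
        )
        (trace,) = ik.simulate_absorbance(sim)
        np.testing.assert_array_equal(trace.absorbance, 0.05)
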