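"""Enthalpy calibration, rate extraction, substrate trajectory, rate curve."""

import numpy as np
import pytest

import itckinetics as ik
from itckinetics import ExclusionPolicy, IncompleteConversionError, ValidationError
from itckinetics.itc import power_to_rate

from .conftest import TRUE_DELTA_H, TRUE_KM, TRUE_VMAX, mm_rate


def _tg(power, dt=5.0):
    power = np.asarray(power, dtype=float)
    return ik.Thermogram(
        time=np.arange(power.size) * dt, power=power, sample_interval=dt
    )


CELL = ik.CellConfig(volume=200.0, enzyme_conc=1.39)


class TestEstimateDeltaH:
    def _pulse_run(self):
        """One 5 μL × 100 μM injection at t=100 s, −1 μcal/s for 100 s."""
        power = np.zeros(200)
        power[21:41] = -1.0  # 105..200 s; trapezoid over the ramps gives -100 μcal
        tg = _tg(power)
        sched = ik.InjectionSchedule(events=[(100.0, 5.0, 100.0)])
        return tg, sched

    def test_rectangular_pulse_hand_division(self):
        """−1.0e−4 cal over a fully-displaced 5 μL bolus: −2.0513×10⁵ cal/mol."""
        tg, sched = self._pulse_run()
        est = ik.estimate_delta_h_app(tg, sched, CELL, bolus_displacement="full")
        assert est.converted_moles == pytest.approx(4.875e-10, rel=1e-12)
        assert est.delta_h_app == pytest.approx(-1e-4 / 4.875e-10, rel=1e-9)
        assert est.delta_h_app == pytest.approx(-2.0513e5, rel=1e-4)

    def test_bolus_conventions(self):
        tg, sched = self._pulse_run()
        naive = ik.estimate_delta_h_app(tg, sched, CELL, bolus_displacement="none")
        half = ik.estimate_delta_h_app(tg, sched, CELL, bolus_displacement="half")
        assert naive.converted_moles == pytest.approx(5e-10)
        assert half.converted_moles == pytest.approx(5e-10 * (1 - 5.0 / 400.0))

    def test_zero_heat_gives_zero_enthalpy(self):
        tg = _tg(np.zeros(300))
        sched = ik.InjectionSchedule(events=[(100.0, 5.0, 100.0)])
        est = ik.estimate_delta_h_app(tg, sched, CELL)
        assert est.delta_h_app == 0.0

    def test_incomplete_conversion_rejected(self):
        """Power still deflected at the next injection is an error."""
        power = np.full(400, -0.5)
        power[:30] = 0.0
        tg = _tg(power)
        sched = ik.InjectionSchedule(events=[(200.0, 5.0, 100.0), (1200.0, 5.0, 100.0)])
        with pytest.raises(IncompleteConversionError):
            ik.estimate_delta_h_app(tg, sched, CELL)

    def test_single_lsa_round_trip_within_2pct(self, delta_h_noise_free):
        est = delta_h_noise_free
        assert est.delta_h_app == pytest.approx(TRUE_DELTA_H, rel=0.02)
        assert len(est.per_injection) == 2
        for per in est.per_injection:
            assert per == pytest.approx(TRUE_DELTA_H, rel=0.02)


class TestPowerToRate:
    def test_arithmetic_example(self):
        tg = _tg([-0.501, -0.501, -0.501])
        rate = power_to_rate(tg, -25040.0, ik.CellConfig(volume=200.0))
        assert rate[0] == pytest.approx(0.10004, rel=1e-4)

    def test_zero_power_zero_rate(self):
        rate = power_to_rate(_tg(np.zeros(10)), -25040.0, CELL)
        np.testing.assert_array_equal(rate, 0.0)

    def test_even_under_joint_sign_flip(self):
        tg_neg = _tg([-0.5, -0.4, -0.3])
        tg_pos = _tg([0.5, 0.4, 0.3])
        r1 = power_to_rate(tg_neg, -25040.0, CELL)
        r2 = power_to_rate(tg_pos, 25040.0, CELL)
        np.testing.assert_array_equal(r1, r2)

    def test_zero_delta_h_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            power_to_rate(_tg([0.0, 0.0]), 0.0, CELL)


class TestSubstrateTrajectory:
    def test_pre_injection_substrate_is_zero(self, multi_rate_curve):
        traj, _ = multi_rate_curve
        pre = traj[traj["time_s"] < 250.0]
        assert np.abs(pre["S_uM"].to_numpy()).max() < 1e-12

    def test_substrate_returns_to_zero_at_completion(self, multi_rate_curve):
        traj, _ = multi_rate_curve
        assert traj["S_uM"].iloc[-1] < 0.05 * traj["S_total_uM"].iloc[-1]

    def test_conservation_exact(self, multi_rate_curve):
        """[S] + [P] = [S]_total by construction (clip-adjusted at the tail)."""
        traj, _ = multi_rate_curve
        gap = traj["S_uM"] + traj["P_uM"] - traj["S_total_uM"]
        tol = traj.attrs["clip_tolerance_uM"]
        assert np.abs(gap).max() <= tol + 1e-12

    def test_rate_integral_matches_product_between_injections(self, multi_rate_curve):
        """Eq-2 rates integrate to the Eq-3 product within each segment."""
        traj, _ = multi_rate_curve
        t = traj["time_s"].to_numpy()
        rate = traj["rate_uM_per_s"].to_numpy()
        p = traj["P_uM"].to_numpy()
        inj = traj["injection_idx"].to_numpy()
        for j in range(0, 29):
            seg = np.flatnonzero(inj == j)[1:]  # skip the injection sample itself
            if seg.size < 3:
                continue
            dp = np.trapezoid(rate[seg], t[seg])
            assert dp == pytest.approx(p[seg[-1]] - p[seg[0]], abs=1e-9)

    def test_half_heat_gives_half_substrate(self):
        """When cumulative heat is half of ΔH·V·[S]_total, [S] = [S]_total/2."""
        # single bolus converting linearly: constant power pulse
        power = np.zeros(400)
        power[21:41] = -1.0  # trapezoid over 100..200 s gives -100 μcal
        tg = _tg(power)
        # pick bolus so that total heat exactly converts it: moles = Q/ΔH
        moles = -100e-6 / TRUE_DELTA_H  # mol
        conc = moles / (200.0 * 1e-12)  # μM in the cell
        vol = 1.0
        sched = ik.InjectionSchedule(events=[(100.0, vol, conc * 200.0 / vol)])
        traj = ik.substrate_trajectory(
            tg, TRUE_DELTA_H, sched, ik.CellConfig(volume=200.0),
            terminal_calibration="never",
        )
        s_tot = traj["S_total_uM"].iloc[-1]
        # cumulative heat is piecewise linear, so interpolate to the exact
        # half-heat time (152.5 s: 2.5 μcal in the opening ramp + 47.5 after)
        s_half = np.interp(152.5, traj["time_s"], traj["S_uM"])
        assert s_half == pytest.approx(s_tot / 2, rel=1e-9)
        assert traj["S_uM"].iloc[-1] == pytest.approx(0.0, abs=1e-6)

    def test_wrong_sign_delta_h_raises(self, multi_run_noise_free):
        params, tg, _ = multi_run_noise_free
        baseline = ik.fit_baseline(tg, params.schedule)
        corrected = ik.correct(tg, baseline)
        with pytest.raises(ValidationError):
            ik.substrate_trajectory(
                corrected, -TRUE_DELTA_H, params.schedule, params.cell
            )


class TestBuildRateCurve:
    def test_six_retained_points_per_interval(self, multi_rate_curve):
        """settle = max(5τ, 20) = 30 s leaves samples at +30..55 s of each 60 s gap."""
        _, rc = multi_rate_curve
        retained = rc.retained
        for j in range(0, 29):
            n = (retained["injection_idx"] == j).sum()
            assert n == 6, f"interval {j} retained {n} points"

    def test_no_exclusion_policy_retains_everything_after_first_injection(
        self, multi_rate_curve
    ):
        traj, _ = multi_rate_curve
        sched = ik.load_protocol("multi_lsa")
        rc = ik.build_rate_curve(
            traj,
            sched,
            ExclusionPolicy(settle_window=0.0, edge_points=0, drop_negative_rates=False),
        )
        after = rc.data[rc.data["time_s"] >= 250.0]
        assert bool(after["retained"].all())

    def test_rate_monotone_in_substrate_during_decay(self, multi_rate_curve):
        """After the last injection the retained (S, rate) pairs follow MM."""
        _, rc = multi_rate_curve
        tail = rc.retained[rc.retained["time_s"] > 2030.0]
        s = tail["S_uM"].to_numpy()
        r = tail["rate_uM_per_s"].to_numpy()
        assert np.all(np.diff(s) <= 0)
        # rates non-increasing as S falls (allow tiny numerical wiggle)
        assert np.all(np.diff(r) <= 1e-5)

    def test_all_points_excluded_raises(self, multi_rate_curve):
        traj, _ = multi_rate_curve
        sched = ik.load_protocol("multi_lsa")
        with pytest.raises(ValidationError, match="every sample"):
            ik.build_rate_curve(traj, sched, ExclusionPolicy(settle_window=1e5))


class TestEndToEnd:
    def test_retained_rates_match_simulator_within_2pct(
        self, multi_run_noise_free, multi_rate_curve
    ):
        params, _, sim_traj = multi_run_noise_free
        _, rc = multi_rate_curve
        pts = rc.retained
        idx = np.searchsorted(sim_traj.time, pts["time_s"].to_numpy())
        true_rate = (
            params.kcat
            * sim_traj.enzyme[idx]
            * sim_traj.substrate[idx]
            / (params.km + sim_traj.substrate[idx])
        )
        # compare the measured (not dilution-normalized) rates where the
        # signal is appreciable
        measured = pts["rate_measured_uM_per_s"].to_numpy()
        strong = true_rate > 0.05 * TRUE_VMAX
        rel = measured[strong] / true_rate[strong] - 1
        assert np.max(np.abs(rel)) < 0.02

    def test_scale_equivariance(self):
        """Doubling cell and injection volumes leaves the rate curve unchanged."""

        def run(scale):
            sched = ik.InjectionSchedule(
                events=[(250.0 + 60 * i, 1.0 * scale, 1000.0) for i in range(10)]
            )
            params = ik.make_default_lsa_params(
                "multi_lsa",
                schedule=sched,
                cell=ik.CellConfig(volume=200.0 * scale, enzyme_conc=1.39),
                noise_sd=0.0,
                duration=2650.0,
            )
            tg, _ = ik.simulate_experiment(params)
            corrected = ik.deconvolve_tian(
                ik.correct(tg, ik.fit_baseline(tg, sched)), 6.0
            )
            traj = ik.substrate_trajectory(
                corrected, TRUE_DELTA_H, sched, params.cell,
                terminal_calibration="never",
            )
            return ik.build_rate_curve(traj, sched, ExclusionPolicy(tau=6.0))

        rc1, rc2 = run(1.0), run(2.0)
        np.testing.assert_allclose(rc1.points, rc2.points, rtol=1e-7, atol=1e-12)

    def test_km_round_trip_noise_free(self, multi_rate_curve):
        _, rc = multi_rate_curve
        fit = ik.fit_michaelis_menten(rc)
        assert fit.km == pytest.approx(TRUE_KM, rel=0.05)
        assert fit.vmax == pytest.approx(TRUE_VMAX, rel=0.05)
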