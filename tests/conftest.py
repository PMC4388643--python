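import numpy as np
import pytest

import itckinetics as ik

# Generating constants of the packaged lignosulfonic-acid parameter set.
TRUE_KCAT = 0.234
TRUE_KM = 56.7
TRUE_E0 = 1.39
TRUE_VMAX = TRUE_KCAT * TRUE_E0
TRUE_DELTA_H = -25040.0


@pytest.fixture(scope="session")
def single_run_noise_free():
    """Noise-free simulated single-injection (enthalpy) experiment."""
    params = ik.make_default_lsa_params("single_lsa", noise_sd=0.0)
    tg, traj = ik.simulate_experiment(params)
    return params, tg, traj


@pytest.fixture(scope="session")
def multi_run_noise_free():
    """Noise-free simulated multiple-injection (kinetics) experiment."""
    params = ik.make_default_lsa_params("multi_lsa", noise_sd=0.0)
    tg, traj = ik.simulate_experiment(params)
    return params, tg, traj


@pytest.fixture(scope="session")
def delta_h_noise_free(single_run_noise_free):
    params, tg, _ = single_run_noise_free
    baseline = ik.fit_baseline(tg, params.schedule)
    corrected = ik.deconvolve_tian(
        ik.correct(tg, baseline), params.instrument_tau, breakpoints=params.schedule.times
    )
    return ik.estimate_delta_h_app(
        corrected, params.schedule, params.cell, noise_sd=baseline.noise_sd
    )


@pytest.fixture(scope="session")
def multi_rate_curve(multi_run_noise_free, delta_h_noise_free):
    """(trajectory DataFrame, RateCurve) for the noise-free kinetics run."""
    params, tg, _ = multi_run_noise_free
    baseline = ik.fit_baseline(tg, params.schedule)
    corrected = ik.deconvolve_tian(
        ik.correct(tg, baseline), params.instrument_tau, breakpoints=params.schedule.times
    )
    traj = ik.substrate_trajectory(
        corrected, delta_h_noise_free, params.schedule, params.cell
    )
    rc = ik.build_rate_curve(
        traj, params.schedule, ik.ExclusionPolicy(tau=params.instrument_tau)
    )
    return traj, rc


def mm_rate(s, vmax=TRUE_VMAX, km=TRUE_KM):
    return vmax * np.asarray(s, dtype=float) / (km + np.asarray(s, dtype=float))
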