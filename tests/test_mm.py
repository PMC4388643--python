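"""Michaelis–Menten fitting: recovery, oracle checks, derived constants."""

import numpy as np
import pytest

import itckinetics as ik
from itckinetics import FitConfig, MichaelisMenten, ValidationError
from itckinetics.mm import derive_catalytic_constants, lineweaver_burk, round_reported


def mm(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


GRID = np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0])


class TestFit:
    def test_exact_data_recovered_to_1e6(self):
        fit = ik.fit_michaelis_menten(np.column_stack([GRID, mm(GRID, 0.325, 56.7)]))
        assert fit.vmax == pytest.approx(0.325, rel=1e-6)
        assert fit.km == pytest.approx(56.7, rel=1e-6)
        assert fit.converged and fit.reliable

    def test_linear_space_agrees_with_log_space(self):
        rng = np.random.default_rng(11)
        y = mm(GRID, 0.325, 56.7) * (1 + rng.normal(0, 0.03, GRID.size))
        f_log = ik.fit_michaelis_menten(np.column_stack([GRID, y]))
        f_lin = ik.fit_michaelis_menten(
            np.column_stack([GRID, y]), FitConfig(log_space=False)
        )
        assert f_lin.vmax == pytest.approx(f_log.vmax, rel=1e-5)
        assert f_lin.km == pytest.approx(f_log.km, rel=1e-5)

    def test_saturated_design_flags_km_unidentifiable(self):
        s = np.array([5000.0, 6000.0, 8000.0, 10000.0, 15000.0])
        rng = np.random.default_rng(5)
        y = 0.3 + rng.normal(0, 1e-4, s.size)  # plateau with a whisper of noise
        fit = ik.fit_michaelis_menten(np.column_stack([s, y]))
        assert fit.vmax == pytest.approx(0.3, rel=0.01)
        assert not fit.reliable  # Km SE dwarfs the estimate

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            ik.fit_michaelis_menten(np.array([[10.0, 0.1], [10.0, 0.11], [10.0, 0.12]]))

    def test_grid_search_oracle_never_beats_optimizer(self):
        """A 400×400 log-grid never improves RSS by more than 0.1%."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            vmax = rng.uniform(0.05, 5.0)
            km = rng.uniform(5.0, 500.0)
            s = np.sort(rng.uniform(0.2 * km, 5 * km, 12))
            y = mm(s, vmax, km) * (1 + rng.normal(0, 0.05, s.size))
            fit = ik.fit_michaelis_menten(np.column_stack([s, y]))
            v_grid = np.geomspace(fit.vmax / 4, fit.vmax * 4, 400)
            k_grid = np.geomspace(fit.km / 10, fit.km * 10, 400)
            pred = (
                v_grid[:, None, None]
                * s[None, None, :]
                / (k_grid[None, :, None] + s[None, None, :])
            )
            rss = ((pred - y[None, None, :]) ** 2).sum(axis=2)
            assert rss.min() >= fit.rss * (1 - 1e-3)

    def test_rate_unit_rescaling(self):
        """Scaling rates scales Vmax, leaves Km invariant."""
        rng = np.random.default_rng(9)
        y = mm(GRID, 0.325, 56.7) * (1 + rng.normal(0, 0.02, GRID.size))
        f1 = ik.fit_michaelis_menten(np.column_stack([GRID, y]))
        f2 = ik.fit_michaelis_menten(np.column_stack([GRID, 60.0 * y]))
        assert f2.vmax == pytest.approx(60.0 * f1.vmax, rel=1e-6)
        assert f2.km == pytest.approx(f1.km, rel=1e-6)

    def test_nonlinear_rss_never_worse_than_lineweaver_burk(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            s = np.sort(rng.uniform(5, 300, 10))
            y = mm(s, 0.5, 60.0) + rng.normal(0, 0.01, s.size)
            y = np.abs(y)
            fit = ik.fit_michaelis_menten(np.column_stack([s, y]))
            lb = lineweaver_burk(np.column_stack([s, y]))
            lb_rss = float(np.sum((mm(s, lb.vmax, lb.km) - y) ** 2))
            assert fit.rss <= lb_rss * (1 + 1e-9)

    def test_se_shrinks_with_sqrt_n(self):
        """Replicated designs: SE ∝ 1/√n within 20%."""
        rng = np.random.default_rng(17)
        ses = {}
        for n_rep in (20, 80, 320):
            reps = []
            for _ in range(30):
                s = np.tile(GRID, n_rep // 10 * 2)[:n_rep]
                y = mm(s, 0.325, 56.7) + rng.normal(0, 0.005, s.size)
                fit = ik.fit_michaelis_menten(np.column_stack([s, np.abs(y)]))
                reps.append(fit.km_se)
            ses[n_rep] = np.median(reps)
        assert ses[80] / ses[20] == pytest.approx(0.5, rel=0.2)
        assert ses[320] / ses[80] == pytest.approx(0.5, rel=0.2)

    def test_summary_contains_estimates(self):
        fit = ik.fit_michaelis_menten(np.column_stack([GRID, mm(GRID, 0.325, 56.7)]))
        text = fit.summary()
        assert "Vmax" in text and "Km" in text and "converged" in text


class TestLineweaverBurk:
    def test_exact_data_round_trips(self):
        lb = lineweaver_burk(np.column_stack([GRID, mm(GRID, 0.325, 56.7)]))
        assert lb.vmax == pytest.approx(0.325, rel=1e-9)
        assert lb.km == pytest.approx(56.7, rel=1e-9)
        assert lb.intercept == pytest.approx(1 / 0.325, rel=1e-9)
        assert lb.intercept == pytest.approx(3.0769, rel=1e-4)

    def test_zero_rate_points_dropped_with_warning(self):
        pts = np.column_stack([GRID, mm(GRID, 0.325, 56.7)])
        pts[0, 1] = 0.0
        with pytest.warns(UserWarning, match="dropping"):
            lb = lineweaver_burk(pts)
        assert lb.n_dropped == 1

    def test_noisy_linearized_differs_from_nonlinear(self):
        """Both estimates exist and are reported; they need not agree."""
        rng = np.random.default_rng(2)
        y = np.abs(mm(GRID, 0.325, 56.7) + rng.normal(0, 0.01, GRID.size))
        fit = ik.fit_michaelis_menten(np.column_stack([GRID, y]))
        lb = lineweaver_burk(np.column_stack([GRID, y]))
        assert np.isfinite(lb.km) and np.isfinite(fit.km)


class TestCatalyticConstants:
    def _fit(self, vmax, km):
        return ik.MMFitResult(
            vmax=vmax, km=km, vmax_se=0.0, km_se=0.0, rss=0.0,
            converged=True, n_iter=1, n_obs=10,
        )

    def test_abts_efficiency_rounds_to_52(self):
        fit = derive_catalytic_constants(self._fit(3382.0 * 1e-3, 65.0), 1e-3)
        assert fit.kcat == pytest.approx(3382.0)
        assert round_reported(fit.efficiency) == 52

    def test_lsa_efficiency_rounds_to_0_004(self):
        fit = derive_catalytic_constants(self._fit(0.234 * 1.39, 56.7), 1.39)
        assert fit.kcat == pytest.approx(0.234)
        assert round_reported(fit.efficiency) == 0.004

    def test_specific_activity_from_molecular_weight(self):
        fit = derive_catalytic_constants(self._fit(3382.0 * 1e-3, 65.0), 1e-3, 67700.0)
        assert fit.specific_activity == pytest.approx(2997, rel=2e-3)

    def test_specific_activity_omitted_without_mw(self):
        fit = derive_catalytic_constants(self._fit(0.325, 56.7), 1.39)
        assert fit.specific_activity is None

    def test_efficiency_identity_exact(self):
        fit = derive_catalytic_constants(self._fit(0.325, 56.7), 1.39)
        assert fit.efficiency == fit.kcat / fit.km

    def test_zero_enzyme_rejected(self):
        with pytest.raises(ValidationError):
            derive_catalytic_constants(self._fit(0.325, 56.7), 0.0)


@pytest.mark.parametrize(
    "value,expected",
    [(52.03, 52.0), (51.51, 52.0), (0.3252, 0.33), (0.2768, 0.28), (0.004127, 0.004)],
)
def test_reporting_rounding_convention(value, expected):
    assert round_reported(value) == expected
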