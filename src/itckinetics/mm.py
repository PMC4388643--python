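"""Michaelis–Menten estimation, statsmodels-style.

``MichaelisMenten`` is a model object built from (substrate, rate) data whose
``fit()`` returns an :class:`MMFitResult` carrying estimates, standard
errors, diagnostics, and a ``summary()`` table.  The optimiser is damped
Gauss–Newton (Levenberg–Marquardt) in log-parameter space, which enforces
V_max, K_m > 0 without constrained optimisation; Eadie–Hofstee and
Lineweaver–Burk linearisations provide starting values and diagnostics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import ValidationError

__all__ = [
    "FitConfig",
    "MMFitResult",
    "MichaelisMenten",
    "fit_michaelis_menten",
    "lineweaver_burk",
    "derive_catalytic_constants",
    "round_reported",
]


@dataclass
class FitConfig:
    """Optimiser settings for the nonlinear MM fit."""

    initialization: str | tuple = "auto"  # "auto" or (vmax0, km0)
    tol: float = 1e-8  # relative convergence tolerance
    max_iter: int = 200
    log_space: bool = True
    weighting: str | None = None  # None (unweighted) or "inverse_rate_sq"

    def __post_init__(self):
        if self.tol <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.weighting not in (None, "inverse_rate_sq"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")


@dataclass
class MMFitResult:
    """Result of a Michaelis–Menten fit.

    V_max in μM/s and K_m in μM, with Jacobian-based standard errors.
    Catalytic constants (k_cat = V_max/[E]₀, efficiency k_cat/K_m, specific
    activity in U/mg) are attached by :func:`derive_catalytic_constants`.
    ``reliable`` is False when the optimiser did not converge or a parameter
    is unidentifiable (its SE is not finite or dwarfs the estimate).
    """

    vmax: float  # μM/s
    km: float  # μM
    vmax_se: float
    km_se: float
    rss: float
    converged: bool
    n_iter: int
    n_obs: int
    reliable: bool = True
    kcat: float | None = None  # s^-1
    efficiency: float | None = None  # s^-1 μM^-1
    specific_activity: float | None = None  # U/mg
    enzyme_conc: float | None = None  # μM
    molecular_weight: float | None = None  # g/mol

    def __post_init__(self):
        if self.converged and (self.vmax <= 0 or self.km <= 0):
            raise ValidationError("a converged fit must have Vmax > 0 and Km > 0")
        if self.efficiency is not None and self.kcat is not None:
            if not np.isclose(self.efficiency, self.kcat / self.km, rtol=1e-12, atol=0):
                raise ValidationError("efficiency must equal kcat/Km exactly")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.vmax, self.km])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.vmax_se, self.km_se])

    def predict(self, substrate) -> np.ndarray:
        s = np.asarray(substrate, dtype=float)
        return self.vmax * s / (self.km + s)

    def summary(self) -> str:
        lines = [
            "Michaelis-Menten fit",
            "=" * 46,
            f"{'n observations':<24}{self.n_obs}",
            f"{'converged':<24}{self.converged}",
            f"{'reliable':<24}{self.reliable}",
            f"{'iterations (nfev)':<24}{self.n_iter}",
            f"{'RSS':<24}{self.rss:.6g}",
            "-" * 46,
            f"{'Vmax (uM/s)':<24}{self.vmax:.6g} +/- {self.vmax_se:.3g}",
            f"{'Km (uM)':<24}{self.km:.6g} +/- {self.km_se:.3g}",
        ]
        if self.kcat is not None:
            lines.append(f"{'kcat (1/s)':<24}{self.kcat:.6g}")
        if self.efficiency is not None:
            lines.append(
                f"{'kcat/Km (1/s/uM)':<24}{self.efficiency:.6g}"
                f"  [reported: {round_reported(self.efficiency)}]"
            )
        if self.specific_activity is not None:
            lines.append(f"{'specific activity (U/mg)':<24}{self.specific_activity:.6g}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "vmax_uM_per_s": self.vmax,
            "km_uM": self.km,
            "vmax_se": self.vmax_se,
            "km_se": self.km_se,
            "rss": self.rss,
            "converged": self.converged,
            "reliable": self.reliable,
            "n_obs": self.n_obs,
        }
        if self.kcat is not None:
            out["kcat_per_s"] = self.kcat
        if self.efficiency is not None:
            out["efficiency_per_s_per_uM"] = self.efficiency
            out["efficiency_reported"] = round_reported(self.efficiency)
        if self.specific_activity is not None:
            out["specific_activity_U_per_mg"] = self.specific_activity
        return out


def round_reported(value: float, ndigits: int = 2) -> float:
    """Report-convention rounding: 2 significant figures, 1 below 0.01."""
    if value == 0:
        return 0.0
    sig = 1 if abs(value) < 0.01 else ndigits
    exponent = int(np.floor(np.log10(abs(value))))
    return float(round(value, -exponent + sig - 1))


class MichaelisMenten:
    """Nonlinear regression model rate = V_max·S/(K_m + S).

    Parameters
    ----------
    rate : array of float
        Observed rates, μM/s (the endogenous variable).
    substrate : array of float
        Substrate concentrations, μM.
    """

    def __init__(self, rate, substrate):
        self.rate = np.asarray(rate, dtype=float)
        self.substrate = np.asarray(substrate, dtype=float)
        if self.rate.shape != self.substrate.shape or self.rate.ndim != 1:
            raise ValidationError("rate and substrate must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(self.rate)) and np.all(np.isfinite(self.substrate))):
            raise ValidationError("rate and substrate must be finite")
        if self.rate.size < 3:
            raise ValidationError("need at least 3 observations")
        if np.unique(self.substrate).size < 2:
            raise ValidationError("degenerate design: all substrate concentrations equal")
        if np.any(self.substrate < 0) or np.any(self.rate < 0):
            raise ValidationError("substrate and rate must be >= 0")

    @classmethod
    def from_rate_curve(cls, rc) -> "MichaelisMenten":
        pts = rc.points
        return cls(rate=pts[:, 1], substrate=pts[:, 0])

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, rate_col: str = "rate_uM_per_s", substrate_col: str = "S_uM"
    ) -> "MichaelisMenten":
        return cls(rate=df[rate_col].to_numpy(), substrate=df[substrate_col].to_numpy())

    # -- starting values -------------------------------------------------
    def _linearized_start(self) -> tuple[float, float]:
        s, y = self.substrate, self.rate
        ok = (s > 0) & (y > 0)
        candidates = []
        if ok.sum() >= 3:
            # Eadie–Hofstee: y = Vmax − Km·(y/s)
            x = y[ok] / s[ok]
            A = np.column_stack([np.ones(ok.sum()), -x])
            coef, *_ = np.linalg.lstsq(A, y[ok], rcond=None)
            if coef[0] > 0 and coef[1] > 0:
                candidates.append((float(coef[0]), float(coef[1])))
            # Lineweaver–Burk fallback
            try:
                lb = lineweaver_burk(np.column_stack([s[ok], y[ok]]))
                if lb.vmax > 0 and lb.km > 0:
                    candidates.append((lb.vmax, lb.km))
            except ValidationError:
                pass
        # Robust fallback: plateau and half-saturation guesses.
        candidates.append((float(max(y.max(), 1e-12)), float(max(np.median(s[s > 0]), 1e-6))))
        rss = [float(np.sum((v * s / (k + s) - y) ** 2)) for v, k in candidates]
        return candidates[int(np.argmin(rss))]

    def fit(self, cfg: FitConfig | None = None) -> MMFitResult:
        cfg = cfg or FitConfig()
        s, y = self.substrate, self.rate
        if cfg.weighting == "inverse_rate_sq":
            w = np.where(y > 0, 1.0 / y, 0.0)
        else:
            w = np.ones_like(y)

        if cfg.initialization == "auto":
            v0, k0 = self._linearized_start()
        else:
            v0, k0 = map(float, cfg.initialization)
            if v0 <= 0 or k0 <= 0:
                raise ValidationError("explicit starting values must be positive")

        if cfg.log_space:

            def residuals(theta):
                v, k = np.exp(theta)
                return w * (v * s / (k + s) - y)

            def jacobian(theta):
                v, k = np.exp(theta)
                denom = k + s
                return np.column_stack(
                    [w * v * s / denom, w * (-v * s * k / denom**2)]
                )

            x0 = np.log([v0, k0])
        else:

            def residuals(theta):
                v, k = theta
                return w * (v * s / (k + s) - y)

            def jacobian(theta):
                v, k = theta
                denom = k + s
                return np.column_stack([w * s / denom, w * (-v * s / denom**2)])

            x0 = np.array([v0, k0])

        sol = least_squares(
            residuals,
            x0,
            jac=jacobian,
            method="lm",
            xtol=cfg.tol,
            ftol=cfg.tol,
            gtol=cfg.tol,
            max_nfev=cfg.max_iter * 3,
        )
        vmax, km = (np.exp(sol.x) if cfg.log_space else sol.x)
        converged = bool(sol.status > 0)
        rss = float(np.sum((vmax * s / (km + s) - y) ** 2))

        # SEs from the Jacobian w.r.t. the natural parameters at the optimum.
        denom = km + s
        J = np.column_stack([w * s / denom, w * (-vmax * s / denom**2)])
        dof = max(y.size - 2, 1)
        sigma2 = rss / dof
        JtJ = J.T @ J
        reliable = converged
        try:
            cov = sigma2 * np.linalg.inv(JtJ)
            ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
            if not np.all(np.isfinite(ses)):
                reliable = False
        except np.linalg.LinAlgError:
            cov = sigma2 * np.linalg.pinv(JtJ)
            ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
            reliable = False
        # A parameter whose SE dwarfs the estimate is unidentified (e.g. Km
        # when every observation sits far above saturation).
        if ses[1] > 10.0 * km or ses[0] > 10.0 * vmax:
            reliable = False
        # Km outside the sampled substrate range is an extrapolation the
        # design cannot support (all-saturated or all-linear designs).
        s_pos = s[s > 0]
        if s_pos.size and not (s_pos.min() / 5.0 <= km <= s_pos.max() * 5.0):
            reliable = False
        if not converged:
            warnings.warn(
                "Michaelis-Menten fit did not converge; parameters flagged unreliable",
                stacklevel=2,
            )
            reliable = False

        return MMFitResult(
            vmax=float(vmax),
            km=float(km),
            vmax_se=float(ses[0]),
            km_se=float(ses[1]),
            rss=rss,
            converged=converged,
            n_iter=int(sol.nfev),
            n_obs=int(y.size),
            reliable=reliable,
        )


def fit_michaelis_menten(points, cfg: FitConfig | None = None) -> MMFitResult:
    """Functional wrapper: ``points`` is an (n, 2) array of (S, rate) pairs
    or a :class:`~itckinetics.core.RateCurve`."""
    from .core import RateCurve

    if isinstance(points, RateCurve):
        model = MichaelisMenten.from_rate_curve(points)
    else:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("points must be an (n, 2) array of (S, rate) pairs")
        model = MichaelisMenten(rate=pts[:, 1], substrate=pts[:, 0])
    return model.fit(cfg)


@dataclass(frozen=True)
class LineweaverBurk:
    """Double-reciprocal diagnostic fit: 1/rate = intercept + slope·(1/S).

    Diagnostic only — the linearisation distorts the error structure and its
    parameter estimates are biased on noisy data; use the nonlinear fit for
    inference.
    """

    slope: float  # s (μM·s per μM ... units of Km/Vmax)
    intercept: float  # s·μM⁻¹ (1/Vmax)
    km: float
    vmax: float
    n_dropped: int = 0


def lineweaver_burk(points) -> LineweaverBurk:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of (S, rate) pairs")
    s, y = pts[:, 0], pts[:, 1]
    if np.any(s <= 0):
        raise ValidationError("Lineweaver-Burk requires all S > 0")
    keep = y > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} zero/negative-rate point(s) from the "
            "double-reciprocal fit",
            stacklevel=2,
        )
    if keep.sum() < 3:
        raise ValidationError("need at least 3 positive-rate points")
    inv_s, inv_y = 1.0 / s[keep], 1.0 / y[keep]
    A = np.column_stack([np.ones(inv_s.size), inv_s])
    (intercept, slope), *_ = np.linalg.lstsq(A, inv_y, rcond=None)
    if intercept <= 0:
        raise ValidationError("non-positive intercept: data inconsistent with saturation")
    return LineweaverBurk(
        slope=float(slope),
        intercept=float(intercept),
        km=float(slope / intercept),
        vmax=float(1.0 / intercept),
        n_dropped=n_dropped,
    )


def derive_catalytic_constants(
    fit: MMFitResult, enzyme_conc: float, molecular_weight: float | None = None
) -> MMFitResult:
    """Attach k_cat, catalytic efficiency, and (with MW) specific activity.

    k_cat = V_max/[E]₀ (s⁻¹); efficiency = k_cat/K_m (s⁻¹μM⁻¹); specific
    activity = k_cat·60·10³/MW (U/mg, 1 U = 1 μmol substrate · min⁻¹).
    Specific activity is omitted — never zero-filled — when MW is not given.
    """
    if enzyme_conc <= 0:
        raise ValidationError("enzyme concentration must be > 0 to derive kcat")
    kcat = fit.vmax / enzyme_conc
    specific = None
    if molecular_weight is not None:
        if molecular_weight <= 0:
            raise ValidationError("molecular weight must be > 0")
        # kcat [1/s] × 60 [s/min] → μmol substrate per μmol enzyme per min;
        # 1 mg enzyme = 1e3/MW μmol → U/mg.
        specific = kcat * 60.0 * 1e3 / molecular_weight
    return replace(
        fit,
        kcat=kcat,
        efficiency=kcat / fit.km,
        specific_activity=specific,
        enzyme_conc=enzyme_conc,
        molecular_weight=molecular_weight,
    )
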