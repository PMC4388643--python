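"""Domain types for calorimetric and spectrophotometric enzyme kinetics.

All numeric fields are in the canonical units of :mod:`itckinetics.units`
(s, μcal/s, μM, μL, cal/mol).  Every type validates its invariants at
construction and rejects NaN/infinite values outright.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "Thermogram",
    "InjectionEvent",
    "InjectionSchedule",
    "CellConfig",
    "AssayConfig",
    "EnthalpyEstimate",
    "RateCurve",
    "CellState",
    "apply_injection",
]


def _finite_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValidationError(f"{name} contains a non-finite value at index {bad}")
    return arr


def _finite_scalar(value, name: str, positive=False, nonnegative=False) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value}")
    if positive and value <= 0:
        raise ValidationError(f"{name} must be > 0, got {value}")
    if nonnegative and value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")
    return value


@dataclass
class Thermogram:
    """A sampled differential-power time series.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing.
    power : array of float
        Differential thermal power in μcal/s.  Exothermic reaction gives a
        negative deflection (power-compensation convention).
    sample_interval : float
        Nominal sampling interval in seconds; must agree with the median
        time step within 1%.
    temperature : float
        Cell temperature in °C (metadata).
    label : str
        Free-text label.
    processing_log : list of str
        Ordered record of transforms applied to this trace.
    """

    time: np.ndarray
    power: np.ndarray
    sample_interval: float
    temperature: float = 30.0
    label: str = ""
    processing_log: list = field(default_factory=list)

    def __post_init__(self):
        self.time = _finite_array(self.time, "time")
        self.power = _finite_array(self.power, "power")
        if self.time.size != self.power.size:
            raise ValidationError(
                f"time ({self.time.size}) and power ({self.power.size}) differ in length"
            )
        if self.time.size < 2:
            raise ValidationError("a thermogram needs at least 2 samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            bad = int(np.flatnonzero(steps <= 0)[0]) + 1
            raise ValidationError(
                f"time must be strictly increasing; violation at sample {bad} "
                f"(t={self.time[bad]!r})"
            )
        self.sample_interval = _finite_scalar(
            self.sample_interval, "sample_interval", positive=True
        )
        median_step = float(np.median(steps))
        if abs(median_step - self.sample_interval) > 0.01 * self.sample_interval:
            raise ValidationError(
                f"sample_interval={self.sample_interval} inconsistent with the "
                f"median time step {median_step:.6g} (tolerance 1%)"
            )
        self.temperature = _finite_scalar(self.temperature, "temperature")

    def __len__(self):
        return self.time.size

    def copy(self, **changes) -> "Thermogram":
        """Copy with optional field replacements; arrays are duplicated."""
        kwargs = dict(
            time=self.time.copy(),
            power=self.power.copy(),
            sample_interval=self.sample_interval,
            temperature=self.temperature,
            label=self.label,
            processing_log=list(self.processing_log),
        )
        kwargs.update(changes)
        return Thermogram(**kwargs)

    def cumulative_heat(self) -> np.ndarray:
        """Cumulative trapezoidal integral of power, in cal, on the time grid."""
        from scipy.integrate import cumulative_trapezoid

        q = cumulative_trapezoid(self.power, self.time, initial=0.0)
        return q * 1e-6  # μcal -> cal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "power_ucal_per_s": self.power})


@dataclass(frozen=True)
class InjectionEvent:
    """One syringe injection: when, how much, and at what concentration."""

    time: float  # s
    volume: float  # μL
    syringe_conc: float  # μM

    def __post_init__(self):
        object.__setattr__(self, "time", _finite_scalar(self.time, "injection time", nonnegative=True))
        object.__setattr__(self, "volume", _finite_scalar(self.volume, "injection volume", nonnegative=True))
        object.__setattr__(
            self, "syringe_conc", _finite_scalar(self.syringe_conc, "syringe concentration", nonnegative=True)
        )


@dataclass
class InjectionSchedule:
    """Ordered injection events plus optional syringe-capacity constraint.

    The two packaged protocols follow the iTC-200 experiments: ``single_lsa``
    (2 × 5 μL of 100 μM substrate, 1000 s spacing) calibrates the apparent
    enthalpy; ``multi_lsa`` (30 × 1 μL of 1000 μM, 60 s spacing) drives the
    rate-versus-substrate inference.
    """

    events: list
    syringe_capacity: float | None = None  # μL
    label: str = ""

    def __post_init__(self):
        self.events = [
            e if isinstance(e, InjectionEvent) else InjectionEvent(*e) for e in self.events
        ]
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("injection times must be strictly increasing")
        if any(e.volume <= 0 for e in self.events):
            raise ValidationError("scheduled injection volumes must be > 0")
        if self.syringe_capacity is not None:
            self.syringe_capacity = _finite_scalar(
                self.syringe_capacity, "syringe_capacity", positive=True
            )
            total = self.total_volume
            if total > self.syringe_capacity + 1e-9:
                raise ValidationError(
                    f"total injected volume {total:g} μL exceeds syringe capacity "
                    f"{self.syringe_capacity:g} μL"
                )

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    @property
    def total_volume(self) -> float:
        return float(sum(e.volume for e in self.events))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time for e in self.events],
                "volume_uL": [e.volume for e in self.events],
                "syringe_conc_uM": [e.syringe_conc for e in self.events],
            }
        )


@dataclass
class CellConfig:
    """Fixed-volume overflow reaction cell.

    ``volume`` is the working cell volume V (μL); ``enzyme_conc`` the enzyme
    concentration at experiment start (μM); ``molecular_weight`` (g/mol) is
    only needed to convert k_cat to specific activity and is never guessed.
    """

    volume: float  # μL
    enzyme_conc: float = 0.0  # μM
    buffer: str = ""
    molecular_weight: float | None = None  # g/mol

    def __post_init__(self):
        self.volume = _finite_scalar(self.volume, "cell volume", positive=True)
        self.enzyme_conc = _finite_scalar(self.enzyme_conc, "enzyme concentration", nonnegative=True)
        if self.molecular_weight is not None:
            self.molecular_weight = _finite_scalar(
                self.molecular_weight, "molecular weight", positive=True
            )


@dataclass
class AssayConfig:
    """Spectrophotometric assay geometry and chromophore constants."""

    wavelength: float  # nm
    extinction_coefficient: float  # M^-1 cm^-1
    path_length: float = 1.0  # cm
    reaction_volume: float | None = None  # mL
    enzyme_mass: float | None = None  # mg
    ph: float | None = None
    temperature: float | None = None  # °C

    def __post_init__(self):
        self.wavelength = _finite_scalar(self.wavelength, "wavelength", positive=True)
        self.extinction_coefficient = _finite_scalar(
            self.extinction_coefficient, "extinction coefficient", positive=True
        )
        self.path_length = _finite_scalar(self.path_length, "path length", positive=True)


# Chromogenic substrates used by the reference laccase assays.
ABTS_ASSAY = AssayConfig(wavelength=420.0, extinction_coefficient=36000.0)
DMP_ASSAY = AssayConfig(wavelength=468.0, extinction_coefficient=49600.0)


@dataclass
class EnthalpyEstimate:
    """Apparent molar enthalpy ΔH_app from a single-injection experiment.

    ``delta_h_app`` (cal/mol) is total integrated heat divided by total
    converted moles; exothermic turnover gives a negative value.
    """

    delta_h_app: float  # cal/mol
    total_heat: float  # cal
    converted_moles: float  # mol
    integration_windows: list  # [(start, end)] in s
    baseline_model: object = None
    per_injection: list = field(default_factory=list)  # per-injection ΔH_app, cal/mol

    def __post_init__(self):
        self.total_heat = _finite_scalar(self.total_heat, "total_heat")
        self.converted_moles = _finite_scalar(self.converted_moles, "converted_moles", positive=True)
        self.delta_h_app = _finite_scalar(self.delta_h_app, "delta_h_app")
        if not np.isclose(
            self.delta_h_app, self.total_heat / self.converted_moles, rtol=0, atol=1e-12 * max(1.0, abs(self.delta_h_app))
        ):
            raise ValidationError("delta_h_app must equal total_heat / converted_moles")


_EXCLUSION_REASONS = {"pre_injection", "settling", "edge", "negative_rate", "manual"}


@dataclass
class RateCurve:
    """Paired (residual substrate, rate) observations from a thermogram.

    ``data`` holds one row per thermogram sample with columns ``time_s``,
    ``S_uM``, ``rate_uM_per_s``, ``injection_idx``, ``retained`` and
    ``reason`` (empty for retained points).  Negative substrate
    concentrations are rejected at construction — clipping is the caller's
    explicit, logged decision, never silent.
    """

    data: pd.DataFrame
    excluded_windows: list = field(default_factory=list)  # [(start, end, reason)]

    def __post_init__(self):
        required = {"time_s", "S_uM", "rate_uM_per_s", "injection_idx", "retained"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"RateCurve data missing columns: {sorted(missing)}")
        if "reason" not in self.data.columns:
            self.data = self.data.assign(reason="")
        t = self.data["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValidationError("RateCurve points must be sorted by strictly increasing time")
        for col in ("time_s", "S_uM", "rate_uM_per_s"):
            if not np.all(np.isfinite(self.data[col].to_numpy(dtype=float))):
                raise ValidationError(f"RateCurve column {col} contains non-finite values")
        s = self.data["S_uM"].to_numpy(dtype=float)
        if np.any(s < 0):
            worst = float(s.min())
            raise ValidationError(
                f"negative residual substrate concentration ({worst:.4g} μM): "
                "resolve the sign/ΔH_app inconsistency or clip explicitly upstream"
            )

    def __len__(self):
        return len(self.data)

    @property
    def retained(self) -> pd.DataFrame:
        return self.data[self.data["retained"]]

    @property
    def points(self) -> np.ndarray:
        """Retained (S, rate) pairs as an (n, 2) array."""
        return self.retained[["S_uM", "rate_uM_per_s"]].to_numpy(dtype=float)


@dataclass
class CellState:
    """Instantaneous in-cell concentrations (μM)."""

    substrate: float = 0.0
    product: float = 0.0
    enzyme: float = 0.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            _finite_scalar(getattr(self, f.name), f.name, nonnegative=True)


def apply_injection(state: CellState, event: InjectionEvent, cell: CellConfig) -> tuple[CellState, float]:
    """Apply one injection to a fixed-volume overflow cell.

    Linear displacement model: injecting volume v into a full cell of volume V
    scales every resident species by (1 − v/V) and raises the injected
    species by c_syringe·(v/V).  At v/V ≤ 2.5% this differs from the
    exponential overflow model by < 0.04% and matches common instrument-vendor
    practice.

    Returns
    -------
    (new_state, added_substrate) : (CellState, float)
        The post-injection state and the substrate concentration contributed
        by the bolus (μM), i.e. the increment to [S]_total.
    """
    v, V = event.volume, cell.volume
    if v > V:
        raise ValidationError(f"injection volume {v:g} μL exceeds cell volume {V:g} μL")
    keep = 1.0 - v / V
    added = event.syringe_conc * (v / V)
    new = CellState(
        substrate=state.substrate * keep + added,
        product=state.product * keep,
        enzyme=state.enzyme * keep,
    )
    return new, added
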