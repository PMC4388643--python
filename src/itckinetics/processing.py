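"""Thermogram signal conditioning.

Baseline estimation and subtraction, Tian (first-order instrument response)
deconvolution, and windowed peak integration — the steps that turn a raw
power trace into a signal whose integral is reaction heat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import InjectionSchedule, Thermogram
from .exceptions import NumericalError, ValidationError

__all__ = [
    "BaselinePolicy",
    "BaselineModel",
    "fit_baseline",
    "correct",
    "deconvolve_tian",
    "integrate_heat",
    "quiet_threshold",
]

#: Absolute power floor (μcal/s) below which a sample counts as "at baseline"
#: even when the estimated noise SD is zero (noise-free synthetic data).
POWER_ATOL = 1e-6


def quiet_threshold(noise_sd: float, peak_power: float = 0.0, peak_frac: float = 0.005) -> float:
    """Threshold for 'power has returned to baseline'.

    max(3×noise SD, ``peak_frac`` of the peak amplitude, an absolute floor).
    The fractional term keeps the rule meaningful on noise-free data, where
    the exponential tail of a first-order reaction never reaches exactly zero.
    """
    return max(3.0 * noise_sd, peak_frac * abs(peak_power), POWER_ATOL)


@dataclass
class BaselinePolicy:
    """How to choose baseline fit windows.

    ``kind`` is ``"constant"`` or ``"linear"``; explicit ``windows`` override
    the automatic choice (pre-first-injection segment plus, when
    ``include_terminal`` and detectable, a terminal return-to-baseline
    segment).  ``include_terminal`` defaults off: a first-order reaction
    approaches baseline only asymptotically, so a terminal window silently
    absorbs real tail heat; enable it when a drifting baseline must be
    pinned at both ends.
    """

    kind: str = "constant"
    windows: list | None = None  # [(start, end)] s
    margin: float = 5.0  # s trimmed before the first injection
    min_pre_injection: float = 30.0  # s of required pre-injection data
    include_terminal: bool = False
    terminal_min_samples: int = 10

    def __post_init__(self):
        if self.kind not in ("constant", "linear"):
            raise ValidationError(f"baseline kind must be constant|linear, got {self.kind!r}")


@dataclass
class BaselineModel:
    """Fitted baseline: power ≈ c0 + c1·t (c1 fixed at 0 for constant kind)."""

    kind: str
    coefficients: np.ndarray  # (c0,) or (c0, c1)
    fit_windows: list  # [(start, end)] s
    noise_sd: float  # μcal/s, MAD-based residual spread

    def __post_init__(self):
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be >= 0")

    def predict(self, time) -> np.ndarray:
        t = np.asarray(time, dtype=float)
        if self.kind == "linear":
            return self.coefficients[0] + self.coefficients[1] * t
        return np.full_like(t, self.coefficients[0])


def _window_mask(time: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(time.size, dtype=bool)
    for start, end in windows:
        mask |= (time >= start) & (time <= end)
    return mask


def fit_baseline(
    tg: Thermogram,
    schedule: InjectionSchedule | None = None,
    policy: BaselinePolicy | None = None,
) -> BaselineModel:
    """Fit a constant or linear baseline to signal-free segments.

    By default the pre-first-injection span (minus a small margin) is used,
    plus a terminal segment when the trace has demonstrably returned to the
    pre-injection level.  With no schedule, the whole trace is baseline.
    """
    policy = policy or BaselinePolicy()
    time, power = tg.time, tg.power

    if policy.windows is not None:
        windows = [tuple(map(float, w)) for w in policy.windows]
        for start, end in windows:
            if start < time[0] - 1e-9 or end > time[-1] + 1e-9:
                raise ValidationError(
                    f"baseline window ({start:g}, {end:g}) lies outside the thermogram"
                )
    elif schedule is None or len(schedule) == 0:
        windows = [(float(time[0]), float(time[-1]))]
    else:
        first = float(schedule.times[0])
        pre_end = first - policy.margin
        if pre_end - time[0] < policy.min_pre_injection:
            raise ValidationError(
                f"only {pre_end - time[0]:.0f} s of pre-injection data "
                f"(need >= {policy.min_pre_injection:g} s); pass explicit windows"
            )
        windows = [(float(time[0]), pre_end)]
        pre_mask = _window_mask(time, windows)
        pre_level = float(np.median(power[pre_mask]))
        pre_sd = 1.4826 * float(np.median(np.abs(power[pre_mask] - pre_level)))
        # Tight threshold on purpose: a slow reaction approaches baseline
        # asymptotically, and a loose terminal window would absorb real tail
        # signal into the baseline estimate.
        thr = max(3.0 * pre_sd, POWER_ATOL)
        if policy.include_terminal:
            after_last = time > float(schedule.times[-1])
            quiet = after_last & (np.abs(power - pre_level) <= thr)
            # longest terminal run of quiet samples
            run = 0
            for q in quiet[::-1]:
                if not q:
                    break
                run += 1
            if run >= policy.terminal_min_samples:
                windows.append((float(time[time.size - run]), float(time[-1])))

    mask = _window_mask(time, windows)
    if mask.sum() < (3 if policy.kind == "linear" else 2):
        raise ValidationError("too few samples in baseline windows")

    t_fit, p_fit = time[mask], power[mask]
    if policy.kind == "linear":
        coeffs = np.polynomial.polynomial.polyfit(t_fit, p_fit, 1)
    else:
        coeffs = np.array([float(np.mean(p_fit))])
    model = BaselineModel(kind=policy.kind, coefficients=coeffs, fit_windows=windows, noise_sd=0.0)
    resid = p_fit - model.predict(t_fit)
    model.noise_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return model


def correct(tg: Thermogram, baseline: BaselineModel) -> Thermogram:
    """Subtract the baseline prediction; appends to the processing log."""
    out = tg.copy(power=tg.power - baseline.predict(tg.time))
    out.processing_log.append(
        f"baseline corrected ({baseline.kind}, coefficients="
        f"{np.array2string(baseline.coefficients, precision=6)})"
    )
    return out


def deconvolve_tian(
    tg: Thermogram, tau: float, window: int = 7, breakpoints=None
) -> Thermogram:
    """Invert the first-order instrument response.

    P_true(t) = P_meas(t) + τ·dP_meas/dt, with the derivative estimated by a
    local-quadratic (Savitzky–Golay) filter of ``window`` points.  τ = 0 is
    the identity.

    ``breakpoints`` (typically the injection times) split the trace into
    segments that are filtered independently, so the smoothing window never
    straddles a known power discontinuity — otherwise the samples on either
    side of an injection inherit a spurious derivative from the jump.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    if tau == 0:
        out = tg.copy()
        out.processing_log.append("tian deconvolution (tau=0, passthrough)")
        return out
    if window % 2 == 0 or window < 5:
        raise ValidationError("smoothing window must be odd and >= 5")
    if window > len(tg):
        raise ValidationError(
            f"smoothing window ({window}) exceeds thermogram length ({len(tg)})"
        )
    steps = np.diff(tg.time)
    if np.max(steps) - np.min(steps) > 0.01 * tg.sample_interval:
        raise ValidationError("tian deconvolution requires uniform sampling")

    edges = [0]
    if breakpoints is not None:
        for b in np.atleast_1d(np.asarray(breakpoints, dtype=float)):
            k = int(np.searchsorted(tg.time, b - 1e-9))
            if 0 < k < len(tg):
                edges.append(k)
    edges = sorted(set(edges)) + [len(tg)]

    dpdt = np.empty(len(tg))
    for i0, i1 in zip(edges[:-1], edges[1:]):
        seg = tg.power[i0:i1]
        if seg.size >= window:
            dpdt[i0:i1] = savgol_filter(
                seg, window_length=window, polyorder=2, deriv=1, delta=tg.sample_interval
            )
        elif seg.size >= 3:
            dpdt[i0:i1] = np.gradient(seg, tg.sample_interval)
        elif seg.size == 2:
            dpdt[i0:i1] = (seg[1] - seg[0]) / tg.sample_interval
        else:
            dpdt[i0:i1] = 0.0
    out = tg.copy(power=tg.power + tau * dpdt)
    out.processing_log.append(
        f"tian deconvolution (tau={tau:g} s, window={window}, "
        f"{len(edges) - 2} breakpoints)"
    )
    return out


def integrate_heat(
    tg: Thermogram,
    window,
    noise_sd: float = 0.0,
    *,
    consecutive: int = 5,
    peak_frac: float = 0.005,
) -> float:
    """Trapezoidal heat over a window, in cal.

    ``window`` is either an explicit ``(start, end)`` pair in seconds, or a
    single start time for automatic closure: the window then runs until the
    power stays within the quiet threshold (3×noise SD with a small
    peak-fraction floor) for ``consecutive`` samples.  The caller caps the
    window at the next injection by passing an explicit end.
    """
    time, power = tg.time, tg.power
    if np.isscalar(window):
        start = float(window)
        sel = time >= start - 1e-9
        if not np.any(sel):
            raise ValidationError(f"window start {start:g} s beyond the thermogram")
        idx = np.flatnonzero(sel)
        peak = float(np.max(np.abs(power[idx]))) if idx.size else 0.0
        thr = quiet_threshold(noise_sd, peak, peak_frac)
        quiet = np.abs(power[idx]) <= thr
        end_idx = None
        run = 0
        for j, q in enumerate(quiet):
            run = run + 1 if q else 0
            if run >= consecutive:
                end_idx = idx[j]
                break
        if end_idx is None:
            raise NumericalError(
                f"auto-window starting at {start:g} s never closed "
                f"(power stayed above {thr:.3g} μcal/s); pass an explicit (start, end)"
            )
        end = float(time[end_idx])
    else:
        start, end = map(float, window)
        if end <= start:
            raise ValidationError(f"empty integration window ({start:g}, {end:g})")
    mask = (time >= start - 1e-9) & (time <= end + 1e-9)
    if mask.sum() < 2:
        raise ValidationError("integration window contains fewer than 2 samples")
    return float(np.trapezoid(power[mask], time[mask])) * 1e-6  # μcal → cal
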