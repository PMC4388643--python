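"""End-to-end analyses and report generation.

``ITCKineticsAnalysis`` chains the calorimetric stages — baseline fit,
correction, Tian deconvolution, ΔH_app calibration, rate/substrate
extraction, exclusion, and the Michaelis–Menten fit — into one model-like
object whose :meth:`~ITCKineticsAnalysis.fit` returns an
:class:`ITCKineticsResults`.  ``run_itc_pipeline`` / ``run_spectro_pipeline``
are the file-driven entry points used by the CLI; both write a dual-format
report (human-readable text plus machine-readable YAML key/value) and record
every exercised default and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as _io
from .core import CellConfig, EnthalpyEstimate, RateCurve, Thermogram
from .exceptions import ITCKineticsError, StageError, ValidationError
from .itc import (
    ExclusionPolicy,
    build_rate_curve,
    estimate_delta_h_app,
    substrate_trajectory,
)
from .mm import FitConfig, MichaelisMenten, MMFitResult, derive_catalytic_constants
from .processing import BaselinePolicy, correct, deconvolve_tian, fit_baseline
from .simulate import make_default_lsa_params, render_thermogram, simulate_cell
from .spectro import UNIT_DEFINITION, assemble_mm_dataset

__all__ = [
    "RunConfig",
    "ITCKineticsAnalysis",
    "ITCKineticsResults",
    "run_itc_pipeline",
    "run_spectro_pipeline",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (file paths and analysis knobs)."""

    outdir: Path = Path("itckin_out")
    single_thermogram: Path | None = None
    single_schedule: Path | None = None
    multi_thermogram: Path | None = None
    multi_schedule: Path | None = None
    trace_paths: list = field(default_factory=list)
    cell: CellConfig | None = None
    assay: object = None
    tau: float = 6.0
    baseline: BaselinePolicy = field(default_factory=BaselinePolicy)
    exclusion: ExclusionPolicy | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    simulate: bool = False
    noise_sd: float = 0.01
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = _io.load_config(path)
        kwargs = {}
        for key in (
            "single_thermogram",
            "single_schedule",
            "multi_thermogram",
            "multi_schedule",
        ):
            if key in raw:
                kwargs[key] = Path(raw[key])
        if "traces" in raw:
            kwargs["trace_paths"] = [Path(p) for p in raw["traces"]]
        for key in ("cell", "assay", "tau", "noise_sd", "seed", "simulate", "verbosity"):
            if key in raw:
                kwargs[key] = raw[key]
        if "outdir" in raw:
            kwargs["outdir"] = Path(raw["outdir"])
        cfg = cls(**kwargs)
        for key in ("single_thermogram", "single_schedule", "multi_thermogram", "multi_schedule"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"configured path does not exist: {p}")
        return cfg


@dataclass
class ITCKineticsResults:
    """Everything the calorimetric chain produced, with provenance."""

    delta_h: EnthalpyEstimate
    mm: MMFitResult
    rate_curve: RateCurve
    corrected_single: Thermogram
    corrected_multi: Thermogram
    baseline_log: dict
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            "ITC enzyme-kinetics analysis",
            "=" * 46,
            f"{'dH_app (cal/mol)':<24}{self.delta_h.delta_h_app:.6g}",
            f"{'per-injection dH':<24}"
            + ", ".join(f"{v:.5g}" for v in self.delta_h.per_injection),
            f"{'rate-curve points':<24}{len(self.rate_curve.retained)} retained / "
            f"{len(self.rate_curve)} total",
            "",
            self.mm.summary(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "delta_h_app_cal_per_mol": self.delta_h.delta_h_app,
            "delta_h_total_heat_cal": self.delta_h.total_heat,
            "delta_h_converted_moles_mol": self.delta_h.converted_moles,
            "delta_h_per_injection": list(self.delta_h.per_injection),
            "rate_curve_points_retained": int(len(self.rate_curve.retained)),
            "rate_curve_points_total": int(len(self.rate_curve)),
            "baseline": self.baseline_log,
            "seed": self.seed,
        }
        out.update(self.mm.to_dict())
        return out


class ITCKineticsAnalysis:
    """The calorimetric inference chain as a single fit-able object.

    Built either from measured thermograms/schedules
    (:meth:`from_files`) or from the built-in calorimeter simulator
    (:meth:`from_simulation`).  ``fit()`` runs:

    baseline → correct → Tian-deconvolve → ΔH_app (single-injection run) →
    Eq-2 rates + Eq-3 substrate (multi-injection run) → exclusions → MM fit →
    catalytic constants.
    """

    def __init__(
        self,
        single_tg: Thermogram,
        single_schedule,
        multi_tg: Thermogram,
        multi_schedule,
        cell: CellConfig,
        *,
        tau: float = 6.0,
        noise_sd: float | None = None,
        baseline_policy: BaselinePolicy | None = None,
        exclusion_policy: ExclusionPolicy | None = None,
        fit_config: FitConfig | None = None,
        seed: int | None = None,
    ):
        self.single_tg = single_tg
        self.single_schedule = single_schedule
        self.multi_tg = multi_tg
        self.multi_schedule = multi_schedule
        self.cell = cell
        self.tau = tau
        self.noise_sd = noise_sd
        self.baseline_policy = baseline_policy or BaselinePolicy()
        self.exclusion_policy = exclusion_policy or ExclusionPolicy(tau=tau)
        self.fit_config = fit_config or FitConfig()
        self.seed = seed

    @classmethod
    def from_files(
        cls,
        single_thermogram,
        single_schedule,
        multi_thermogram,
        multi_schedule,
        cell: CellConfig,
        **kwargs,
    ) -> "ITCKineticsAnalysis":
        return cls(
            _io.read_thermogram(single_thermogram),
            _io.read_injection_schedule(single_schedule),
            _io.read_thermogram(multi_thermogram),
            _io.read_injection_schedule(multi_schedule),
            cell,
            **kwargs,
        )

    @classmethod
    def from_params(cls, p_single, p_multi, **kwargs) -> "ITCKineticsAnalysis":
        """Simulate a calibration/titration pair from explicit parameter sets."""
        tg_s = render_thermogram(simulate_cell(p_single), p_single)
        tg_m = render_thermogram(simulate_cell(p_multi), p_multi)
        kwargs.setdefault("tau", p_multi.instrument_tau)
        kwargs.setdefault("noise_sd", p_multi.noise_sd)
        kwargs.setdefault("seed", p_multi.seed)
        return cls(
            tg_s, p_single.schedule, tg_m, p_multi.schedule, p_single.cell, **kwargs
        )

    @classmethod
    def from_simulation(
        cls, *, noise_sd: float = 0.01, seed: int = 0, tau: float = 6.0, **overrides
    ) -> "ITCKineticsAnalysis":
        """Simulate both reference protocols and wrap them for analysis."""
        p_single = make_default_lsa_params(
            "single_lsa", noise_sd=noise_sd, seed=seed, instrument_tau=tau, **overrides
        )
        p_multi = make_default_lsa_params(
            "multi_lsa", noise_sd=noise_sd, seed=seed + 1, instrument_tau=tau, **overrides
        )
        return cls.from_params(p_single, p_multi, tau=tau, noise_sd=noise_sd, seed=seed)

    def fit(self) -> ITCKineticsResults:
        def stage(name, hint, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ITCKineticsError as exc:
                raise StageError(name, str(exc), hint) from exc

        base_s = stage(
            "baseline(single)",
            "check pre-injection span or pass explicit windows",
            fit_baseline,
            self.single_tg,
            self.single_schedule,
            self.baseline_policy,
        )
        base_m = stage(
            "baseline(multi)",
            "check pre-injection span or pass explicit windows",
            fit_baseline,
            self.multi_tg,
            self.multi_schedule,
            self.baseline_policy,
        )
        noise = self.noise_sd if self.noise_sd is not None else base_m.noise_sd

        corr_s = correct(self.single_tg, base_s)
        corr_m = correct(self.multi_tg, base_m)
        dec_s = stage(
            "deconvolve(single)",
            "reduce the smoothing window",
            deconvolve_tian,
            corr_s,
            self.tau,
            breakpoints=self.single_schedule.times,
        )
        dec_m = stage(
            "deconvolve(multi)",
            "reduce the smoothing window",
            deconvolve_tian,
            corr_m,
            self.tau,
            breakpoints=self.multi_schedule.times,
        )

        dh = stage(
            "deltaH",
            "use a longer injection spacing or mark windows manually",
            estimate_delta_h_app,
            dec_s,
            self.single_schedule,
            self.cell,
            noise_sd=noise,
            baseline_model=base_s,
        )
        traj = stage(
            "substrate_trajectory",
            "verify ΔH_app sign and magnitude",
            substrate_trajectory,
            dec_m,
            dh,
            self.multi_schedule,
            self.cell,
            noise_sd=noise,
        )
        rc = stage(
            "rate_curve",
            "relax the exclusion policy",
            build_rate_curve,
            traj,
            self.multi_schedule,
            self.exclusion_policy,
        )
        mm = stage(
            "mm_fit",
            "inspect the rate curve for degeneracy",
            lambda: MichaelisMenten.from_rate_curve(rc).fit(self.fit_config),
        )
        if self.cell.enzyme_conc > 0:
            mm = derive_catalytic_constants(
                mm, self.cell.enzyme_conc, self.cell.molecular_weight
            )
        return ITCKineticsResults(
            delta_h=dh,
            mm=mm,
            rate_curve=rc,
            corrected_single=dec_s,
            corrected_multi=dec_m,
            baseline_log={
                "kind": self.baseline_policy.kind,
                "single_coefficients": [float(c) for c in base_s.coefficients],
                "multi_coefficients": [float(c) for c in base_m.coefficients],
                "noise_sd_ucal_per_s": float(base_m.noise_sd),
                "tau_s": float(self.tau),
                "settle_window_s": float(self.exclusion_policy.resolved_settle()),
            },
            seed=self.seed,
        )


def _write_report(outdir: Path, name: str, text: str, payload: dict) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    txt_path = outdir / f"{name}.txt"
    kv_path = outdir / f"{name}.yaml"
    txt_path.write_text(text + "\n")
    kv_path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return {"text": txt_path, "keyvalue": kv_path}


def run_itc_pipeline(cfg: RunConfig) -> dict:
    """File-driven calorimetric analysis; returns a report bundle dict."""
    if cfg.simulate:
        analysis = ITCKineticsAnalysis.from_simulation(
            noise_sd=cfg.noise_sd, seed=cfg.seed, tau=cfg.tau
        )
    else:
        needed = {
            "single_thermogram": cfg.single_thermogram,
            "single_schedule": cfg.single_schedule,
            "multi_thermogram": cfg.multi_thermogram,
            "multi_schedule": cfg.multi_schedule,
        }
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise StageError(
                "inputs",
                f"missing {', '.join(missing)}",
                "supply the files or pass --simulate",
            )
        if cfg.cell is None:
            raise StageError("inputs", "missing cell configuration", "add a `cell:` section")
        analysis = ITCKineticsAnalysis.from_files(
            cfg.single_thermogram,
            cfg.single_schedule,
            cfg.multi_thermogram,
            cfg.multi_schedule,
            cfg.cell,
            tau=cfg.tau,
            baseline_policy=cfg.baseline,
            exclusion_policy=cfg.exclusion,
            fit_config=cfg.fit,
            seed=cfg.seed,
        )
    results = analysis.fit()
    payload = results.to_dict()
    payload["seed"] = cfg.seed
    bundle = _write_report(Path(cfg.outdir), "itc_report", results.summary(), payload)
    rc_path = Path(cfg.outdir) / "rate_curve.csv"
    _io.write_rate_curve(results.rate_curve, rc_path)
    _io.write_thermogram(results.corrected_multi, Path(cfg.outdir) / "multi_corrected.csv")
    _io.write_thermogram(results.corrected_single, Path(cfg.outdir) / "single_corrected.csv")
    bundle["rate_curve"] = rc_path
    bundle["results"] = results
    return bundle


def run_spectro_pipeline(cfg: RunConfig) -> dict:
    """File-driven initial-rate analysis; returns a report bundle dict."""
    if not cfg.trace_paths:
        raise StageError(
            "inputs", "no absorbance traces supplied", "list them under `traces:`"
        )
    traces = [_io.read_absorbance_trace(p) for p in cfg.trace_paths]
    points = assemble_mm_dataset(traces)
    model = MichaelisMenten(rate=points[:, 1], substrate=points[:, 0])
    mm = model.fit(cfg.fit)
    if cfg.cell is not None and cfg.cell.enzyme_conc > 0:
        mm = derive_catalytic_constants(mm, cfg.cell.enzyme_conc, cfg.cell.molecular_weight)
    payload = mm.to_dict()
    payload["seed"] = cfg.seed
    payload["unit_definition"] = UNIT_DEFINITION
    payload["n_traces"] = len(traces)
    payload["substrate_concs_uM"] = [float(s) for s in points[:, 0]]
    payload["initial_rates_uM_per_s"] = [float(r) for r in points[:, 1]]
    text = mm.summary() + f"\nunit definition: {UNIT_DEFINITION}"
    bundle = _write_report(Path(cfg.outdir), "spectro_report", text, payload)
    bundle["mm"] = mm
    bundle["points"] = points
    return bundle
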