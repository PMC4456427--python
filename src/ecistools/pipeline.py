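"""End-to-end orchestration: simulate/load -> channels -> wound detection ->
healing kinetics -> adhesion-parameter fit -> micromotion -> group stats.

The pipeline consumes a single configuration mapping (JSON/YAML-friendly)
and writes per-stage outputs, a JSON report, and a run manifest.  Output is
a pure function of (config, input files): all randomness derives from the
config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .core import extract_channel, read_timecourse, write_timecourse
from .errors import EcisError
from .gk import NakedElectrodeModel, calibrate_naked_electrode, fit_alpha
from .kinetics import (
    attachment_slope,
    detect_wound,
    fit_healing_sigmoid,
    healing_time,
    migration_rate,
)
from .micromotion import micromotion_analysis, transition_half_time
from .simulate import (
    GroupParams,
    MicromotionModel,
    PhaseSchedule,
    SimulationConfig,
    WoundSpec,
    simulate_timecourse,
)
from .stats import GroupSample, tukey_kramer

__all__ = ["RunManifest", "PipelineStageError", "run_pipeline",
           "simulation_config_from_dict"]

log = logging.getLogger("ecistools.pipeline")


class PipelineStageError(EcisError):
    """Wraps a stage failure with the stage name and offending input."""

    def __init__(self, stage: str, source: str, cause: Exception):
        self.stage = stage
        self.source = source
        self.cause = cause
        super().__init__(f"stage {stage!r} failed on {source}: {cause}")


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: Mapping[str, Any]) -> str:
    """SHA-256 of the canonical (key-sorted) JSON form of the config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"),
                       default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def simulation_config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from a plain mapping (CLI config files)."""
    kw: dict[str, Any] = {}
    for key in ("seed", "interval_s", "duration_h", "frequencies_hz",
                "wound_radius_um", "noise_sd", "well_level_sd_ohm"):
        if key in d:
            kw[key] = d[key]
    if "schedule" in d:
        kw["schedule"] = PhaseSchedule(**d["schedule"])
    if "electrode" in d:
        kw["electrode"] = NakedElectrodeModel(**d["electrode"])
    if "wound" in d:
        kw["wound"] = WoundSpec(**d["wound"])
    if "micromotion" in d:
        kw["micromotion"] = MicromotionModel(**d["micromotion"])
    if "groups" in d:
        groups = {}
        for name, g in d["groups"].items():
            g = dict(g)
            if "schedule" in g:
                g["schedule"] = PhaseSchedule(**g["schedule"])
            groups[name] = GroupParams(**g)
        kw["groups"] = groups
    if "wells" in d:
        kw["wells"] = [tuple(w) for w in d["wells"]]
    return SimulationConfig(**kw)


def _stage(manifest: RunManifest, name: str):
    manifest.timestamps[name] = time.time()
    log.info("stage %s", name)


def run_pipeline(config: Mapping[str, Any], out_dir,
                 seed: int | None = None) -> tuple[RunManifest, dict]:
    """Execute the full analysis described by ``config``.

    The config holds either a ``simulate`` block (see
    :func:`simulation_config_from_dict`) or an ``input`` block
    (``{"path": ..., "dialect": ...}``), plus an optional ``analysis``
    block with keys ``cellfree_ohm``, ``radius_um``, ``threshold``,
    ``window_h``, ``rate_convention``, ``attachment_window_h``,
    ``micromotion`` (bool), ``alpha_fit`` (bool), ``stats_alpha``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    if seed is not None and "simulate" in cfg:
        cfg["simulate"] = dict(cfg["simulate"], seed=seed)
    manifest = RunManifest(config_hash=config_hash(cfg),
                           seed=cfg.get("simulate", {}).get("seed", seed),
                           version=__version__)
    report: dict[str, Any] = {"wells": {}, "groups": {}, "comparisons": {}}

    ana = dict(cfg.get("analysis", {}))
    cellfree = float(ana.get("cellfree_ohm", 2600.0))
    radius = float(ana.get("radius_um", 125.0))
    threshold = float(ana.get("threshold", 0.95))
    window = ana.get("window_h", "auto")
    convention = ana.get("rate_convention", "radius")
    stats_alpha = float(ana.get("stats_alpha", 0.01))

    # ---- stage: data -----------------------------------------------------
    _stage(manifest, "data")
    sim_truth = None
    if "simulate" in cfg:
        sim_cfg = simulation_config_from_dict(cfg["simulate"])
        ts, sim_truth = simulate_timecourse(sim_cfg)
        data_path = out / "timecourse.csv"
        write_timecourse(ts, data_path)
        (out / "ground_truth.json").write_text(
            json.dumps(sim_truth, indent=2, default=float))
        manifest.outputs["timecourse"] = str(data_path)
        manifest.outputs["ground_truth"] = str(out / "ground_truth.json")
        well_groups = dict(sim_cfg.wells)
        naked = sim_cfg.electrode or calibrate_naked_electrode(
            r_target_ohm=sim_cfg.schedule.cellfree_r4k)
    elif "input" in cfg:
        src = cfg["input"]
        try:
            ts = read_timecourse(src["path"], src.get("dialect", "long"))
        except EcisError as exc:
            raise PipelineStageError("read_timecourse", str(src["path"]), exc)
        well_groups = dict(cfg.get("well_groups",
                                   {w: "all" for w in ts.wells}))
        naked = (NakedElectrodeModel(**cfg["electrode"])
                 if "electrode" in cfg
                 else calibrate_naked_electrode(r_target_ohm=cellfree))
    else:
        raise PipelineStageError("data", "<config>",
                                 ValueError("config needs 'simulate' or 'input'"))
    log.info("data: %d sweeps x %d wells x %d frequencies",
             *ts.impedance.shape)

    # ---- per-well stages -------------------------------------------------
    endpoints: dict[str, dict[str, list[float]]] = {}

    def record(group: str, endpoint: str, value: float) -> None:
        endpoints.setdefault(endpoint, {}).setdefault(group, []).append(value)

    for well in ts.wells:
        group = well_groups.get(well, "all")
        wrep: dict[str, Any] = {"group": group}
        try:
            r4k = extract_channel(ts, well, 4000.0, "R")
        except EcisError as exc:
            raise PipelineStageError("extract_channel", well, exc)

        # maturation QC
        _stage(manifest, f"maturation[{well}]")
        finite = np.isfinite(r4k.values)
        wrep["maturation"] = {
            "peak_ohm": float(np.nanmax(r4k.values)),
            "peak_time_h": float(r4k.times_h[np.nanargmax(r4k.values)]),
        }

        # attachment-slope adhesion assay (first 24 h)
        if ana.get("attachment", True) and r4k.times_h[finite].min() < 24.0:
            try:
                att = attachment_slope(r4k, tuple(ana.get(
                    "attachment_window_h", (0.0, 24.0))))
                wrep["attachment"] = asdict(att)
                record(group, "attachment_slope_ohm_per_h", att.slope_ohm_per_h)
            except EcisError as exc:
                wrep["attachment"] = {"error": str(exc)}

        # wound -> healing -> rate
        if ana.get("healing", True):
            _stage(manifest, f"healing[{well}]")
            try:
                wound = detect_wound(r4k, cellfree)
                fit = fit_healing_sigmoid(r4k, wound, window_h=window)
                wrep["wound"] = {"t_wound_h": wound.t_wound_h,
                                 "baseline_ohm": wound.baseline_ohm}
                wrep["sigmoid"] = {
                    "r_base": fit.r_base, "r_plateau": fit.r_plateau,
                    "hill_slope": fit.hill_slope, "t50": fit.t50,
                    "residual_sd": fit.residual_sd,
                    "converged": fit.converged,
                }
                if fit.converged:
                    ht = healing_time(fit, threshold)
                    mr = migration_rate(ht, radius, convention)
                    wrep["migration"] = asdict(mr)
                    record(group, "migration_rate_um_per_h", mr.rate_um_per_h)
                    record(group, "hill_slope_per_h", fit.hill_slope)
                    record(group, "t50_h", fit.t50)
            except EcisError as exc:
                wrep["healing_error"] = str(exc)

        # adhesion parameter from the pre-wound plateau spectrum
        if ana.get("alpha_fit", True):
            _stage(manifest, f"alpha[{well}]")
            try:
                t_end = (wrep.get("wound", {}).get("t_wound_h")
                         or r4k.times_h[finite].max())
                # average over the stable plateau just before the wound
                alpha_window = float(ana.get("alpha_window_h", 2.0))
                wi = ts.well_index(well)
                sel = (ts.times_s / 3600.0 >= t_end - alpha_window) & \
                      (ts.times_s / 3600.0 < t_end - 0.1)
                if sel.sum() >= 10:
                    spec = np.nanmean(np.where(ts.missing[sel, wi, :],
                                               np.nan + 0j,
                                               ts.impedance[sel, wi, :]),
                                      axis=0)
                    res = fit_alpha(ts.frequencies_hz, spec, naked)
                    wrep["alpha_fit"] = {
                        "alpha": res.params.alpha, "rb": res.params.rb,
                        "cm": res.params.cm, "converged": res.converged,
                        "stderr": dict(res.stderr),
                    }
                    if res.converged:
                        record(group, "alpha_ohm_sqrt_cm", res.params.alpha)
            except EcisError as exc:
                wrep["alpha_fit"] = {"error": str(exc)}

        # micromotion transition
        if ana.get("micromotion", False):
            _stage(manifest, f"micromotion[{well}]")
            try:
                start = ana.get("micromotion_start_h")
                segs = micromotion_analysis(r4k, start_h=start)
                est = transition_half_time(segs[0])
                wrep["micromotion"] = {
                    "half_time_h": est.half_time_h,
                    "high": est.high_level, "low": est.low_level,
                    "converged": est.converged,
                }
                if est.converged:
                    record(group, "micromotion_half_time_h", est.half_time_h)
            except EcisError as exc:
                wrep["micromotion"] = {"error": str(exc)}

        report["wells"][well] = wrep

    # ---- group summaries and comparisons ---------------------------------
    _stage(manifest, "group_stats")
    for endpoint, per_group in endpoints.items():
        for group, values in per_group.items():
            gsum = report["groups"].setdefault(group, {})
            arr = np.asarray(values)
            gsum[endpoint] = {
                "n": int(arr.size), "mean": float(arr.mean()),
                "se": float(arr.std(ddof=1) / np.sqrt(arr.size))
                if arr.size > 1 else None,
            }
        usable = {g: v for g, v in per_group.items() if len(v) >= 2}
        if len(usable) >= 2:
            samples = [GroupSample(g, v) for g, v in usable.items()]
            report["comparisons"][endpoint] = tukey_kramer(
                samples, alpha=stats_alpha).to_dict()

    if sim_truth is not None:
        report["ground_truth"] = sim_truth

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    manifest.outputs["report"] = str(report_path)
    manifest_path = out / "manifest.json"
    _stage(manifest, "done")
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2))
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest, report
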