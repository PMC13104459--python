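"""End-to-end orchestration: simulate → screen → select → validate.

The pipeline runs the full workflow on a simulated (or supplied) cohort and
writes one artefact per stage plus a manifest recording the configuration
hash and seed that produced everything, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .cohort import read_cohort, write_cohort
from .errors import ConfigError
from .mi import DeltaConfig, MIConfig, calibrate_delta
from .screening import ScreeningConfig, screen
from .selection import SelectionConfig, SelectionTrace, run_selection
from .simulate import SimConfig, simulate
from .validation import Estimand, travel_back

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    sim: SimConfig | None = None
    cohort_path: Path | None = None
    meta_path: Path | None = None
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    mi: MIConfig = field(default_factory=MIConfig)
    target_sweep: int | None = None
    estimand: Estimand | None = None
    delta: DeltaConfig | None = None

    def __post_init__(self) -> None:
        if self.sim is None and self.cohort_path is None:
            raise ConfigError("cohort_path: either sim or cohort_path required")


def _config_dict(cfg) -> dict:
    from dataclasses import asdict, is_dataclass

    def conv(x):
        if is_dataclass(x) and not isinstance(x, type):
            return {k: conv(v) for k, v in asdict(x).items()}
        if isinstance(x, Path):
            return str(x)
        if isinstance(x, dict):
            return {str(k): conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        return x

    return conv(cfg)


def config_hash(cfg: RunConfig) -> str:
    d = _config_dict(cfg)
    d.pop("out_dir", None)  # where artefacts land is not part of the science
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, writing artefacts and a manifest; returns the
    manifest dict.  Any stage failure raises with a diagnostic."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: list[str] = []
    t0 = time.time()

    def stage(name):
        logger.info("stage %s at %.1fs", name, time.time() - t0)

    stage("simulate/load")
    if cfg.sim is not None:
        sim = replace(cfg.sim, seed=cfg.seed)
        cohort, truth = simulate(sim)
        write_cohort(cohort, out / "cohort.csv", out / "meta.csv")
        (out / "truth.json").write_text(truth.to_json())
        artefacts += ["cohort.csv", "meta.csv", "truth.json"]
    else:
        if cfg.cohort_path is None or cfg.meta_path is None:
            raise ConfigError("meta_path: required when loading a cohort")
        for p in (cfg.cohort_path, cfg.meta_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        cohort = read_cohort(cfg.cohort_path, cfg.meta_path)
        artefacts += [str(cfg.cohort_path), str(cfg.meta_path)]

    stage("screen")
    sres = screen(cohort, config=cfg.screening)
    sres.report.to_csv(out / "screening_report.csv")
    artefacts.append("screening_report.csv")

    stage("select")
    target = cfg.target_sweep or cohort.n_sweeps
    mi_cfg = replace(cfg.mi, seed=cfg.seed)
    trace = run_selection(sres.cohort, sres.meta, target, cfg.selection, mi_cfg)
    (out / "selection_trace.json").write_text(
        json.dumps(trace_to_dict(trace), indent=2)
    )
    artefacts.append("selection_trace.json")

    stage("validate")
    estimand = cfg.estimand or Estimand(kind="mean", variable="bas_score")
    report = travel_back(sres.cohort, estimand, target, trace.final, mi_cfg)
    (out / "validation_report.json").write_text(
        json.dumps(report.rows, indent=2, default=float)
    )
    artefacts.append("validation_report.json")

    if cfg.delta is not None and cfg.delta.benchmark is not None:
        stage("calibrate-delta")
        sub = sres.cohort.values[
            [cfg.delta.target_variable, *trace.final]
        ].copy()
        res = calibrate_delta(
            sub, {v: sres.cohort.meta[v] for v in sub.columns}, mi_cfg,
            cfg.delta,
        )
        (out / "delta.json").write_text(json.dumps(res, indent=2, default=float))
        artefacts.append("delta.json")

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "target_sweep": target,
        "artefacts": artefacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def trace_to_dict(trace: SelectionTrace) -> dict:
    def stage_dict(st):
        return {
            "kept": {str(k): v for k, v in st.kept.items()},
            "dropped": st.dropped,
        }

    return {
        "target_sweep": trace.target_sweep,
        "stage1": stage_dict(trace.stage1),
        "stage2": stage_dict(trace.stage2),
        "stage3": stage_dict(trace.stage3),
        "apriori_used": trace.apriori_used,
        "final": trace.final,
    }


def load_run_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file; ``seed`` overrides the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw: dict = {"out_dir": Path(raw.get("out_dir", "pipeline_out"))}
    if seed is not None:
        kw["seed"] = int(seed)
    elif "seed" in raw:
        kw["seed"] = int(raw["seed"])
    if "sim" in raw:
        sim_raw = dict(raw["sim"])
        if "nonresponse_rate" in sim_raw and isinstance(
            sim_raw["nonresponse_rate"], list
        ):
            sim_raw["nonresponse_rate"] = tuple(sim_raw["nonresponse_rate"])
        kw["sim"] = SimConfig(seed=kw.get("seed", 0), **sim_raw)
    for name, cls in (
        ("screening", ScreeningConfig),
        ("selection", SelectionConfig),
        ("mi", MIConfig),
        ("delta", DeltaConfig),
    ):
        if name in raw:
            section = dict(raw[name])
            if name == "selection" and "apriori" in section:
                section["apriori"] = tuple(section["apriori"])
            try:
                kw[name] = cls(**section)
            except TypeError as exc:
                raise ConfigError(f"{name}: {exc}") from exc
    if "estimand" in raw:
        kw["estimand"] = Estimand(**raw["estimand"])
    if "cohort_path" in raw:
        kw["cohort_path"] = Path(raw["cohort_path"])
        kw["meta_path"] = Path(raw.get("meta_path", ""))
    if "target_sweep" in raw:
        kw["target_sweep"] = int(raw["target_sweep"])
    return RunConfig(**kw)
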