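"""Declarative run configuration and the staged pipeline.

A :class:`RunConfig` (usually loaded from YAML) describes which stages to
run — simulate, validate, extract, mine, discover — and their parameters.
``run_pipeline`` executes the enabled stages in order and writes artifacts
under the output directory together with a ``provenance.json`` sidecar
(config hash, seed, package version) so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .cdm import CdmDataset, load_cdm, validate_cdm, write_cdm
from .cpmining import build_case_profiles, cp_report, greedy_cp_mine, \
    render_cp_report
from .discovery import compute_variants, discover_dfg, dotted_chart, \
    filter_mainstream, los_summary, write_dfg
from .extraction import LogSpec, extract_log, repair_dateonly_timestamps
from .log_io import write_log
from .synthetic import SyntheticConfig, generate_er_visits, \
    generate_inpatient_cohort, generate_outpatient_visits, \
    generate_patient_journeys

logger = logging.getLogger(__name__)

GENERATORS = {
    "inpatient": generate_inpatient_cohort,
    "outpatient": generate_outpatient_visits,
    "er": generate_er_visits,
    "journeys": generate_patient_journeys,
}


class ConfigError(Exception):
    """Raised for schema or cross-field configuration problems (exit 2)."""


class DataError(Exception):
    """Raised for problems with the input data (exit 3)."""


class SyntheticSection(BaseModel):
    generator: str = "inpatient"
    config: SyntheticConfig = Field(default_factory=SyntheticConfig)


class CpMiningSection(BaseModel):
    anchor_concept_id: Optional[int] = None
    day_window: tuple[int, int] = (-1, 2)
    k_max: int = 500
    selection: str = "application_rate"


class DiscoverySection(BaseModel):
    activity_fraction: float = 1.0
    path_fraction: float = 1.0
    stat: str = "mean"  # mean | median (performance annotation)
    sort: str = "start_time"
    time_axis: str = "absolute"


class RunConfig(BaseModel):
    seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"
    stages: list[str] = Field(
        default_factory=lambda: ["simulate", "validate", "extract", "mine",
                                 "discover"])
    cdm_dir: Optional[str] = None
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    log_spec: Optional[LogSpec] = None
    cp_mining: CpMiningSection = Field(default_factory=CpMiningSection)
    discovery: DiscoverySection = Field(default_factory=DiscoverySection)
    repair_timestamps: bool = False
    log_format: str = "csv"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config_hash(config), "seed": config.seed,
            "tool": "omopflow", "version": __version__}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the enabled stages; return a manifest of written artifacts."""
    known = {"simulate", "validate", "extract", "mine", "discover"}
    unknown = set(config.stages) - known
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    dataset: Optional[CdmDataset] = None
    truth = None
    if "simulate" in config.stages:
        gen = GENERATORS.get(config.synthetic.generator)
        if gen is None:
            raise ConfigError(
                f"unknown generator {config.synthetic.generator!r}")
        syn = config.synthetic.config.model_copy(update={"seed": config.seed})
        dataset, truth = gen(syn)
        cdm_dir = out_dir / "cdm"
        write_cdm(dataset, cdm_dir)
        artifacts["cdm_dir"] = cdm_dir
        gt_path = out_dir / "ground_truth.json"
        gt_path.write_text(json.dumps(
            {**truth.to_json(), "_provenance": _provenance(config)},
            indent=2, default=str))
        artifacts["ground_truth"] = gt_path
    elif any(s in config.stages for s in ("validate", "extract")):
        if not config.cdm_dir:
            raise ConfigError("cdm_dir is required when extract or validate "
                              "is enabled without simulate")
        try:
            dataset = load_cdm(config.cdm_dir)
        except (FileNotFoundError, ValueError) as exc:
            raise DataError(str(exc)) from exc

    if "validate" in config.stages:
        report = validate_cdm(dataset)
        path = out_dir / "validation.json"
        path.write_text(json.dumps(
            {"ok": report.ok, "counts": report.counts(),
             "violations": [vars(v) for v in report.violations[:200]],
             "_provenance": _provenance(config)}, indent=2, default=str))
        artifacts["validation"] = path
        if not report.ok:
            logger.warning("validation found %d violations",
                           len(report.violations))

    log = None
    if "extract" in config.stages:
        if config.log_spec is None:
            raise ConfigError("log_spec is required when extract is enabled")
        log = extract_log(dataset, config.log_spec)
        if config.repair_timestamps:
            log = repair_dateonly_timestamps(log)
        path = out_dir / f"event_log.{config.log_format}"
        write_log(log, path, config.log_format)
        artifacts["event_log"] = path

    if "mine" in config.stages:
        if log is None:
            raise ConfigError("mine stage needs the extract stage")
        anchor = config.cp_mining.anchor_concept_id
        if anchor is None:
            anchor = config.synthetic.config.surgery_concept_id
        profiles = build_case_profiles(log, anchor,
                                       config.cp_mining.day_window)
        if not profiles:
            raise DataError("no case profiles: anchor concept absent from "
                            "every case")
        cp = greedy_cp_mine(profiles, config.cp_mining.k_max,
                            config.cp_mining.selection)
        curve_path = out_dir / "cp_curve.csv"
        with open(curve_path, "w") as fh:
            fh.write("k,application_rate,matched_ratio,matching_rate\n")
            for k, m in enumerate(cp.curve, start=1):
                fh.write(f"{k},{m.application_rate:.6f},"
                         f"{m.matched_ratio:.6f},{m.matching_rate:.6f}\n")
        artifacts["cp_curve"] = curve_path
        resolver = dataset.concept_name if dataset is not None else \
            (lambda cid: None)
        report = cp_report(cp.optimal_entries, resolver)
        cp_json = out_dir / "cp.json"
        cp_json.write_text(json.dumps({
            "optimal_k": cp.optimal_k,
            "metrics": (cp.optimal_metrics._asdict()
                        if cp.optimal_metrics else None),
            "entries": [e._asdict() for e in cp.optimal_entries],
            "report": report,
            "_provenance": _provenance(config)}, indent=2))
        artifacts["cp"] = cp_json
        (out_dir / "cp_report.txt").write_text(render_cp_report(report) + "\n")
        artifacts["cp_report"] = out_dir / "cp_report.txt"

    if "discover" in config.stages:
        if log is None:
            raise ConfigError("discover stage needs the extract stage")
        d = config.discovery
        _, dfg = filter_mainstream(log, d.activity_fraction, d.path_fraction)
        for p in write_dfg(dfg, out_dir, d.stat):
            artifacts[p.name] = p
        variants = compute_variants(log)
        vpath = out_dir / "variants.csv"
        with open(vpath, "w") as fh:
            fh.write("variant,count,support\n")
            for seq, cnt, sup in variants.variants:
                fh.write(f"\"{' > '.join(seq)}\",{cnt},{sup:.6f}\n")
        artifacts["variants"] = vpath
        chart = dotted_chart(log, d.sort, d.time_axis)
        cpath = out_dir / "dotted_chart.csv"
        with open(cpath, "w") as fh:
            fh.write("case_index,time,activity\n")
            for idx, t, act in chart.points:
                fh.write(f"{idx},{t:.3f},\"{act}\"\n")
        artifacts["dotted_chart"] = cpath
        if log.traces and ("los_days" in log.traces[0].attributes
                           or "los_hours" in log.traces[0].attributes):
            attr = ("los_days" if "los_days" in log.traces[0].attributes
                    else "los_hours")
            summary = los_summary(log, attr)
            spath = out_dir / "los_summary.json"
            spath.write_text(json.dumps(
                {**summary, "attribute": attr,
                 "_provenance": _provenance(config)}, indent=2))
            artifacts["los_summary"] = spath

    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(
        {**_provenance(config), "artifacts": sorted(str(p) for p in
                                                    artifacts.values())},
        indent=2))
    artifacts["provenance"] = prov_path
    return artifacts
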