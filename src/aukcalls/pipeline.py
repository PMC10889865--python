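"""End-to-end analysis runner and its configuration.

Stages: obtain a feature table (simulate / extract from audio / read CSV),
nested permuted DFA for the context effect, per-parameter mixed models with
parametric-bootstrap p-values, then per-context KMO + PCA + Beecher's Hs.
One master seed deterministically derives every stage seed, so a config file
fully reproduces a run.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustics import AnalysisSettings, extract_features
from .callsim import SimConfig, generate_dataset
from .individuality import HsSettings, format_hs_table, individuality_report
from .io import load_annotated_calls, read_feature_csv, write_feature_csv
from .mixedmodels import format_lmm_table, run_context_models
from .pdfa import PDFASettings, format_pdfa_table, nested_pdfa
from .schema import (
    ConfigError,
    DataError,
    REPORT_SCHEMA_VERSION,
    validate_report,
)

logger = logging.getLogger(__name__)

#: Stage names, in execution order (used for seed derivation and MANIFEST).
STAGES = ("simulate", "extract", "pdfa", "lmm", "individuality")


def stage_seeds(master_seed: int) -> Dict[str, int]:
    """Derive one sub-seed per stage from the master seed.

    Uses numpy's SeedSequence keyed by (master, stage index); values are kept
    below 2**31 so they survive any integer round-trip.
    """
    return {
        name: int(np.random.SeedSequence([master_seed, i]).generate_state(1)[0]
                  % (2**31))
        for i, name in enumerate(STAGES)
    }


@dataclass
class PipelineConfig:
    """Full pipeline configuration (round-trips losslessly through YAML).

    Exactly one input mode: "simulate" (tier feature or audio), "audio"
    (WAV + selection table paths) or "features" (existing feature CSV).
    """

    mode: str = "simulate"
    tier: str = "feature"
    wav_path: Optional[str] = None
    selection_table_path: Optional[str] = None
    feature_csv_path: Optional[str] = None
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    pdfa: PDFASettings = field(default_factory=PDFASettings)
    hs: HsSettings = field(default_factory=HsSettings)
    lmm_n_boot: int = 1000
    output_dir: str = "results/run"
    seed: int = 1
    log_level: str = "INFO"
    config_version: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "audio", "features"):
            raise ConfigError(f"unknown input mode {self.mode!r}")
        if self.mode == "audio" and not (self.wav_path and self.selection_table_path):
            raise ConfigError("audio mode needs wav_path and selection_table_path")
        if self.mode == "features" and not self.feature_csv_path:
            raise ConfigError("features mode needs feature_csv_path")

    def resolve_seeds(self) -> "PipelineConfig":
        """Copy with every stage seed derived from the master seed."""
        seeds = stage_seeds(self.seed)
        cfg = dataclasses.replace(self)
        cfg.sim = dataclasses.replace(self.sim, seed=seeds["simulate"])
        cfg.pdfa = dataclasses.replace(self.pdfa, seed=seeds["pdfa"])
        cfg.hs = dataclasses.replace(self.hs, seed=seeds["individuality"])
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        blob = asdict(self)
        blob["sim"]["context_means"] = {
            k: list(v) for k, v in blob["sim"]["context_means"].items()
        }
        Path(path).write_text(yaml.safe_dump(blob, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        blob = yaml.safe_load(Path(path).read_text())
        for key, sub in (("sim", SimConfig), ("analysis", AnalysisSettings),
                         ("pdfa", PDFASettings), ("hs", HsSettings)):
            if key in blob and isinstance(blob[key], dict):
                if key == "sim" and "context_means" in blob[key]:
                    blob[key]["context_means"] = {
                        k: tuple(v) for k, v in blob[key]["context_means"].items()
                    }
                blob[key] = sub(**blob[key])
        return cls(**blob)


def _features_stage(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.mode == "features":
        return read_feature_csv(cfg.feature_csv_path)
    if cfg.mode == "audio":
        calls = load_annotated_calls(cfg.wav_path, cfg.selection_table_path)
    else:
        ds = generate_dataset(cfg.sim, tier=cfg.tier)
        if cfg.tier == "feature":
            return ds.features
        calls = ds.recordings
    rows = []
    n_short = 0
    for rec in calls:
        try:
            fv = extract_features(rec, cfg.analysis)
        except DataError as err:
            logger.warning("call %s excluded: %s", rec.call_id, err)
            n_short += 1
            continue
        rows.append({"call_id": rec.call_id, "individual_id": rec.individual_id,
                     "context": rec.context, **fv.as_row()})
    if not rows:
        raise DataError("no usable calls after extraction")
    if n_short:
        logger.info("extraction: excluded %d unusable calls", n_short)
    return pd.DataFrame(rows)


def run_full_analysis(config: PipelineConfig, write: bool = True) -> Dict:
    """Execute the full pipeline; returns (and optionally writes) the report.

    Any stage failure halts with the stage name; outputs completed so far are
    kept, and a MANIFEST lists the completed stages.
    """
    logging.getLogger("aukcalls").setLevel(config.log_level.upper())
    cfg = config.resolve_seeds()
    outdir = Path(cfg.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    completed: List[str] = []

    def checkpoint(stage: str) -> None:
        completed.append(stage)
        if write:
            (outdir / "MANIFEST").write_text("\n".join(completed) + "\n")

    def fail(stage: str, err: Exception) -> None:
        raise DataError(f"stage {stage!r} failed: {err}") from err

    try:
        features = _features_stage(cfg)
    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        fail("features", err)
    n_missing_f0 = int(features["mean_f0_hz"].isna().sum())
    usable = features.dropna(subset=["mean_f0_hz"])
    if write:
        write_feature_csv(outdir / "features.csv", features)
    checkpoint("features")

    try:
        pdfa_result = nested_pdfa(usable, cfg.pdfa)
    except Exception as err:
        fail("pdfa", err)
    if write:
        (outdir / "table_pdfa.txt").write_text(format_pdfa_table(pdfa_result) + "\n")
    checkpoint("pdfa")

    try:
        lmm_reports = run_context_models(usable, n_boot=cfg.lmm_n_boot,
                                         seed=stage_seeds(cfg.seed)["lmm"])
    except Exception as err:
        fail("lmm", err)
    if write:
        (outdir / "table_lmm.txt").write_text(format_lmm_table(lmm_reports) + "\n")
    checkpoint("lmm")

    hs_reports = {}
    hs_errors = {}
    for ctx in sorted(usable["context"].unique()):
        try:
            hs_reports[ctx] = individuality_report(usable, context=ctx,
                                                   settings=cfg.hs)
        except DataError as err:
            logger.warning("individuality (%s) skipped: %s", ctx, err)
            hs_errors[ctx] = str(err)
    if not hs_reports:
        fail("individuality", DataError(f"no context usable: {hs_errors}"))
    if write:
        (outdir / "table_hs.txt").write_text(format_hs_table(hs_reports) + "\n")
    checkpoint("individuality")

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "software_version": __version__,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "n_calls": int(len(features)),
        "pdfa": pdfa_result.as_dict(),
        "lmm": {k: v.as_dict() for k, v in lmm_reports.items()},
        "individuality": {k: v.as_dict() for k, v in hs_reports.items()},
        "logs": {
            "n_calls_missing_f0": n_missing_f0,
            "latent_repairs": dict(getattr(features, "attrs", {}).get("repairs", {})),
            "individuality_skipped": hs_errors,
            "completed_stages": completed,
        },
    }
    validate_report(report)
    if write:
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       default=float))
    return report
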