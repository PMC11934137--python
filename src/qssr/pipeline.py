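"""End-to-end orchestration: simulate/descriptors -> model search -> classify.

A run is described by a :class:`RunConfig` (usually parsed from one YAML
file, with CLI flags overriding).  Every stage declares its inputs and
outputs; the merged effective config -- with no hidden defaults -- is
serialized next to the outputs together with a run record carrying the config
hash, so any tabular artifact can be traced to the exact settings that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import mvlr, synthetic, threshold
from .structures import read_xyz
from .table import (
    DescriptorTable,
    StericSettings,
    attach_computed_descriptors,
    load_table,
    save_table,
)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "descriptors", "model-search", "classify")


class ConfigError(ValueError):
    """Invalid run configuration; raised before any computation starts."""


@dataclass
class ModelSearchConfig:
    max_features: int = 6
    ranking: str = "r2_test"
    split_seed: int | None = None  # reassign split randomly when set
    test_fraction: float = 0.2
    loo_method: str = "hat"


@dataclass
class ClassifyConfig:
    yield_cutoff: float = 50.0
    features: list[str] = field(default_factory=list)  # empty = all descriptors


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: ["simulate", "model-search", "classify"])
    outdir: str = "qssr_run"
    table_path: str | None = None  # input table when 'simulate' is not run
    geometries_path: str | None = None  # multi-XYZ for the 'descriptors' stage
    synthetic: synthetic.SyntheticSpec = field(default_factory=synthetic.SyntheticSpec)
    steric: StericSettings = field(default_factory=StericSettings)
    model_search: ModelSearchConfig = field(default_factory=ModelSearchConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
        if not self.stages:
            raise ConfigError("no stages selected")
        if "simulate" not in self.stages and self.table_path is None:
            raise ConfigError("table_path is required when 'simulate' is not among the stages")
        if "descriptors" in self.stages and self.geometries_path is None:
            raise ConfigError("geometries_path is required for the 'descriptors' stage")

    def effective_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        # hash only reproduction-critical settings: where outputs land and
        # how chatty the log is do not change any computed value
        d = self.effective_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    # tuples arrive from YAML as lists
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list) and "tuple" in str(f.type):
            v = tuple(v)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from None


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus flat override entries."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    sub = {
        "synthetic": _build(synthetic.SyntheticSpec, data.pop("synthetic", {}), "synthetic"),
        "steric": _build(StericSettings, data.pop("steric", {}), "steric"),
        "model_search": _build(ModelSearchConfig, data.pop("model_search", {}), "model_search"),
        "classify": _build(ClassifyConfig, data.pop("classify", {}), "classify"),
    }
    cfg = _build(RunConfig, {**data, **sub}, "run config")
    cfg.validate()
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order; returns the run record.

    Validation happens before any compute.  Stage outputs land in
    ``config.outdir``; the first hard error aborts with the stage name while
    earlier outputs are left in place.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    record: dict = {"config_hash": chash, "stages": [], "outputs": {}}

    # validation-first: a model search needs a response column
    table: DescriptorTable | None = None
    if config.table_path is not None:
        table = load_table(config.table_path)
        if "model-search" in config.stages and "simulate" not in config.stages:
            if "response" not in table.df.columns:
                raise ConfigError(
                    "model-search requested but the input table has no "
                    "'response' column"
                )

    current_stage = "setup"
    try:
        for stage in [s for s in STAGES if s in config.stages]:
            current_stage = stage
            logger.info("stage %s (config %s)", stage, chash)
            if stage == "simulate":
                table = synthetic.generate_table(config.synthetic)
                path = outdir / "table.csv"
                save_table(table, path)
                record["outputs"]["table"] = str(path)
            elif stage == "descriptors":
                assert table is not None
                mols = read_xyz(config.geometries_path)
                geometries = {m.title.split()[0] if m.title else f"L{i+1}": m
                              for i, m in enumerate(mols)}
                table = attach_computed_descriptors(table, geometries, config.steric)
                path = outdir / "table_with_steric.csv"
                save_table(table, path)
                record["outputs"]["table_with_steric"] = str(path)
            elif stage == "model-search":
                assert table is not None
                ms = config.model_search
                if ms.split_seed is not None or "split" not in table.df.columns:
                    df = table.df.copy()
                    df["split"] = mvlr.random_split(
                        len(df), ms.test_fraction, ms.split_seed
                    )
                    table = DescriptorTable(df=df, provenance=table.provenance)
                results, skipped = mvlr.exhaustive_search(
                    table,
                    max_features=ms.max_features,
                    ranking=ms.ranking,
                    loo_method=ms.loo_method,
                )
                board = mvlr.leaderboard_frame(results)
                board.insert(0, "config_hash", chash)
                path = outdir / "leaderboard.csv"
                board.to_csv(path, index=False)
                record["outputs"]["leaderboard"] = str(path)
                record["n_models"] = len(results)
                record["n_skipped"] = len(skipped)
                if results:
                    best = results[0]
                    record["best_model"] = {
                        "features": list(best.model.features),
                        "coefficients_std": best.model.coefficients.tolist(),
                        "intercept": best.model.intercept,
                        "evaluation": asdict(best.evaluation),
                    }
            elif stage == "classify":
                assert table is not None
                feats = config.classify.features or table.descriptor_names
                results, failures = threshold.classify_all(
                    table, feats, cutoff=config.classify.yield_cutoff
                )
                import pandas as pd

                rows = [
                    {
                        "config_hash": chash,
                        "feature": r.feature,
                        "cut": r.cut,
                        "direction": r.direction,
                        "threshold_kind": r.kind,
                        "accuracy": r.accuracy,
                        "tp": r.confusion[0],
                        "fp": r.confusion[1],
                        "fn": r.confusion[2],
                        "tn": r.confusion[3],
                        "gap_low": r.cut_interval[0],
                        "gap_high": r.cut_interval[1],
                        "degenerate": r.degenerate,
                    }
                    for r in results
                ]
                path = outdir / "thresholds.csv"
                pd.DataFrame(rows).to_csv(path, index=False)
                record["outputs"]["thresholds"] = str(path)
                record["threshold_failures"] = failures
            record["stages"].append(stage)
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {current_stage!r} failed: {exc}") from exc

    (outdir / "effective_config.yaml").write_text(
        yaml.safe_dump(config.effective_dict(), sort_keys=True)
    )
    (outdir / "run_record.json").write_text(json.dumps(record, indent=2, default=str))
    return record
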