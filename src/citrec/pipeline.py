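"""Full-pipeline orchestration: ingest -> engagement -> profiling ->
spatial -> taxa -> traits from one configuration.

Each enabled stage writes its own CSV outputs under the run directory
and contributes to a machine-readable ``summary.json`` that embeds the
seed and a hash of the configuration, so a rerun with the same config
is byte-for-byte reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import engagement, profiling, records_io, spatial, taxa, traits

__all__ = ["RunConfig", "StageFailure", "run_pipeline"]

logger = logging.getLogger("citrec")


class StageFailure(RuntimeError):
    """A pipeline stage failed; the stage name is in ``.stage``."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative pipeline run.

    ``input_csv`` is a raw occurrence CSV; stage toggles and the module
    parameters mirror the individual stage interfaces.
    """

    input_csv: str
    output_dir: str
    seed: int = 17
    collapse_synonyms: bool = False
    max_precision_m: int = 1000
    stages: tuple[str, ...] = ("ingest", "engagement", "profile", "spatial", "taxa")
    k_min: int = 2
    k_max: int = 8
    asw_threshold: float = profiling.ASW_THRESHOLD
    pairing: str = "union"
    family_alpha: float = 0.05
    mapping_csv: str | None = None
    checklist_csv: str | None = None
    traits_csv: str | None = None
    trait_columns: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "trait_columns"):
            if key in doc:
                doc[key] = tuple(doc[key])
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ValueError(f"invalid config: {exc}") from exc

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            default=str,
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the summary dict (also written to ``summary.json``).  A
    stage failure raises :class:`StageFailure`; outputs of completed
    stages are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    summary: dict = {"seed": config.seed, "config_hash": config.digest(), "stages": {}}
    clean = None
    metrics = None
    try:
        if "ingest" in config.stages:
            clean, audit = _stage("ingest", _ingest, config, out)
            summary["stages"]["ingest"] = audit.to_dict()
        if "engagement" in config.stages:
            metrics = _stage("engagement", _engagement, config, out, clean)
            summary["stages"]["engagement"] = {"n_volunteers": int(len(metrics))}
        if "profile" in config.stages:
            diag = _stage("profile", _profile, config, out, metrics)
            summary["stages"]["profile"] = diag
        if "spatial" in config.stages:
            summary["stages"]["spatial"] = _stage("spatial", _spatial, config, out, clean)
        if "taxa" in config.stages:
            summary["stages"]["taxa"] = _stage("taxa", _taxa, config, out, clean)
        if "traits" in config.stages:
            summary["stages"]["traits"] = _stage("traits", _traits, config, out)
    finally:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.removeHandler(handler)
        handler.close()
    return summary


def _stage(name, fn, *args):
    logger.info("running stage %s", name)
    try:
        return fn(*args)
    except StageFailure:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise StageFailure(name, exc) from exc


def _ingest(config: RunConfig, out: Path):
    raw = records_io.read_raw_csv(config.input_csv)
    policy = records_io.IngestPolicy(
        max_precision_m=config.max_precision_m,
        collapse_synonyms=config.collapse_synonyms,
    )
    clean, audit = records_io.clean_records(raw, policy)
    if config.mapping_csv:
        clean = taxa.assign_groups(clean, taxa.load_mapping(config.mapping_csv))
    clean.to_csv(out / "clean.csv", index=False)
    with open(out / "audit.json", "w") as fh:
        json.dump(audit.to_dict(), fh, indent=2)
    return clean, audit


def _load_clean(config: RunConfig, out: Path, clean):
    if clean is not None:
        return clean
    path = out / "clean.csv"
    if not path.exists():
        raise ValueError("ingest stage disabled and no clean.csv present")
    return pd.read_csv(path, parse_dates=["date"])


def _engagement(config: RunConfig, out: Path, clean):
    clean = _load_clean(config, out, clean)
    individual = clean[~clean["is_group"] & ~clean["is_anonymous"]]
    metrics = engagement.engagement_table(individual)
    metrics.to_csv(out / "engagement.csv")
    return metrics


def _profile(config: RunConfig, out: Path, metrics):
    if metrics is None:
        metrics = pd.read_csv(out / "engagement.csv", index_col="recorder_id")
    profiler = profiling.EngagementProfiler(
        metrics,
        k_range=range(config.k_min, config.k_max + 1),
        asw_threshold=config.asw_threshold,
    )
    results = profiler.fit(seed=config.seed)
    results.assignments.to_csv(out / "profiles.csv")
    results.summary().to_csv(out / "profile_summary.csv")
    diag = results.diagnostics()
    with open(out / "profile_diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    return diag


def _spatial(config: RunConfig, out: Path, clean):
    clean = _load_clean(config, out, clean)
    cells = spatial.aggregate_cells(clean)
    cells.to_csv(out / "cells.csv")
    spatial.cells_to_geojson(cells[spatial.CELL_METRICS], out / "cells.geojson")
    tops = {
        metric: spatial.hotspots(cells, metric)["monad"].tolist()
        for metric in ("n_records", "n_volunteers", "n_informal_groups")
    }
    pd.concat(
        [spatial.hotspots(cells, m).assign(metric=m) for m in tops], ignore_index=True
    ).to_csv(out / "hotspots.csv", index=False)
    return {"n_cells": int(len(cells)), "top10": tops}


def _taxa(config: RunConfig, out: Path, clean):
    clean = _load_clean(config, out, clean)
    if "informal_group" not in clean.columns:
        raise ValueError("taxa stage needs group labels; supply mapping_csv")
    checklist = (
        taxa.load_checklist(config.checklist_csv)
        if config.checklist_csv
        else taxa.default_checklist()
    )
    comp = taxa.composition(clean, "higher")
    comp.to_csv(out / "composition_higher.csv")
    stats = taxa.group_stats(clean, checklist)
    stats.to_csv(out / "group_stats.csv")
    return {
        "composition_higher": comp["percent"].round(1).to_dict(),
        "n_groups": int(len(stats)),
    }


def _traits(config: RunConfig, out: Path):
    if not config.traits_csv or not config.trait_columns:
        raise ValueError("traits stage needs traits_csv and trait_columns")
    data = pd.read_csv(config.traits_csv)
    screen = traits.trait_screen(
        data, list(config.trait_columns), family_alpha=config.family_alpha
    )
    table = screen.summary()
    table.to_csv(out / "traits_results.csv", index=False)
    return {
        "n_tests": int(len(table)),
        "significant_raw": table.loc[table["sig_raw"], "trait"].tolist(),
    }
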