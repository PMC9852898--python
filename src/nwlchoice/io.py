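"""On-disk layout of a pipeline run: versioned CSV tables, JSON summaries,
a YAML study configuration, and a manifest with content digests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ddm import DDMParams
from .synthetic import (
    ContaminationRates,
    RatingModel,
    StudyConfig,
    SyntheticStudy,
)

SCHEMA_VERSION = 1

__all__ = [
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "load_config",
    "dump_config",
    "write_study",
    "read_study_tables",
    "file_digest",
    "Manifest",
]


def write_table(df: pd.DataFrame, path: Path | str, name: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# nwlchoice {name} schema v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(data: dict, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(data), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def dump_config(config: StudyConfig, path: Path | str) -> Path:
    """Serialize a StudyConfig to YAML mirroring its field names."""
    data = {
        "n_participants": config.n_participants,
        "contexts": list(config.contexts),
        "pairs_per_combo": config.pairs_per_combo,
        "timeout": config.timeout,
        "sampling_rate_mean": config.sampling_rate_mean,
        "sampling_rate_sd": config.sampling_rate_sd,
        "pair_drift_sd": config.pair_drift_sd,
        "dnwl_drift_slope": config.dnwl_drift_slope,
        "conflict_gain": config.conflict_gain,
        "rng_seed": config.rng_seed,
        "rating_model": asdict(config.rating_model),
        "contamination": asdict(config.contamination),
        "ddm_truth": {
            ctx: {
                ("nwl" if shown else "no_nwl"): {
                    "boundary_sep": p.boundary_sep,
                    "non_decision": p.non_decision,
                    "bias": p.bias,
                    "drift": p.drift,
                }
                for (c, shown), p in config.ddm_truth.items()
                if c == ctx
            }
            for ctx in config.contexts
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_jsonify(data), sort_keys=False))
    return path


def load_config(path: Path | str) -> StudyConfig:
    """Read a YAML study configuration; absent fields keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    simple = (
        "n_participants", "pairs_per_combo", "timeout", "sampling_rate_mean",
        "sampling_rate_sd", "pair_drift_sd", "dnwl_drift_slope",
        "conflict_gain", "rng_seed",
    )
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    if "contexts" in raw:
        kwargs["contexts"] = tuple(raw["contexts"])
    if "rating_model" in raw:
        kwargs["rating_model"] = RatingModel(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in raw["rating_model"].items()}
        )
    if "contamination" in raw:
        kwargs["contamination"] = ContaminationRates(**raw["contamination"])
    if "ddm_truth" in raw:
        truth = {}
        for ctx, blocks in raw["ddm_truth"].items():
            for label, p in blocks.items():
                truth[(ctx, label == "nwl")] = DDMParams(**p)
        kwargs["ddm_truth"] = truth
    return StudyConfig(**kwargs)


def write_study(study: SyntheticStudy, out_dir: Path | str) -> dict[str, Path]:
    """Write trials/paths/ratings/participants/truth (and the inventory
    table) for one synthetic study."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "trials": write_table(study.trials, out / "trials.csv", "trials"),
        "paths": write_table(study.paths, out / "paths.csv", "paths"),
        "ratings": write_table(study.ratings, out / "ratings.csv", "ratings"),
        "participants": write_table(
            study.participants, out / "participants.csv", "participants"
        ),
        "truth": write_json(study.truth, out / "truth.json"),
    }
    inv_rows = [
        {
            "context": ctx,
            "image_id": img.image_id,
            "category": img.category,
            "nwl_count": img.nwl_count,
            "kcal": img.kcal,
            "sat_fat_g": img.sat_fat_g,
            "sugar_g": img.sugar_g,
            "sodium_mg": img.sodium_mg,
        }
        for ctx, inv in study.inventories.items()
        for img in inv.images
    ]
    files["inventories"] = write_table(
        pd.DataFrame(inv_rows), out / "inventories.csv", "inventories"
    )
    files["config"] = dump_config(study.config, out / "config.yaml")
    return files


def read_study_tables(in_dir: Path | str) -> dict[str, pd.DataFrame]:
    out = {}
    in_dir = Path(in_dir)
    for name in ("trials", "paths", "ratings", "participants"):
        p = in_dir / f"{name}.csv"
        if p.exists():
            out[name] = read_table(p)
    return out


def file_digest(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Run manifest: config snapshot, seeds, per-stage outputs with sha256
    digests, timestamps."""

    def __init__(self, path: Path | str):
        self.path = Path(path)
        if self.path.exists():
            self.data = read_json(self.path)
        else:
            self.data = {"schema": SCHEMA_VERSION, "stages": {}}

    def record_stage(self, name: str, outputs: dict[str, Path], extra: dict | None = None):
        self.data["stages"][name] = {
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "outputs": {
                key: {"path": str(p), "sha256": file_digest(p)}
                for key, p in outputs.items()
            },
            **(extra or {}),
        }
        write_json(self.data, self.path)

    def set_config(self, config_snapshot: dict, seed: int):
        self.data["config"] = _jsonify(config_snapshot)
        self.data["master_seed"] = int(seed)
        write_json(self.data, self.path)
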