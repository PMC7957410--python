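"""CellTable serialisation, YAML configuration and run provenance."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import GeneParams, GeneratorParams, StudyDesign, default_params

log = logging.getLogger("circaburst")

REQUIRED_COLUMNS = ("time_h", "area", "replicate")


def write_cell_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cell_table(path, renormalise_area: bool = True) -> pd.DataFrame:
    """Read and validate a tab-delimited CellTable.

    Required columns: time_h, area, replicate and at least one count_<gene>
    column.  Counts must be non-negative integers (empty cells are allowed
    and treated as held-out); areas must be positive and are renormalised to
    mean 1 (the scale factor is logged).
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    count_cols = [c for c in table.columns if c.startswith("count_")]
    if not count_cols:
        raise ValueError(f"{path}: no count_<gene> columns found")
    for col in count_cols:
        vals = table[col]
        bad = vals.notna() & ((vals < 0) | (vals != np.round(vals)))
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: column {col!r} has a non-integer or negative "
                f"count at row {row} (value {vals.iloc[row]!r})")
    area = table["area"].to_numpy(dtype=float)
    if np.any(~np.isfinite(area)) or np.any(area <= 0):
        row = int(np.argmax(~np.isfinite(area) | (area <= 0)))
        raise ValueError(f"{path}: non-positive area at row {row}")
    if renormalise_area:
        scale = float(area.mean())
        if not np.isclose(scale, 1.0):
            log.info("renormalising areas by factor %.6g", scale)
        table["area"] = area / scale
    if "cell_id" not in table.columns:
        table.insert(0, "cell_id", np.arange(len(table)))
    return table


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Pipeline configuration; every stochastic stage derives its seed from
    the single root seed."""

    seed: int
    outdir: str = "circaburst_run"
    models: tuple = ("M1", "M2", "M4")
    generator_model: str = "M4"
    chains: int = 4
    draws: int = 1000
    cv_S: int = 1000
    run_cv: bool = False
    design: StudyDesign = field(default_factory=StudyDesign)
    params: GeneratorParams = field(default_factory=default_params)

    def to_dict(self) -> dict:
        return _plain(asdict(self))


def _plain(obj):
    """Recursively convert tuples/numpy scalars to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "seed" not in raw or raw["seed"] is None:
        raise ValueError("config must set an explicit seed")
    design = StudyDesign(**{**raw.get("design", {}),
                            "times": tuple(raw.get("design", {}).get(
                                "times", StudyDesign().times)),
                            "gene_pair": tuple(raw.get("design", {}).get(
                                "gene_pair", StudyDesign().gene_pair))})
    praw = dict(raw.get("params", {}))
    genes = tuple(GeneParams(**g) for g in praw.pop("genes", []))
    params = (GeneratorParams(genes=genes, **praw) if genes
              else default_params())
    kwargs = {k: v for k, v in raw.items() if k not in ("design", "params")}
    if "models" in kwargs:
        kwargs["models"] = tuple(kwargs["models"])
    return RunConfig(design=design, params=params, **kwargs)


def config_hash(config: RunConfig) -> str:
    doc = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
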