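"""Serialization of fit results, latent scores and study configurations."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .inference import LatentScores
from .model import FitResult
from .simulate import SimulationConfig


def write_fit_result(fit: FitResult, csv_path, json_path=None) -> None:
    """Write the parameter table as CSV and the fit header as JSON.

    The JSON path defaults to the CSV path with a ``.json`` suffix.
    """
    csv_path = Path(csv_path)
    fit.to_frame().to_csv(csv_path, index=False)
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    json_path.write_text(json.dumps(fit.header(), indent=1))


def write_latent_scores(scores: LatentScores, path, sample_ids=None) -> None:
    scores.to_frame(index=sample_ids).to_csv(path, index_label="sample_id")


def load_config(path) -> SimulationConfig:
    """Read a simulation configuration from a YAML or JSON file.

    Unknown keys raise, so typos do not silently fall back to defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    for key in ("group_sizes", "maf_beta_shapes", "loading_range"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)


def write_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    data = dataclasses.asdict(config)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    path.write_text(yaml.safe_dump(data, sort_keys=False))


def write_study_result(result, csv_path, json_path=None) -> None:
    """Tidy long-format study table (metric, value per replicate) + summary."""
    csv_path = Path(csv_path)
    aic = result.aic.rename(columns={"model": "name", "aic": "value"}).assign(metric="aic")
    auc = result.auc.rename(columns={"method": "name", "auc": "value"}).assign(metric="auc")
    pd.concat([aic, auc], ignore_index=True).to_csv(csv_path, index=False)
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    json_path.write_text(json.dumps(result.summary(), indent=1))
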