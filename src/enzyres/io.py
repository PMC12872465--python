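"""Run configuration, external-data loading and report export."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import EvaluationReport, Protocol
from .table import META_PREFIX, FeatureTable


class UserInputError(ValueError):
    """A problem attributable to the user's files or configuration."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: scenario, tasks, protocol, seeds."""

    scenario: str = "classification"
    scenario_params: dict = field(default_factory=dict)
    dataset: str | None = None  # path to a pre-simulated table instead
    tasks: list[dict] = field(default_factory=lambda: [{"name": "xor"}])
    trainer: dict = field(default_factory=lambda: {"alpha": 1.0, "C": 1.0})
    protocol: dict = field(default_factory=dict)
    reservoir_seed: int = 0
    scenario_seed: int = 1
    cv_seed: int = 0
    enzymes: list[str] | None = None
    snr_group_key: str | None = None
    outdir: str = "runs"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise UserInputError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise UserInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def make_protocol(self) -> Protocol:
        return Protocol(**self.protocol)


def load_external_table(path, mapping: dict | str | Path, sep: str = ",") -> FeatureTable:
    """Load a deposited processed-data table through an explicit mapping.

    ``mapping`` (a dict or a YAML file) must contain ``features`` (list of
    column names, or ``{"prefix": str}``) and ``metadata`` ({meta key ->
    source column}); nothing is guessed silently.  Malformed numeric cells
    raise with the offending row index.
    """
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"data file not found: {path}")
    if not isinstance(mapping, dict):
        with open(mapping) as fh:
            mapping = yaml.safe_load(fh)
    if "features" not in mapping or "metadata" not in mapping:
        raise UserInputError("mapping must define 'features' and 'metadata'")
    raw = pd.read_csv(path, sep=sep)
    feats = mapping["features"]
    if isinstance(feats, dict) and "prefix" in feats:
        feature_cols = [c for c in raw.columns if c.startswith(feats["prefix"])]
    else:
        feature_cols = list(feats)
    missing = [c for c in feature_cols if c not in raw.columns]
    missing += [c for c in mapping["metadata"].values() if c not in raw.columns]
    if missing:
        raise UserInputError(f"mapped columns absent from {path.name}: {missing}")
    out = {}
    for key, col in mapping["metadata"].items():
        name = key if key.startswith(META_PREFIX) else META_PREFIX + key
        out[name] = raw[col]
    for col in feature_cols:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[vals.isna() & raw[col].notna()]
        if len(bad):
            raise UserInputError(
                f"malformed numeric value in column {col!r}, row(s) {list(bad[:5])}"
            )
        out[col] = vals
    return FeatureTable(pd.DataFrame(out))


def export_report(report: EvaluationReport, outdir, stem: str) -> list[Path]:
    """Write per-split scores (TSV) plus a text summary; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    scores_path = outdir / f"{stem}_scores.tsv"
    if report.kind == "binary":
        pd.DataFrame({"split": np.arange(len(report.scores)),
                      "transformed_phi": report.scores}).to_csv(
            scores_path, sep="\t", index=False)
    else:
        report.predictions.to_csv(scores_path, sep="\t", index=False)
    written.append(scores_path)
    summary_path = outdir / f"{stem}_summary.txt"
    summary_path.write_text(report.summary() + "\n")
    written.append(summary_path)
    return written
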