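"""Configuration, readers and writers for reproducible runs.

Artifacts are plain CSV plus JSON sidecars: the unit of analysis is a flat
cell table, so no geospatial serialization is needed.  All randomness
flows from seeds recorded in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .glm import INTERCEPT, FittedLogisticModel
from .pipeline import PartitionResult, PredictorTable, RunResult
from .synthetic import ClimateScenario


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything a run needs, loadable from YAML."""

    grid_csv: str | None = None
    scenario_csvs: list[str] = field(default_factory=list)
    output_dir: str = "out"
    sets: dict[str, str] = field(default_factory=dict)
    q: float = 0.05
    p_enter: float = 0.05
    p_remove: float = 0.10
    split_fraction: float = 0.7
    split_seed: int = 0
    stratified: bool = False
    low_cut: float = 0.2
    high_cut: float = 0.8
    trend_surface_mode: str = "all-data"
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("q", "p_enter", "p_remove", "split_fraction", "low_cut", "high_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}={v} must lie in (0, 1)")
        if self.p_enter > self.p_remove:
            raise ConfigError("p_enter must not exceed p_remove")
        if not self.low_cut < self.high_cut:
            raise ConfigError("low_cut must be below high_cut")
        if self.trend_surface_mode not in ("all-data", "split-safe"):
            raise ConfigError("trend_surface_mode must be 'all-data' or 'split-safe'")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
    try:
        return RunConfig(**raw)
    except TypeError as err:
        raise ConfigError(str(err)) from None


def read_grid_csv(path, sets: dict[str, str]) -> tuple[PredictorTable, np.ndarray]:
    """Load a grid CSV into a PredictorTable plus the presence vector."""
    data = pd.read_csv(path)
    for col in ("cell_id", "lon", "lat", "presence"):
        if col not in data.columns:
            raise ValueError(f"grid table lacks required column {col!r}")
    missing = [c for c in sets if c not in data.columns]
    if missing:
        raise ValueError(f"assigned columns missing from grid table: {', '.join(missing)}")
    presence = data["presence"].to_numpy()
    return PredictorTable(data=data, sets=dict(sets)), presence


def read_scenario_csv(path, label: str | None = None) -> ClimateScenario:
    repl = pd.read_csv(path)
    if "cell_id" not in repl.columns:
        raise ValueError(f"scenario table {path} lacks 'cell_id'")
    return ClimateScenario(label=label or Path(path).stem, replacements=repl)


def model_to_dict(model: FittedLogisticModel) -> dict:
    return {
        "terms": model.terms,
        "beta": {t: float(b) for t, b in zip(model.terms, model.beta)},
        "se": {t: float(s) for t, s in zip(model.terms, model.se)},
        "p_value": {t: float(p) for t, p in zip(model.terms, model.p_value)},
        "entry_order": model.entry_order,
        "log_lik": model.log_lik,
        "null_log_lik": model.null_log_lik,
        "n": model.n,
        "n1": model.n1,
        "n0": model.n0,
        "converged": model.converged,
        "separation": model.separation,
    }


def model_from_dict(d: dict) -> FittedLogisticModel:
    terms = list(d["terms"])
    return FittedLogisticModel(
        terms=terms,
        beta=np.array([d["beta"][t] for t in terms]),
        se=np.array([d["se"][t] for t in terms]),
        p_value=np.array([d["p_value"][t] for t in terms]),
        log_lik=d["log_lik"],
        null_log_lik=d["null_log_lik"],
        n=d["n"],
        n1=d["n1"],
        n0=d["n0"],
        entry_order={k: int(v) for k, v in d["entry_order"].items()},
        converged=d["converged"],
        separation=d["separation"],
    )


def write_model_json(path, model: FittedLogisticModel) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def read_model_json(path) -> FittedLogisticModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def evaluation_frame(result: RunResult) -> pd.DataFrame:
    """Per-variable coefficients and per-model metrics, long format."""
    rows = []
    for kind, model, report, vifs in (
        ("space-included", result.pair.space_included, result.pair.eval_included, result.pair.vif_included),
        ("space-excluded", result.pair.space_excluded, result.pair.eval_excluded, result.pair.vif_excluded),
    ):
        for t, b, s, p in zip(model.terms, model.beta, model.se, model.p_value):
            rows.append(
                {
                    "model": kind,
                    "row": "coefficient",
                    "term": t,
                    "beta": b,
                    "se": s,
                    "sig": p,
                    "order": model.entry_order.get(t, ""),
                    "vif": float(vifs[t]) if vifs is not None and t in vifs.index else "",
                }
            )
        if report is not None:
            for metric in ("deviance_explained", "auc", "sensitivity", "specificity", "ccr", "aic"):
                rows.append({"model": kind, "row": "metric", "term": metric, "beta": getattr(report, metric)})
    return pd.DataFrame(rows)


def partition_frame(partition: PartitionResult | None, model_label: str) -> pd.DataFrame:
    if partition is None:
        return pd.DataFrame(columns=["model", "subset", "fraction", "percent"])
    pct = partition.as_percentages()
    rows = [
        {
            "model": model_label,
            "subset": "+".join(subset),
            "fraction": frac,
            "percent": pct[subset],
        }
        for subset, frac in sorted(partition.fractions.items())
    ]
    rows.append({"model": model_label, "subset": "TOTAL", "fraction": partition.total, "percent": 100.0})
    return pd.DataFrame(rows)


def write_selection_log(path, log: list) -> None:
    with open(path, "w") as fh:
        for entry in log:
            fh.write("\t".join(str(x) for x in entry) + "\n")


def write_truth_json(path, truth) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "true_coefficients": truth.true_coefficients,
                "field_params": truth.field_params,
                "target_prevalence": truth.target_prevalence,
                "seed": truth.seed,
            },
            indent=2,
        )
        + "\n"
    )
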