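"""End-to-end pipeline: records → bibliometrics → breakpoint → richness →
projection, bundled into one machine-readable report."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .curve import BreakpointFit, accumulation_curve, fit_breakpoint
from .errors import LinneangapError
from .projection import DEFAULT_R_GRID, ScenarioSuite, project_scenarios
from .records import SurveyDataset, read_records
from .richness import (
    RichnessBudget,
    RichnessEstimate,
    build_incidence,
    chao2,
    jackknife1,
    resampled_se,
    richness_budget,
)
from .summaries import (
    RatesSummary,
    authors_per_article_series,
    baseline_description_rate,
    frequency_table,
    rates_summary,
)

__all__ = ["ReportBundle", "StageError", "run_pipeline", "default_config",
           "validate_report", "load_config"]


class StageError(LinneangapError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict[str, Any]:
    return {
        "seed": 0,
        "estimator": "jack2",
        "n_randomizations": 1000,
        "r_grid": list(DEFAULT_R_GRID),
        "threshold_fraction": 0.995,
        "n0_mode": "window_only",
        "t0": None,
        "dialect": "csv",
    }


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Merge a YAML/JSON config file over the defaults."""
    cfg = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(loaded) - set(cfg)
        if unknown:
            raise LinneangapError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    return cfg


@dataclass(frozen=True)
class ReportBundle:
    """Consolidated pipeline outputs with full provenance."""

    rates: RatesSummary
    baseline_rate: float
    tables: Mapping[str, Mapping[str, tuple[int, float]]]
    authors_per_article: Mapping[int, float]
    breakpoint: BreakpointFit
    richness_estimates: tuple[RichnessEstimate, ...]
    budget: RichnessBudget
    scenarios: ScenarioSuite
    provenance: Mapping[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "rates": {
                "species_per_year": self.rates.species_per_year,
                "species_per_article": self.rates.species_per_article,
                "articles_per_author": self.rates.articles_per_author,
                "ranges": {k: list(v) for k, v in self.rates.ranges.items()},
            },
            "baseline_rate": self.baseline_rate,
            "tables": {
                f: {lab: [c, frac] for lab, (c, frac) in tab.items()}
                for f, tab in self.tables.items()
            },
            "authors_per_article": {
                str(y): v for y, v in self.authors_per_article.items()
            },
            "breakpoint": self.breakpoint.to_dict(),
            "richness_estimates": [asdict(e) for e in self.richness_estimates],
            "budget": asdict(self.budget),
            "scenarios": self.scenarios.to_dict(),
            "provenance": dict(self.provenance),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(name, exc) from exc


def run_pipeline(
    dataset: SurveyDataset | str | Path,
    config: Mapping[str, Any] | str | Path | None = None,
    out_path: str | Path | None = None,
) -> ReportBundle:
    """Run every analysis stage on a dataset (or records file) and return
    the consolidated report; optionally write it as JSON.

    Stages: summarize → accumulate → fit_breakpoint → build_incidence →
    estimate richness (Jackknife2 with a bootstrap SE, plus Jackknife1 and
    Chao2 companions) → richness_budget → project_scenarios.  Any stage
    failure is re-raised as a :class:`StageError` naming the stage.
    """
    cfg = (
        dict(config)
        if isinstance(config, Mapping)
        else load_config(config)
    )
    base = default_config()
    base.update(cfg)
    cfg = base

    if not isinstance(dataset, SurveyDataset):
        dataset = _stage("read_records", read_records, dataset, cfg["dialect"])

    rates = _stage("summarize", rates_summary, dataset)
    baseline = _stage(
        "summarize",
        baseline_description_rate,
        dataset.pre_window_species,
        dataset.pre_window_start,
        dataset.window_start,
    )
    tables = {
        f: _stage("summarize", frequency_table, dataset, f)
        for f in ("journal", "family", "country", "state", "ecoregion")
    }
    series = _stage("summarize", authors_per_article_series, dataset)
    curve = _stage("accumulate", accumulation_curve, dataset)
    bp = _stage("fit_breakpoint", fit_breakpoint, curve)
    matrix = _stage("build_incidence", build_incidence, dataset)
    main_est = _stage(
        "richness",
        resampled_se,
        matrix,
        cfg["estimator"],
        cfg["n_randomizations"],
        cfg["seed"],
    )
    companions = (
        _stage("richness", jackknife1, matrix),
        _stage("richness", chao2, matrix),
    )
    budget = _stage("richness_budget", richness_budget, main_est, dataset)
    suite = _stage(
        "project",
        project_scenarios,
        budget,
        curve,
        tuple(cfg["r_grid"]),
        cfg["threshold_fraction"],
        cfg["t0"],
        cfg["n0_mode"],
    )

    bundle = ReportBundle(
        rates=rates,
        baseline_rate=baseline,
        tables=tables,
        authors_per_article=series,
        breakpoint=bp,
        richness_estimates=(main_est, *companions),
        budget=budget,
        scenarios=suite,
        provenance={
            "package": "linneangap",
            "version": __version__,
            "config": {k: cfg[k] for k in sorted(cfg)},
            "n_records": dataset.n_species,
            "window": [dataset.window_start, dataset.window_end],
        },
    )
    if out_path is not None:
        Path(out_path).write_text(bundle.to_json() + "\n", encoding="utf-8")
    return bundle


# ---------------------------------------------------------------------------
# Structural report validation against the shipped schema description
# ---------------------------------------------------------------------------

_TYPES = {"object": dict, "array": list, "string": str, "integer": int,
          "number": (int, float), "boolean": bool}


def _check(node: Any, schema: Mapping[str, Any], path: str, problems: list[str]):
    expected = _TYPES[schema["type"]]
    if not isinstance(node, expected):
        problems.append(f"{path}: expected {schema['type']}")
        return
    if schema["type"] == "object":
        for key, sub in schema.get("properties", {}).items():
            if key in schema.get("required", list(schema.get("properties", {}))):
                if key not in node:
                    problems.append(f"{path}.{key}: missing")
                    continue
            if key in node:
                _check(node[key], sub, f"{path}.{key}", problems)
    elif schema["type"] == "array" and "items" in schema:
        for i, item in enumerate(node):
            _check(item, schema["items"], f"{path}[{i}]", problems)


def validate_report(report: Mapping[str, Any]) -> list[str]:
    """Check a report dict against the shipped structural schema; returns a
    list of problems (empty when valid)."""
    schema = json.loads(
        resources.files("linneangap")
        .joinpath("data/report_schema.json")
        .read_text(encoding="utf-8")
    )
    problems: list[str] = []
    _check(dict(report), schema, "$", problems)
    return problems
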