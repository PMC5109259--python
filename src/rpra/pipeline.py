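"""Study orchestration: configuration, execution, report emission.

A :class:`RunConfig` binds the input tables (exposure parameters, metal
properties, concentration summaries — bundled defaults when unset), the
Monte Carlo settings (seed, iterations) and the output directory.
:func:`run_study` executes every scenario, writes the summary tables
(per-scenario/per-route statistics, per-metal contribution shares,
sensitivity rankings, cumulative-probability curves, raw THQ samples) and a
JSON manifest recording the seed, iteration count and SHA-256 digests of
the input tables, so a rerun with the same manifest reproduces the outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import load_metal_properties
from .params import read_parameter_table
from .risk import bootstrap_p95_se, contribution_shares, cumulative_curve, summarize
from .scenarios import build_default_study, default_correlations, run_scenario
from .sensitivity import sensitivity_ranking
from .synthetic import load_concentration_summaries, summaries_for_stratum
from .params import fit_summary_to_spec

logger = logging.getLogger("rpra")

__all__ = ["RunConfig", "StudyResult", "run_study"]


@dataclass
class RunConfig:
    """Settings for one reproducible study run."""

    seed: int = 42
    n_iterations: int = 10_000
    parameter_table: str | None = None  # CSV path; bundled defaults if None
    metal_table: str | None = None
    summaries: str | None = None
    output_dir: str | None = None
    percentile: float = 95.0
    threshold: float = 1.0
    sensitivity_method: str = "spearman"
    top_k: int = 5
    bw_sa_correlation: float = 0.7
    puf_kd_correlation: float = -0.7
    bootstrap: int = 200

    def __post_init__(self) -> None:
        if self.n_iterations < 100:
            raise ValueError(f"n_iterations must be >= 100, got {self.n_iterations}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class StudyResult:
    """In-memory result bundle of a full study run."""

    config: RunConfig
    scenario_results: dict
    summary: pd.DataFrame  # per (scenario, route | THQ) statistics
    contributions: pd.DataFrame  # per (scenario, route, metal) shares
    sensitivity: pd.DataFrame  # per scenario ranked parameters
    manifest: dict

    def thq_p95(self) -> pd.Series:
        rows = self.summary[self.summary["route"] == "THQ"]
        return rows.set_index("scenario")["p95"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _resolve_input(path_str, default_loader, reader):
    if path_str is None:
        return default_loader(), None
    path = Path(path_str)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    return reader(path), path


def run_study(config: RunConfig) -> StudyResult:
    """Run every scenario of the study and assemble the report tables.

    With ``config.output_dir`` set, writes summary.csv, contributions.csv,
    sensitivity.csv, curves/<scenario>_thq_curve.csv,
    samples/<scenario>_samples.csv and manifest.json.
    """
    exposure_specs, param_path = _resolve_input(
        config.parameter_table,
        lambda: read_parameter_table(
            resources.files("rpra.data") / "exposure_parameters_default.csv"
        ),
        read_parameter_table,
    )
    props, metal_path = _resolve_input(
        config.metal_table, load_metal_properties, load_metal_properties
    )
    summaries, summary_path = _resolve_input(
        config.summaries, load_concentration_summaries, load_concentration_summaries
    )

    correlations = default_correlations(
        bw_sa=config.bw_sa_correlation, puf_kd=config.puf_kd_correlation
    )
    scenarios = build_default_study()

    scenario_results = {}
    summary_rows = []
    contribution_rows = []
    sensitivity_tables = []

    for scenario in scenarios:
        by_metal = summaries_for_stratum(summaries, scenario.conc_stratum)
        conc_specs = {
            metal: fit_summary_to_spec(summ, name=f"C_{metal}")
            for metal, summ in by_metal.items()
        }
        result = run_scenario(
            scenario,
            conc_specs,
            exposure_specs,
            props,
            n_iterations=config.n_iterations,
            seed=config.seed,
            correlations=correlations,
        )
        scenario_results[scenario.name] = result
        logger.info(
            "scenario %s: %d iterations, %d routes, THQ mean %.3g",
            scenario.name, config.n_iterations, len(result.hq), result.thq.mean(),
        )

        for route, totals in result.route_totals.items():
            stats = summarize(totals, threshold=config.threshold)
            summary_rows.append({"scenario": scenario.name, "route": route, **stats})
            shares = contribution_shares(result.hq[route])
            for metal, share in shares.items():
                contribution_rows.append(
                    {
                        "scenario": scenario.name,
                        "route": route,
                        "metal": metal,
                        "share_pct": share,
                    }
                )
        thq_stats = summarize(
            result.thq,
            threshold=config.threshold,
            bootstrap=config.bootstrap,
            seed=config.seed,
        )
        summary_rows.append({"scenario": scenario.name, "route": "THQ", **thq_stats})

        # point-family parameters are constant by declaration; drop them
        # rather than warn about undefined correlations
        varying = result.samples.data.loc[:, result.samples.data.nunique() > 1]
        table = sensitivity_ranking(
            varying,
            result.thq,
            top_k=config.top_k,
            method=config.sensitivity_method,
        )
        table.insert(0, "scenario", scenario.name)
        sensitivity_tables.append(table)

    summary = pd.DataFrame(summary_rows)
    contributions = pd.DataFrame(contribution_rows)
    sensitivity = pd.concat(sensitivity_tables, ignore_index=True)
    sensitivity.attrs["method"] = config.sensitivity_method

    manifest = {
        "package": "rpra",
        "version": __version__,
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "threshold": config.threshold,
        "sensitivity_method": config.sensitivity_method,
        "inputs": {
            "parameter_table": str(param_path) if param_path else "bundled defaults",
            "metal_table": str(metal_path) if metal_path else "bundled defaults",
            "summaries": str(summary_path) if summary_path else "bundled defaults",
        },
        "input_digests": {
            name: _sha256(p)
            for name, p in {
                "parameter_table": param_path,
                "metal_table": metal_path,
                "summaries": summary_path,
            }.items()
            if p is not None
        },
        "scenarios": [s.name for s in scenarios],
    }

    result_bundle = StudyResult(
        config, scenario_results, summary, contributions, sensitivity, manifest
    )
    if config.output_dir is not None:
        _write_outputs(result_bundle, Path(config.output_dir))
    return result_bundle


def _write_outputs(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out_dir / "summary.csv", index=False)
    result.contributions.to_csv(out_dir / "contributions.csv", index=False)
    result.sensitivity.to_csv(out_dir / "sensitivity.csv", index=False)

    curves_dir = out_dir / "curves"
    samples_dir = out_dir / "samples"
    curves_dir.mkdir(exist_ok=True)
    samples_dir.mkdir(exist_ok=True)
    for name, sr in result.scenario_results.items():
        cumulative_curve(sr.thq, n_points=500).to_csv(
            curves_dir / f"{name}_thq_curve.csv", index=False
        )
        frame = pd.DataFrame({"THQ": sr.thq})
        for route, totals in sr.route_totals.items():
            frame[f"HQ_{route}"] = totals
        frame.to_csv(samples_dir / f"{name}_samples.csv", index=False)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote study outputs to %s", out_dir)
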