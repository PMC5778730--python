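"""Whole-study orchestration: cohort -> three panels -> oracle comparison.

``reproduce_study`` runs the full pipeline from a :class:`StudyConfig` and
writes four artifacts: the cohort CSV, the results CSV (one row per grid
condition, the published-table layout), an oracle-comparison CSV holding
each condition's closed-form expected IDI and dCalibration together with
the standardized simulation-vs-oracle discrepancy, and a JSON run log
(seed, versions, counts of post-injection risks above 1).

The oracle comparison evaluates the closed forms at the *realized* cohort
summaries (sample group risk means, realized baseline calibration), not at
the nominal spec targets, so it isolates Monte-Carlo error of the carrier
draws from cohort sampling error.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec, generate_cohort, manitoba_like, write_cohort
from .metrics import auroc, calibration_ratio
from .oracles import OracleInputs
from .simulate import GridDefaults, paper_style_grids, run_grid

__all__ = ["StudyConfig", "StudyResult", "reproduce_study", "oracle_comparison"]

_ROUND = 3  # printed-table precision used by --paper-style output


class ConfigError(ValueError):
    """Invalid or unreadable study configuration."""


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one full study run."""

    cohort: CohortSpec = field(default_factory=manitoba_like)
    grids: dict[str, list[float]] = field(default_factory=paper_style_grids)
    defaults: GridDefaults = field(default_factory=GridDefaults)
    replicates: int = 200
    seed: int = 0
    output_dir: Path = Path("results")
    paper_style: bool = False
    cap: bool = False

    def validate(self) -> None:
        try:
            self.cohort.validate()
        except ValueError as exc:
            raise ConfigError(f"cohort: {exc}") from exc
        for name in ("rr", "prevalence", "threshold"):
            if name not in self.grids or len(self.grids[name]) == 0:
                raise ConfigError(f"grids.{name} is missing or empty")
        if not (self.defaults.rr >= 1.0 and 0.0 < self.defaults.prevalence <= 1.0
                and 0.0 < self.defaults.threshold < 1.0):
            raise ConfigError("defaults out of range")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "grids": {k: list(map(float, v)) for k, v in self.grids.items()},
            "defaults": dataclasses.asdict(self.defaults),
            "replicates": self.replicates,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "paper_style": self.paper_style,
            "cap": self.cap,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        try:
            kwargs: dict[str, Any] = {}
            if "cohort" in d:
                kwargs["cohort"] = CohortSpec(**d["cohort"])
            if "grids" in d:
                kwargs["grids"] = {k: list(v) for k, v in d["grids"].items()}
            if "defaults" in d:
                kwargs["defaults"] = GridDefaults(**d["defaults"])
            for key in ("replicates", "seed", "paper_style", "cap"):
                if key in d:
                    kwargs[key] = d[key]
            if "output_dir" in d:
                kwargs["output_dir"] = Path(d["output_dir"])
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(raw)


@dataclass
class StudyResult:
    cohort: Cohort
    results: pd.DataFrame
    oracle_comparison: pd.DataFrame
    log: dict[str, Any]
    paths: dict[str, Path]


def oracle_comparison(results: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Closed-form expected IDI/dCalibration per condition, evaluated at the
    cohort's realized summaries, with standardized discrepancies."""
    ev = cohort.events_mask
    inputs = OracleInputs(
        baseline_calibration=calibration_ratio(cohort.outcome, cohort.risk),
        mean_risk_events=float(cohort.risk[ev].mean()),
        mean_risk_nonevents=float(cohort.risk[~ev].mean()),
    )
    rows = []
    for _, row in results.iterrows():
        oracle = inputs.evaluate(row["rr"], row["prevalence"])
        rec = {
            "panel": row["panel"], "rr": row["rr"],
            "prevalence": row["prevalence"], "threshold": row["threshold"],
            **oracle,
        }
        for stat, key in (("idi", "expected_idi"),
                          ("delta_calibration", "expected_delta_calibration")):
            # SE floor guards the deterministic prevalence-1 condition,
            # where replicates are identical and the sample SD is float dust
            se = max(row[f"{stat}_se"], 1e-12)
            rec[f"{stat}_z"] = (row[stat] - oracle[key]) / se
        rows.append(rec)
    return pd.DataFrame.from_records(rows)


def reproduce_study(config: StudyConfig) -> StudyResult:
    """Run the full study and write its artifacts under config.output_dir.

    Any stage failure raises ``RuntimeError`` naming the stage, after
    removing partially written outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "results": out / "results.csv",
        "oracle_comparison": out / "oracle_comparison.csv",
        "log": out / "run_log.json",
    }

    written: list[Path] = []
    stage = "generate cohort"
    try:
        cohort = generate_cohort(config.cohort.with_seed(config.cohort.seed))
        write_cohort(cohort, paths["cohort"])
        written.append(paths["cohort"])

        stage = "run grid"
        results = run_grid(
            cohort,
            config.grids["rr"], config.grids["prevalence"],
            config.grids["threshold"],
            defaults=config.defaults, replicates=config.replicates,
            seed=config.seed, cap=config.cap,
        )
        out_results = results.round(_ROUND) if config.paper_style else results
        out_results.to_csv(paths["results"], index=False)
        written.append(paths["results"])

        stage = "oracle comparison"
        comparison = oracle_comparison(results, cohort)
        comparison.to_csv(paths["oracle_comparison"], index=False)
        written.append(paths["oracle_comparison"])

        stage = "run log"
        log = {
            "config": config.to_dict(),
            "versions": {
                "riskreclass": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "python": platform.python_version(),
            },
            "baseline_auroc": auroc(cohort.risk, cohort.outcome),
            "baseline_calibration": calibration_ratio(cohort.outcome, cohort.risk),
            "n_risks_gt1_max": float(results["n_risks_gt1"].max()),
            "n_risks_gt1_total": float(results["n_risks_gt1"].sum()),
        }
        paths["log"].write_text(json.dumps(log, indent=2))
        written.append(paths["log"])
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"study failed during stage '{stage}': {exc}") from exc

    return StudyResult(
        cohort=cohort, results=results, oracle_comparison=comparison,
        log=log, paths=paths,
    )
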