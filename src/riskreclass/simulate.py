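"""Injection of a simulated binary risk factor and the parameter-grid sweep.

The experiment: a carrier indicator X_i ~ Bernoulli(p), independent of the
baseline predictions and of the outcome, multiplies each carrier's
predicted risk by an assumed relative risk RR.  The "new model" is the
updated prediction; because X carries no outcome information, RR encodes
the model's *assumed* effect, not a real association.  For each
(RR, prevalence, threshold) condition the four change statistics — NRI,
IDI, dAUROC, dCalibration — are averaged over Monte-Carlo replicates of
the carrier draw, with Monte-Carlo standard errors.

New risks are NOT capped at 1 by default: the cap would break the rank
invariance that forces dAUROC = 0 at prevalence 1 and the closed-form
calibration shift.  Values exceeding 1 are counted and reported.

Seed policy: one master seed; each condition's replicate streams derive
deterministically from (panel, prevalence), so conditions that differ only
in RR or threshold share identical carrier draws.  This reproduces the
design property that IDI, dAUROC and dCalibration are constant across the
threshold panel within a replicate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort
from .metrics import RiskCategorySchema, calibration_ratio, categorize, idi, nri

__all__ = [
    "SimulationCondition",
    "MetricDelta",
    "GridDefaults",
    "draw_risk_factor",
    "apply_risk_factor",
    "run_condition",
    "run_grid",
    "paper_style_grids",
]

DELTA_COLUMNS = [
    "nri", "idi", "delta_auroc", "delta_calibration",
    "nri_se", "idi_se", "delta_auroc_se", "delta_calibration_se",
    "n_risks_gt1",
]


@dataclass(frozen=True)
class SimulationCondition:
    """One (RR, prevalence, threshold) point of the grid."""

    rr: float
    prevalence: float
    threshold: float
    replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rr < 1.0:
            raise ValueError("rr must be >= 1")
        if not 0.0 < self.prevalence <= 1.0:
            raise ValueError("prevalence must be in (0, 1]")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class MetricDelta:
    """Across-replicate means and Monte-Carlo SEs of the change statistics.

    Deltas are (new model - original model); NRI and IDI are change
    statistics by construction.  ``n_risks_gt1`` is the mean per-replicate
    count of post-injection risks above 1 (reported, never silently
    clamped).
    """

    condition: SimulationCondition
    nri: float
    idi: float
    delta_auroc: float
    delta_calibration: float
    nri_se: float
    idi_se: float
    delta_auroc_se: float
    delta_calibration_se: float
    n_risks_gt1: float

    def as_dict(self) -> dict[str, float]:
        d = {
            "rr": self.condition.rr,
            "prevalence": self.condition.prevalence,
            "threshold": self.condition.threshold,
        }
        for name in DELTA_COLUMNS:
            d[name] = getattr(self, name)
        return d


def draw_risk_factor(
    n: int, prevalence: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Independent Bernoulli(prevalence) carrier indicators.

    Prevalence 0 and 1 are deterministic (no draws consumed differ in
    outcome); otherwise one uniform per subject.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if prevalence == 0.0:
        return np.zeros(n, dtype=np.int64)
    if prevalence == 1.0:
        return np.ones(n, dtype=np.int64)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return (rng.random(n) < prevalence).astype(np.int64)


def apply_risk_factor(
    risks, carriers, rr: float, cap: bool = False
) -> np.ndarray:
    """Multiply carriers' predicted risks by RR.

    ``cap=True`` clamps the result to 1; off by default (see module notes).
    """
    r = np.asarray(risks, dtype=float)
    x = np.asarray(carriers)
    if r.shape != x.shape:
        raise ValueError("risks and carriers must have equal length")
    if rr < 1.0:
        raise ValueError("rr must be >= 1")
    new = np.where(x == 1, r * rr, r)
    if cap:
        new = np.minimum(new, 1.0)
    return new


def _auroc_from_ranks(ranks: np.ndarray, events: np.ndarray) -> float:
    n_e = int(events.sum())
    n_ne = len(ranks) - n_e
    return float((ranks[events].sum() - n_e * (n_e + 1) / 2.0) / (n_e * n_ne))


def run_condition(
    cohort: Cohort,
    condition: SimulationCondition,
    cap: bool = False,
) -> MetricDelta:
    """Monte-Carlo estimate of the four change statistics at one condition.

    Replicate r uses a child seed derived deterministically from
    (condition.seed, r), so any single replicate is reproducible in
    isolation and ``replicates=1`` (single-draw, paper-style output) is the
    first replicate of the full run.
    """
    risks = cohort.risk
    events = cohort.events_mask
    schema = RiskCategorySchema.from_threshold(condition.threshold)
    auroc_old = _auroc_from_ranks(rankdata(risks), events)
    cal_old = calibration_ratio(cohort.outcome, risks)

    children = np.random.SeedSequence(condition.seed).spawn(condition.replicates)
    rows = np.empty((condition.replicates, 5))
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        carriers = draw_risk_factor(len(cohort), condition.prevalence, rng)
        new = apply_risk_factor(risks, carriers, condition.rr, cap=cap)
        res = nri(risks, new, cohort.outcome, schema)
        rows[r, 0] = res.nri
        rows[r, 1] = idi(risks, new, cohort.outcome)
        rows[r, 2] = _auroc_from_ranks(rankdata(new), events) - auroc_old
        rows[r, 3] = calibration_ratio(cohort.outcome, new) - cal_old
        rows[r, 4] = int((new > 1.0).sum())

    means = rows.mean(axis=0)
    if condition.replicates > 1:
        ses = rows[:, :4].std(axis=0, ddof=1) / np.sqrt(condition.replicates)
    else:
        ses = np.zeros(4)
    return MetricDelta(
        condition=condition,
        nri=means[0], idi=means[1],
        delta_auroc=means[2], delta_calibration=means[3],
        nri_se=float(ses[0]), idi_se=float(ses[1]),
        delta_auroc_se=float(ses[2]), delta_calibration_se=float(ses[3]),
        n_risks_gt1=float(means[4]),
    )


@dataclass(frozen=True)
class GridDefaults:
    """Held-constant values while one parameter varies."""

    rr: float = 2.0
    prevalence: float = 1.0 / 3.0
    threshold: float = 0.20


def paper_style_grids() -> dict[str, list[float]]:
    """The published grids: RR 1.25–3.50 by 0.25, prevalence 10–100% by
    10%, intervention threshold 5–50% by 5%."""
    return {
        "rr": [1.25 + 0.25 * i for i in range(10)],
        "prevalence": [0.1 * (i + 1) for i in range(10)],
        "threshold": [0.05 * (i + 1) for i in range(10)],
    }


_PANELS = ("rr", "prevalence", "threshold")


def _condition_seed(master_seed: int, panel: str, prevalence: float) -> int:
    """Replicate streams depend only on (panel, prevalence): the carrier
    draw is the sole source of randomness and depends only on prevalence."""
    key = (_PANELS.index(panel), int(round(prevalence * 1_000_000)))
    ss = np.random.SeedSequence(master_seed, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_grid(
    cohort: Cohort,
    rr_grid: Sequence[float],
    prevalence_grid: Sequence[float],
    threshold_grid: Sequence[float],
    defaults: GridDefaults = GridDefaults(),
    replicates: int = 200,
    seed: int = 0,
    cap: bool = False,
) -> pd.DataFrame:
    """Sweep the three one-at-a-time panels and return one row per condition.

    Panel "rr" varies RR with (prevalence, threshold) held at the defaults,
    and similarly for the other two panels — the layout of the published
    results table.
    """
    for name, grid in (("rr", rr_grid), ("prevalence", prevalence_grid),
                       ("threshold", threshold_grid)):
        if len(grid) == 0:
            raise ValueError(f"{name} grid is empty")
    records = []
    panels = {
        "rr": [(v, defaults.prevalence, defaults.threshold) for v in rr_grid],
        "prevalence": [(defaults.rr, v, defaults.threshold) for v in prevalence_grid],
        "threshold": [(defaults.rr, defaults.prevalence, v) for v in threshold_grid],
    }
    for panel, conditions in panels.items():
        for rr, prev, thr in conditions:
            cond = SimulationCondition(
                rr=rr, prevalence=prev, threshold=thr, replicates=replicates,
                seed=_condition_seed(seed, panel, prev),
            )
            delta = run_condition(cohort, cond, cap=cap)
            records.append({"panel": panel, **delta.as_dict()})
    return pd.DataFrame.from_records(records)
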