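"""Discrimination, calibration and reclassification statistics.

The four performance measures used throughout the package:

* ``auroc`` — area under the ROC curve, computed as the Mann–Whitney
  concordance statistic (tied pairs credited 0.5).
* ``calibration_ratio`` — observed event fraction divided by mean predicted
  risk; 1.0 is perfect calibration-in-the-large.
* ``nri`` — net reclassification improvement over an ordinal category
  schema (the intervention threshold is the single-cutpoint case).
* ``idi`` — integrated discrimination improvement, the change in
  discrimination slope (mean risk among events minus mean risk among
  non-events).

All functions accept array-likes of per-subject predicted risks and binary
outcomes and validate that both outcome classes are present where the
statistic requires it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RiskCategorySchema",
    "ReclassificationTable",
    "NriResult",
    "ModelComparison",
    "auroc",
    "calibration_ratio",
    "categorize",
    "reclassification_table",
    "nri",
    "idi",
    "compare_models",
]


def _as_arrays(risks, outcomes) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(risks, dtype=float)
    o = np.asarray(outcomes)
    if r.shape != o.shape:
        raise ValueError(f"length mismatch: {r.shape} risks vs {o.shape} outcomes")
    if not np.isin(o, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    return r, o.astype(bool)


def _require_both_classes(events: np.ndarray) -> None:
    if events.all() or not events.any():
        raise ValueError("statistic requires at least one event and one non-event")


def auroc(risks, outcomes) -> float:
    """Mann–Whitney AUROC: P(risk_event > risk_nonevent) + 0.5 P(tie).

    Equivalent to the normalized rank-sum of the events' risks; midranks
    give tied pairs 0.5 credit.
    """
    r, ev = _as_arrays(risks, outcomes)
    _require_both_classes(ev)
    n_e = int(ev.sum())
    n_ne = len(r) - n_e
    ranks = rankdata(r)
    return float((ranks[ev].sum() - n_e * (n_e + 1) / 2.0) / (n_e * n_ne))


def calibration_ratio(outcomes, risks) -> float:
    """Observed event fraction divided by mean predicted risk.

    In a synthetic cohort with fully observed binary outcomes the "observed
    incidence" is the crude event fraction (no censoring exists to
    distinguish it from a cumulative incidence).
    """
    r, ev = _as_arrays(risks, outcomes)
    mean_risk = r.mean()
    if mean_risk <= 0.0:
        raise ValueError("mean predicted risk is zero; calibration undefined")
    return float(ev.mean() / mean_risk)


@dataclass(frozen=True)
class RiskCategorySchema:
    """Ordered risk-category cutpoints; a risk at a cutpoint is in the
    upper category (half-open [low, high) bins)."""

    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutpoints)
        if len(cuts) == 0:
            raise ValueError("need at least one cutpoint")
        if any(not 0.0 < c < 1.0 for c in cuts):
            raise ValueError("cutpoints must lie in (0,1)")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        object.__setattr__(self, "cutpoints", cuts)

    @classmethod
    def from_threshold(cls, threshold: float) -> "RiskCategorySchema":
        """Two categories split at a single intervention threshold."""
        return cls((threshold,))

    @property
    def n_categories(self) -> int:
        return len(self.cutpoints) + 1


def categorize(risks, schema: RiskCategorySchema) -> np.ndarray:
    """Ordinal category index (0-based) of each risk under the schema."""
    r = np.asarray(risks, dtype=float)
    return np.searchsorted(np.asarray(schema.cutpoints), r, side="right")


@dataclass(frozen=True)
class ReclassificationTable:
    """Old-category x new-category counts, one matrix per outcome stratum."""

    events: np.ndarray
    nonevents: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_nonevents(self) -> int:
        return int(self.nonevents.sum())


def reclassification_table(
    old_risks, new_risks, outcomes, schema: RiskCategorySchema
) -> ReclassificationTable:
    old, ev = _as_arrays(old_risks, outcomes)
    new, _ = _as_arrays(new_risks, outcomes)
    if old.shape != new.shape:
        raise ValueError("old and new risks must have equal length")
    k = schema.n_categories
    c_old = categorize(old, schema)
    c_new = categorize(new, schema)
    tables = []
    for stratum in (ev, ~ev):
        flat = np.bincount(c_old[stratum] * k + c_new[stratum], minlength=k * k)
        tables.append(flat.reshape(k, k))
    return ReclassificationTable(events=tables[0], nonevents=tables[1])


@dataclass(frozen=True)
class NriResult:
    """Stratified NRI with its four movement probabilities.

    ``nri`` is the conventional two-part estimator
    [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)],
    bounded in [-2, 2].  ``unstratified`` divides the summed per-subject
    scores by the whole cohort size instead (bounded in [-1, 1]); both are
    reported because published verbal definitions are sometimes ambiguous
    between the two.
    """

    nri: float
    p_up_event: float
    p_down_event: float
    p_up_nonevent: float
    p_down_nonevent: float
    unstratified: float


def nri(old_risks, new_risks, outcomes, schema: RiskCategorySchema) -> NriResult:
    """Net reclassification improvement over the category schema.

    Events score +1 for moving to a higher category and -1 for lower;
    non-events score the opposite; no move scores 0.
    """
    old, ev = _as_arrays(old_risks, outcomes)
    new, _ = _as_arrays(new_risks, outcomes)
    if old.shape != new.shape:
        raise ValueError("old and new risks must have equal length")
    _require_both_classes(ev)
    c_old = categorize(old, schema)
    c_new = categorize(new, schema)
    up = c_new > c_old
    down = c_new < c_old
    n_e = ev.sum()
    n_ne = (~ev).sum()
    p_up_e = float(up[ev].sum() / n_e)
    p_down_e = float(down[ev].sum() / n_e)
    p_up_ne = float(up[~ev].sum() / n_ne)
    p_down_ne = float(down[~ev].sum() / n_ne)
    scores = np.where(ev, up.astype(int) - down.astype(int),
                      down.astype(int) - up.astype(int))
    return NriResult(
        nri=(p_up_e - p_down_e) + (p_down_ne - p_up_ne),
        p_up_event=p_up_e,
        p_down_event=p_down_e,
        p_up_nonevent=p_up_ne,
        p_down_nonevent=p_down_ne,
        unstratified=float(scores.sum() / len(scores)),
    )


def idi(old_risks, new_risks, outcomes) -> float:
    """Integrated discrimination improvement: change in discrimination slope."""
    old, ev = _as_arrays(old_risks, outcomes)
    new, _ = _as_arrays(new_risks, outcomes)
    if old.shape != new.shape:
        raise ValueError("old and new risks must have equal length")
    _require_both_classes(ev)
    slope_new = new[ev].mean() - new[~ev].mean()
    slope_old = old[ev].mean() - old[~ev].mean()
    return float(slope_new - slope_old)


@dataclass(frozen=True)
class ModelComparison:
    """All four statistics for an old-vs-new model comparison."""

    auroc_old: float
    auroc_new: float
    calibration_old: float
    calibration_new: float
    nri: NriResult
    idi: float

    @property
    def delta_auroc(self) -> float:
        return self.auroc_new - self.auroc_old

    @property
    def delta_calibration(self) -> float:
        return self.calibration_new - self.calibration_old


def compare_models(
    old_risks, new_risks, outcomes, schema: RiskCategorySchema
) -> ModelComparison:
    """Compute AUROC and calibration for both models plus NRI and IDI."""
    return ModelComparison(
        auroc_old=auroc(old_risks, outcomes),
        auroc_new=auroc(new_risks, outcomes),
        calibration_old=calibration_ratio(outcomes, old_risks),
        calibration_new=calibration_ratio(outcomes, new_risks),
        nri=nri(old_risks, new_risks, outcomes, schema),
        idi=idi(old_risks, new_risks, outcomes),
    )
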