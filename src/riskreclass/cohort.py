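"""Synthetic fracture-risk cohorts.

A cohort is the substrate for every statistic in this package: one baseline
10-year predicted fracture-risk probability per subject plus a binary
major-osteoporotic-fracture (MOF) outcome.  Real registry data of this kind
(e.g. a provincial bone-density registry scored with FRAX) cannot be
redistributed, so cohorts are generated to match the published summary
structure: cohort size, event fraction, group-conditional risk moments
(mean +/- SD of predicted risk among events and non-events), and the
baseline observed/expected calibration ratio.

Two generation modes are offered.  ``outcome_first`` draws outcomes first
and then risks from a moment-matched bounded distribution within each
outcome group, so the group moments are matched directly.  ``risk_first``
draws risks from the outcome-weighted mixture of the two group
distributions and then outcomes as Bernoulli(C0 * risk), so the expected
calibration ratio equals the target C0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize

__all__ = [
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "event_rate_for_calibration",
    "manitoba_like",
]

RiskFamily = Literal["logitnormal", "beta"]


class InfeasibleMomentsError(ValueError):
    """Requested (mean, sd) cannot come from a distribution bounded in (0,1)."""


def _check_group_feasible(mean: float, sd: float, group: str) -> None:
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"{group}: mean risk {mean} not in (0,1)")
    if sd <= 0.0:
        raise InfeasibleMomentsError(f"{group}: sd {sd} must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"{group}: sd^2 = {sd * sd:.6g} >= mean*(1-mean) = "
            f"{mean * (1.0 - mean):.6g}; no bounded (0,1) distribution has "
            "these moments"
        )


@dataclass(frozen=True)
class CohortSpec:
    """Target summary structure of a synthetic cohort.

    Parameters
    ----------
    n_subjects
        Cohort size.
    event_rate
        Marginal probability of the binary outcome (``outcome_first`` mode)
        or mixture weight of the event component (``risk_first`` mode).
    mean_risk_events, sd_risk_events
        Moments of baseline predicted risk among subjects with the outcome.
    mean_risk_nonevents, sd_risk_nonevents
        Moments among subjects without the outcome.
    target_calibration
        Baseline observed/expected ratio C0 targeted by ``risk_first`` mode.
    mode
        ``outcome_first`` (default) or ``risk_first``.
    family
        Group-conditional risk distribution family, moment-matched per
        group: ``logitnormal`` (default) or ``beta``.
    exact_event_count
        ``outcome_first`` only: fix the number of events to
        round(n * event_rate) instead of Bernoulli draws.
    match_moments
        ``outcome_first`` only: affinely standardize each group's risks so
        sample mean and SD equal the targets exactly.
    seed
        Seed for the generator; identical spec -> identical cohort.
    """

    n_subjects: int = 31_999
    event_rate: float = 0.0994
    mean_risk_events: float = 0.163
    sd_risk_events: float = 0.096
    mean_risk_nonevents: float = 0.105
    sd_risk_nonevents: float = 0.068
    target_calibration: float = 0.990
    mode: Literal["outcome_first", "risk_first"] = "outcome_first"
    family: RiskFamily = "logitnormal"
    exact_event_count: bool = False
    match_moments: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0.0 < self.event_rate < 1.0:
            raise ValueError("event_rate must be in (0,1)")
        if self.target_calibration <= 0.0:
            raise ValueError("target_calibration must be positive")
        if self.mode not in ("outcome_first", "risk_first"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.family not in ("logitnormal", "beta"):
            raise ValueError(f"unknown family {self.family!r}")
        _check_group_feasible(self.mean_risk_events, self.sd_risk_events, "events")
        _check_group_feasible(
            self.mean_risk_nonevents, self.sd_risk_nonevents, "non-events"
        )

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


@dataclass
class Cohort:
    """Per-subject baseline predicted risk and binary outcome."""

    subject_id: np.ndarray
    risk: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.risk = np.asarray(self.risk, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=np.int64)
        if not (self.subject_id.shape == self.risk.shape == self.outcome.shape):
            raise ValueError("subject_id, risk and outcome must share one length")
        if np.any((self.risk < 0.0) | (self.risk > 1.0)) or np.any(
            ~np.isfinite(self.risk)
        ):
            bad = int(np.flatnonzero((self.risk < 0) | (self.risk > 1))[0])
            raise ValueError(f"risk outside [0,1] at position {bad}")
        if not np.isin(self.outcome, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(self.outcome, (0, 1)))[0])
            raise ValueError(f"non-binary outcome at position {bad}")
        if self.outcome.sum() == 0 or self.outcome.sum() == len(self.outcome):
            raise ValueError("cohort needs at least one event and one non-event")

    def __len__(self) -> int:
        return len(self.risk)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    @property
    def events_mask(self) -> np.ndarray:
        return self.outcome == 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_id, "risk": self.risk, "outcome": self.outcome}
        )


# ---------------------------------------------------------------------------
# moment-matched families on (0, 1)


def _beta_params(mean: float, sd: float, group: str) -> tuple[float, float]:
    _check_group_feasible(mean, sd, group)
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def _logitnormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    # Gauss-Hermite quadrature of sigmoid(mu + sigma Z), Z ~ N(0,1)
    nodes, weights = hermegauss(80)
    p = 1.0 / (1.0 + np.exp(-(mu + sigma * nodes)))
    w = weights / weights.sum()
    m = float(np.dot(w, p))
    v = float(np.dot(w, p * p)) - m * m
    return m, float(np.sqrt(max(v, 0.0)))


@lru_cache(maxsize=64)
def _logitnormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the logit-normal with the given mean and SD."""

    def residual(theta: np.ndarray) -> list[float]:
        m, s = _logitnormal_moments(theta[0], float(np.exp(theta[1])))
        return [m - mean, s - sd]

    x0 = [np.log(mean / (1.0 - mean)), np.log(sd / (mean * (1.0 - mean)))]
    sol, info, ier, msg = optimize.fsolve(residual, x0, full_output=True)
    if ier != 1:  # pragma: no cover - fsolve converges for all feasible moments
        raise RuntimeError(f"logit-normal moment match failed: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def _draw_group(
    rng: np.random.Generator, n: int, mean: float, sd: float, family: str, group: str
) -> np.ndarray:
    _check_group_feasible(mean, sd, group)
    if n == 0:
        return np.empty(0)
    if family == "beta":
        a, b = _beta_params(mean, sd, group)
        return rng.beta(a, b, size=n)
    mu, sigma = _logitnormal_params(mean, sd)
    z = rng.standard_normal(n)
    return 1.0 / (1.0 + np.exp(-(mu + sigma * z)))


def _standardize(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affine map to exact sample moments; keeps values inside (0,1)."""
    if len(x) < 2:
        return x
    y = mean + (x - x.mean()) * (sd / x.std())
    return np.clip(y, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------


def event_rate_for_calibration(
    c0: float, mean_risk_events: float, mean_risk_nonevents: float
) -> float:
    """Event fraction e solving e / (e*m_e + (1-e)*m_ne) = c0.

    With group-conditional risk means fixed, the crude calibration ratio of
    an ``outcome_first`` cohort is a function of the event fraction alone;
    this inverts it so a cohort can be pinned at a target baseline ratio.
    """
    denom = 1.0 - c0 * (mean_risk_events - mean_risk_nonevents)
    e = c0 * mean_risk_nonevents / denom
    if not 0.0 < e < 1.0:
        raise ValueError(
            f"calibration target {c0} infeasible for the given group means"
        )
    return e


def manitoba_like(seed: int = 0, family: RiskFamily = "logitnormal") -> CohortSpec:
    """Spec of the default study cohort emulating the published registry.

    n = 31,999 women; group risk moments 16.3 +/- 9.6% (events) and
    10.5 +/- 6.8% (non-events).  Outcomes are drawn at the 10-year
    cumulative-incidence scale implied by the published calibration ratio
    0.990 (event fraction 11.03%), not at the crude censored fraction 9.9%,
    because the synthetic world has no censoring and the calibration ratio
    is the quantity the downstream analyses consume.  Exact event count and
    exact group sample moments pin the realized baseline calibration at
    0.990 so expected-value checks are sharp.
    """
    spec = CohortSpec(
        family=family,
        exact_event_count=True,
        match_moments=True,
        seed=seed,
    )
    return replace(
        spec,
        event_rate=event_rate_for_calibration(
            spec.target_calibration,
            spec.mean_risk_events,
            spec.mean_risk_nonevents,
        ),
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort from a :class:`CohortSpec`.

    Deterministic in the spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    if spec.mode == "outcome_first":
        if spec.exact_event_count:
            n_events = int(round(n * spec.event_rate))
            n_events = min(max(n_events, 1), n - 1)
            outcome = np.zeros(n, dtype=np.int64)
            outcome[rng.permutation(n)[:n_events]] = 1
        else:
            outcome = (rng.random(n) < spec.event_rate).astype(np.int64)
            # metrics are undefined for single-class cohorts; nudge the two
            # all-but-impossible corner draws
            if outcome.sum() == 0:
                outcome[rng.integers(n)] = 1
            elif outcome.sum() == n:
                outcome[rng.integers(n)] = 0
        risk = np.empty(n)
        ev = outcome == 1
        risk[ev] = _draw_group(
            rng, int(ev.sum()), spec.mean_risk_events, spec.sd_risk_events,
            spec.family, "events",
        )
        risk[~ev] = _draw_group(
            rng, int((~ev).sum()), spec.mean_risk_nonevents,
            spec.sd_risk_nonevents, spec.family, "non-events",
        )
        if spec.match_moments:
            risk[ev] = _standardize(
                risk[ev], spec.mean_risk_events, spec.sd_risk_events
            )
            risk[~ev] = _standardize(
                risk[~ev], spec.mean_risk_nonevents, spec.sd_risk_nonevents
            )
    else:  # risk_first
        from_events = rng.random(n) < spec.event_rate
        risk = np.empty(n)
        risk[from_events] = _draw_group(
            rng, int(from_events.sum()), spec.mean_risk_events,
            spec.sd_risk_events, spec.family, "events",
        )
        risk[~from_events] = _draw_group(
            rng, int((~from_events).sum()), spec.mean_risk_nonevents,
            spec.sd_risk_nonevents, spec.family, "non-events",
        )
        p_event = np.minimum(1.0, spec.target_calibration * risk)
        outcome = (rng.random(n) < p_event).astype(np.int64)
        if outcome.sum() == 0:
            outcome[int(np.argmax(risk))] = 1
        elif outcome.sum() == n:
            outcome[int(np.argmin(risk))] = 0

    return Cohort(subject_id=np.arange(1, n + 1), risk=risk, outcome=outcome)


# ---------------------------------------------------------------------------
# CSV round trip

_COLUMNS = ["subject_id", "risk", "outcome"]


def write_cohort(cohort: Cohort, destination: str | Path) -> None:
    """Write ``subject_id,risk,outcome`` CSV at full float precision."""
    cohort.to_frame().to_csv(destination, index=False, float_format="%.17g")


def read_cohort(source: str | Path) -> Cohort:
    """Read a cohort CSV, validating every row.

    Errors name the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(source)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError("empty cohort: CSV has a header but no rows")
    risk = pd.to_numeric(df["risk"], errors="coerce").to_numpy(dtype=float)
    outcome = pd.to_numeric(df["outcome"], errors="coerce").to_numpy(dtype=float)
    bad_risk = np.flatnonzero(~np.isfinite(risk) | (risk < 0.0) | (risk > 1.0))
    if bad_risk.size:
        raise ValueError(f"risk outside [0,1] or non-numeric at row {bad_risk[0] + 1}")
    bad_out = np.flatnonzero(~np.isin(outcome, (0.0, 1.0)))
    if bad_out.size:
        raise ValueError(f"non-binary outcome at row {bad_out[0] + 1}")
    return Cohort(
        subject_id=df["subject_id"].to_numpy(),
        risk=risk,
        outcome=outcome.astype(np.int64),
    )
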