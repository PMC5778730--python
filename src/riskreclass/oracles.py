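"""Closed-form expected values under the noise-factor model.

The injected factor is a Bernoulli(p) carrier indicator, independent of
both the baseline predicted risk and the outcome, that multiplies a
carrier's predicted risk by RR.  Because the factor carries no outcome
information, the expected effect of the injection on IDI and on the
calibration ratio follows in closed form from first-order expectations
(the realized carrier fraction replaced by p):

* mean new risk = (1 + p (RR - 1)) * mean old risk, so the calibration
  ratio shrinks by that factor:  E[dCal] = C0 / (1 + p (RR - 1)) - C0;
* the discrimination slope grows by p (RR - 1) times the old slope:
  E[IDI] = p (RR - 1) (m_e - m_ne);
* at p = 1 every prediction is multiplied by the same positive constant,
  ranks are unchanged, and dAUROC = 0 exactly.

No closed form is attempted for the NRI or for dAUROC at p < 1: both
depend on the full shape of the baseline risk distribution and are checked
by simulation and brute force instead.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OracleInputs",
    "expected_delta_calibration",
    "expected_idi",
    "expected_delta_auroc_full_prevalence",
]


def _validate(rr: float, prevalence: float) -> None:
    if rr < 1.0:
        raise ValueError("rr must be >= 1")
    if not 0.0 < prevalence <= 1.0:
        raise ValueError("prevalence must be in (0, 1]")


def expected_delta_calibration(c0: float, rr: float, prevalence: float) -> float:
    """Expected change in the observed/expected ratio after injection."""
    if c0 <= 0.0:
        raise ValueError("baseline calibration must be positive")
    _validate(rr, prevalence)
    return c0 / (1.0 + prevalence * (rr - 1.0)) - c0


def expected_idi(
    mean_risk_events: float,
    mean_risk_nonevents: float,
    rr: float,
    prevalence: float,
) -> float:
    """Expected integrated discrimination improvement after injection."""
    _validate(rr, prevalence)
    return prevalence * (rr - 1.0) * (mean_risk_events - mean_risk_nonevents)


def expected_delta_auroc_full_prevalence() -> float:
    """dAUROC at prevalence 1: exactly 0 (ranks invariant under a common
    positive multiplier; holds for every cohort and RR when risks are not
    capped at 1)."""
    return 0.0


@dataclass(frozen=True)
class OracleInputs:
    """Inputs of the closed forms, bundled for grid-wide evaluation."""

    baseline_calibration: float
    mean_risk_events: float
    mean_risk_nonevents: float

    def evaluate(self, rr: float, prevalence: float) -> dict[str, float]:
        return {
            "expected_idi": expected_idi(
                self.mean_risk_events, self.mean_risk_nonevents, rr, prevalence
            ),
            "expected_delta_calibration": expected_delta_calibration(
                self.baseline_calibration, rr, prevalence
            ),
        }
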