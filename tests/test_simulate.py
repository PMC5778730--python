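"""Tests of the risk-factor injection and grid sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskreclass import (
    CohortSpec,
    GridDefaults,
    RiskCategorySchema,
    SimulationCondition,
    apply_risk_factor,
    auroc,
    calibration_ratio,
    draw_risk_factor,
    expected_delta_calibration,
    expected_idi,
    generate_cohort,
    idi,
    nri,
    paper_style_grids,
    run_condition,
    run_grid,
)

from conftest import random_small_cohort


def small_study_cohort(seed=0, n=6000):
    """Down-scaled analogue of the study cohort with pinned moments."""
    spec = CohortSpec(
        n_subjects=n,
        event_rate=0.110282,
        exact_event_count=True,
        match_moments=True,
        seed=seed,
    )
    return generate_cohort(spec)


class TestDrawRiskFactor:
    def test_extremes_are_deterministic(self):
        rng = np.random.default_rng(0)
        assert draw_risk_factor(5, 0.0, rng).tolist() == [0] * 5
        assert draw_risk_factor(5, 1.0, rng).tolist() == [1] * 5

    def test_carrier_fraction(self):
        x = draw_risk_factor(10_000, 0.5, np.random.default_rng(1))
        assert abs(x.mean() - 0.5) < 0.015  # 3 binomial SEs

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            draw_risk_factor(5, 1.5, np.random.default_rng(0))


class TestApplyRiskFactor:
    def test_rr_one_is_identity(self):
        risks = np.array([0.1, 0.5, 0.9])
        out = apply_risk_factor(risks, np.array([1, 1, 0]), 1.0)
        assert np.array_equal(out, risks)

    def test_carriers_scaled(self):
        out = apply_risk_factor(np.array([0.1, 0.3]), np.array([1, 0]), 2.0)
        assert out.tolist() == [0.2, 0.3]

    def test_no_cap_by_default_and_cap_option(self):
        risks = np.array([0.6, 0.6])
        carriers = np.array([1, 0])
        assert apply_risk_factor(risks, carriers, 2.0)[0] == pytest.approx(1.2)
        assert apply_risk_factor(risks, carriers, 2.0, cap=True)[0] == 1.0

    def test_full_prevalence_preserves_auroc(self, toy_cohort):
        """A common positive multiplier cannot change ranks."""
        for rr in (1.5, 2.0, 3.5):
            new = apply_risk_factor(
                toy_cohort.risk, np.ones(len(toy_cohort), dtype=int), rr
            )
            assert auroc(new, toy_cohort.outcome) == auroc(
                toy_cohort.risk, toy_cohort.outcome
            )


class TestExactIdentities:
    """Realized (not just expected) values obey closed-form identities."""

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idi_identity(self, seed):
        rng = np.random.default_rng(seed)
        c = random_small_cohort(rng, n_max=20)
        rr = 1.0 + 2.5 * rng.random()
        x = draw_risk_factor(len(c), 0.5, rng)
        new = apply_risk_factor(c.risk, x, rr)
        ev = c.events_mask
        identity = (rr - 1.0) * (
            (x * c.risk)[ev].mean() - (x * c.risk)[~ev].mean()
        )
        assert idi(c.risk, new, c.outcome) == pytest.approx(identity)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_delta_calibration_identity(self, seed):
        rng = np.random.default_rng(seed)
        c = random_small_cohort(rng, n_max=20)
        x = draw_risk_factor(len(c), 0.4, rng)
        new = apply_risk_factor(c.risk, x, 2.5)
        c_old = calibration_ratio(c.outcome, c.risk)
        expected = c_old * (c.risk.mean() / new.mean()) - c_old
        observed = calibration_ratio(c.outcome, new) - c_old
        assert observed == pytest.approx(expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nri_reduces_to_boundary_band_identity(self, seed):
        """With RR > 1 nobody moves down; movers are carriers whose old
        risk lies in [t/RR, t)."""
        rng = np.random.default_rng(seed)
        c = random_small_cohort(rng, n_max=20)
        rr, t = 2.0, 0.20
        x = draw_risk_factor(len(c), 0.5, rng)
        new = apply_risk_factor(c.risk, x, rr)
        schema = RiskCategorySchema.from_threshold(t)
        res = nri(c.risk, new, c.outcome, schema)
        assert res.p_down_event == 0.0
        assert res.p_down_nonevent == 0.0
        band = (x == 1) & (c.risk >= t / rr) & (c.risk < t)
        ev = c.events_mask
        assert res.nri == pytest.approx(band[ev].mean() - band[~ev].mean())


class TestRunCondition:
    def test_null_injection_is_exactly_zero(self, toy_cohort):
        cond = SimulationCondition(rr=1.0, prevalence=0.5, threshold=0.2,
                                   replicates=5, seed=0)
        d = run_condition(toy_cohort, cond)
        for name in ("nri", "idi", "delta_auroc", "delta_calibration"):
            assert getattr(d, name) == 0.0
            assert getattr(d, f"{name}_se") == 0.0
        assert d.n_risks_gt1 == 0.0

    def test_full_prevalence_delta_auroc_exactly_zero(self):
        c = small_study_cohort()
        cond = SimulationCondition(rr=3.5, prevalence=1.0, threshold=0.2,
                                   replicates=3, seed=1)
        d = run_condition(c, cond)
        assert d.delta_auroc == 0.0
        assert d.delta_auroc_se == 0.0

    def test_reproducible_and_seed_sensitive(self, toy_cohort):
        cond = SimulationCondition(rr=2.0, prevalence=0.5, threshold=0.2,
                                   replicates=10, seed=9)
        a, b = run_condition(toy_cohort, cond), run_condition(toy_cohort, cond)
        assert a == b
        c = run_condition(
            toy_cohort,
            SimulationCondition(rr=2.0, prevalence=0.5, threshold=0.2,
                                replicates=10, seed=10),
        )
        assert c != a

    def test_converges_to_oracles(self):
        """Simulated means agree with the closed forms to 3 MC SEs."""
        cohort = small_study_cohort(seed=2)
        rr, p = 2.0, 1.0 / 3.0
        cond = SimulationCondition(rr=rr, prevalence=p, threshold=0.2,
                                   replicates=200, seed=3)
        d = run_condition(cohort, cond)
        ev = cohort.events_mask
        idi_oracle = expected_idi(
            cohort.risk[ev].mean(), cohort.risk[~ev].mean(), rr, p
        )
        cal_oracle = expected_delta_calibration(
            calibration_ratio(cohort.outcome, cohort.risk), rr, p
        )
        assert abs(d.idi - idi_oracle) < 3 * d.idi_se
        assert abs(d.delta_calibration - cal_oracle) < 3 * d.delta_calibration_se

    def test_counts_risks_above_one(self):
        c = small_study_cohort(seed=4)
        cond = SimulationCondition(rr=3.5, prevalence=1.0, threshold=0.2,
                                   replicates=2, seed=0)
        d = run_condition(c, cond)
        assert d.n_risks_gt1 == float((c.risk > 1.0 / 3.5).sum())


class TestRunGrid:
    def test_paper_grids_have_thirty_conditions(self):
        grids = paper_style_grids()
        assert len(grids["rr"]) == len(grids["prevalence"]) == 10
        assert len(grids["threshold"]) == 10
        assert grids["rr"][0] == 1.25 and grids["rr"][-1] == 3.5
        c = small_study_cohort(n=400)
        table = run_grid(c, grids["rr"], grids["prevalence"], grids["threshold"],
                         replicates=2, seed=0)
        assert len(table) == 30
        assert table["panel"].value_counts().to_dict() == {
            "rr": 10, "prevalence": 10, "threshold": 10,
        }

    def test_single_value_grids(self):
        c = small_study_cohort(n=400)
        table = run_grid(c, [2.0], [0.5], [0.2], replicates=2, seed=0)
        assert len(table) == 3

    def test_threshold_panel_shares_replicate_draws(self):
        """IDI, dAUROC and dCalibration are threshold-free statistics and
        must be identical across the threshold panel within a replicate set."""
        c = small_study_cohort(n=2000)
        table = run_grid(c, [2.0], [1.0 / 3.0], [0.1, 0.2, 0.3, 0.4],
                         replicates=5, seed=7)
        thr = table[table.panel == "threshold"]
        for col in ("idi", "delta_auroc", "delta_calibration"):
            assert thr[col].nunique() == 1

    def test_empty_grid_raises(self):
        c = small_study_cohort(n=400)
        with pytest.raises(ValueError, match="grid"):
            run_grid(c, [], [0.5], [0.2])

    def test_monotone_signs_on_small_cohort(self):
        """dCalibration strictly decreasing in RR and prevalence; dAUROC
        non-positive across the RR panel."""
        c = small_study_cohort(seed=6)
        table = run_grid(
            c, [1.25, 2.0, 2.75, 3.5], [0.2, 0.5, 0.8, 1.0], [0.2],
            defaults=GridDefaults(), replicates=20, seed=11,
        )
        rr_panel = table[table.panel == "rr"].sort_values("rr")
        assert (np.diff(rr_panel["delta_calibration"]) < 0).all()
        assert (rr_panel["delta_auroc"] <= 1e-12).all()
        prev_panel = table[table.panel == "prevalence"].sort_values("prevalence")
        assert (np.diff(prev_panel["delta_calibration"]) < 0).all()
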