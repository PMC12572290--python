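"""DiD model, bootstrap CIs and synthetic control."""

import numpy as np
import pandas as pd
import pytest

from ldis.impact_analysis import (
    DiDModel,
    DiDSpec,
    balance_panel,
    counterfactual_series,
    fit_did,
    mean_change_ci,
    synthetic_control,
)
from ldis.synthetic_data import DiDParams, gen_did_panel


def _panel_from_cells(cb, ca, tb, ta, n_per_cell=5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for zone, period, mean in [("annulus", "at_planting", cb), ("annulus", "plus1", ca),
                               ("site", "at_planting", tb), ("site", "plus1", ta)]:
        for i in range(n_per_cell):
            rows.append({"site_id": f"s{i}", "zone": zone, "period": period,
                         "year": 2018, "ndvi": mean + rng.normal(0, noise),
                         "ndre": np.nan, "savi": np.nan, "n_valid_cells": 1})
    return pd.DataFrame(rows)


class TestBalancePanel:
    def test_incomplete_site_dropped(self):
        p = _panel_from_cells(0.2, 0.3, 0.1, 0.2, n_per_cell=3)
        p = p[~((p["site_id"] == "s1") & (p["period"] == "plus1") & (p["zone"] == "site"))]
        out = balance_panel(p, ["at_planting", "plus1"])
        assert set(out["site_id"]) == {"s0", "s2"}

    def test_complete_panel_unchanged(self):
        p = _panel_from_cells(0.2, 0.3, 0.1, 0.2, n_per_cell=4)
        out = balance_panel(p, ["at_planting", "plus1"])
        assert len(out) == len(p)

    def test_row_count_after_balancing(self):
        # 3 of 5 sites complete over 2 periods x 2 zones -> 3 * 2 * 2 rows
        p = _panel_from_cells(0.2, 0.3, 0.1, 0.2, n_per_cell=5)
        p = p[~(p["site_id"].isin(["s3", "s4"]) & (p["zone"] == "annulus")
                & (p["period"] == "plus1"))]
        out = balance_panel(p, ["at_planting", "plus1"])
        assert len(out) == 3 * 2 * 2

    def test_empty_result_raises(self):
        p = _panel_from_cells(0.2, 0.3, 0.1, 0.2, n_per_cell=2)
        p = p[p["zone"] == "site"]
        with pytest.raises(ValueError):
            balance_panel(p, ["at_planting", "plus1"])


class TestFitDiD:
    def test_noiseless_cells_recovered_exactly(self):
        """The published one-year-after column's cell means, noiseless."""
        p = _panel_from_cells(0.265, 0.313, 0.175, 0.271, n_per_cell=10)
        res = fit_did(p, DiDSpec(period_after="plus1"))
        assert res.intercept == pytest.approx(0.265, abs=1e-12)
        assert res.beta_g == pytest.approx(-0.090, abs=1e-12)
        assert res.beta_t == pytest.approx(0.048, abs=1e-12)
        assert res.beta_gt == pytest.approx(0.048, abs=1e-12)
        assert res.rsquared == pytest.approx(1.0)
        assert res.n_obs == 40

    def test_ols_equals_cell_mean_contrasts(self):
        p = _panel_from_cells(0.3, 0.35, 0.2, 0.33, n_per_cell=17, noise=0.1, seed=4)
        res = fit_did(p, DiDSpec(period_after="plus1"))
        m = res.cell_means
        assert res.intercept == pytest.approx(m["control_before"], abs=1e-10)
        assert res.beta_g == pytest.approx(m["treat_before"] - m["control_before"], abs=1e-10)
        assert res.beta_t == pytest.approx(m["control_after"] - m["control_before"], abs=1e-10)
        assert res.beta_gt == pytest.approx(
            (m["treat_after"] - m["treat_before"]) - (m["control_after"] - m["control_before"]),
            abs=1e-10,
        )

    def test_invariant_to_row_order_and_site_relabelling(self):
        p = _panel_from_cells(0.3, 0.35, 0.2, 0.33, n_per_cell=9, noise=0.05, seed=1)
        res1 = fit_did(p, DiDSpec(period_after="plus1"))
        shuffled = p.sample(frac=1.0, random_state=7).reset_index(drop=True)
        shuffled["site_id"] = shuffled["site_id"].map(lambda s: "x" + s)
        res2 = fit_did(shuffled, DiDSpec(period_after="plus1"))
        np.testing.assert_allclose(res1.params, res2.params, atol=1e-12)

    def test_empty_cell_is_design_error(self):
        with pytest.raises(ValueError, match="empty design cell"):
            DiDModel(y=[1.0, 2.0], g=[0, 0], t=[0, 1])

    def test_null_effect_estimate_near_zero(self):
        """beta_gt = 0 generating process: estimate within 3 SE in >= 99 of
        100 seeded runs (approximately the nominal 99.7%)."""
        params = DiDParams(0.3, -0.05, 0.04, 0.0, 0.1, 2000)
        hits = 0
        for seed in range(100):
            res = fit_did(gen_did_panel(params, seed=seed), DiDSpec(period_after="plus1"))
            if abs(res.beta_gt) < 3 * res.bse[3]:
                hits += 1
        assert hits >= 99

    def test_unbiased_parameter_recovery(self):
        """Mean bias over 100 replicates is statistically indistinguishable
        from zero for every coefficient (3 SEs of the mean, the joint bound
        for checking four coefficients at once)."""
        params = DiDParams(0.25, -0.08, 0.05, 0.06, 0.15, 1200)
        truth = np.array([0.25, -0.08, 0.05, 0.06])
        fits, ses = [], []
        for seed in range(100):
            res = fit_did(gen_did_panel(params, seed=200 + seed),
                          DiDSpec(period_after="plus1"))
            fits.append(res.params)
            ses.append(res.bse)
        bias = np.mean(fits, axis=0) - truth
        se_of_mean = np.mean(ses, axis=0) / np.sqrt(100)
        assert np.all(np.abs(bias) < 3 * se_of_mean), bias


class TestCounterfactual:
    def test_published_cells_arithmetic(self):
        p = _panel_from_cells(0.265, 0.313, 0.175, 0.271, n_per_cell=3)
        res = fit_did(p, DiDSpec(period_after="plus1"))
        cf = counterfactual_series(res)
        assert cf["treat_after"] == pytest.approx(0.265 - 0.090 + 0.048, abs=1e-12)

    def test_null_interaction_counterfactual_equals_fit(self):
        p = _panel_from_cells(0.2, 0.25, 0.3, 0.35, n_per_cell=4)  # parallel trends
        res = fit_did(p, DiDSpec(period_after="plus1"))
        assert res.beta_gt == pytest.approx(0.0, abs=1e-12)
        cf = res.counterfactual_series()
        assert cf["treat_after"] == pytest.approx(res.cell_means["treat_after"], abs=1e-12)

    def test_did_gap_equals_interaction(self):
        p = _panel_from_cells(0.22, 0.31, 0.18, 0.33, n_per_cell=6, noise=0.02, seed=2)
        res = fit_did(p, DiDSpec(period_after="plus1"))
        gap = res.cell_means["treat_after"] - res.counterfactual_series()["treat_after"]
        assert gap == pytest.approx(res.beta_gt, abs=1e-10)


class TestMeanChangeCI:
    def test_zero_variance_degenerate_ci(self):
        p = _panel_from_cells(0.2, 0.25, 0.3, 0.35, n_per_cell=8)
        mean, lo, hi = mean_change_ci(p, "site", "plus1", B=200, seed=1)
        assert mean == pytest.approx(0.05)
        assert lo == pytest.approx(mean) and hi == pytest.approx(mean)

    def test_seeded_reproducibility(self):
        p = _panel_from_cells(0.2, 0.26, 0.3, 0.36, n_per_cell=40, noise=0.05, seed=3)
        a = mean_change_ci(p, "site", "plus1", B=500, seed=11)
        b = mean_change_ci(p, "site", "plus1", B=500, seed=11)
        assert a == b
        c = mean_change_ci(p, "site", "plus1", B=500, seed=12)
        assert a != c

    def test_bootstrap_coverage(self):
        """CI covers the true mean change in roughly 95% of seeded runs."""
        rng = np.random.default_rng(99)
        covered = 0
        n_reps = 200
        for rep in range(n_reps):
            changes = rng.normal(0.05, 0.01, size=500)
            rows = []
            for i, ch in enumerate(changes):
                rows.append({"site_id": f"s{i}", "zone": "site",
                             "period": "at_planting", "ndvi": 0.3})
                rows.append({"site_id": f"s{i}", "zone": "site",
                             "period": "plus1", "ndvi": 0.3 + ch})
            p = pd.DataFrame(rows)
            _, lo, hi = mean_change_ci(p, "site", "plus1", B=1000, seed=rep)
            if lo <= 0.05 <= hi:
                covered += 1
        assert 0.90 <= covered / n_reps <= 0.99


class TestSyntheticControl:
    def test_single_bucket_equals_plain_mean(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(0.4, 0.1, 500)
        site = rng.normal(0.35, 0.08, 300)
        follow = ctrl + 0.02
        res = synthetic_control(ctrl, site, {"plus1": follow}, n_buckets=1)
        assert res.control_means_by_period["plus1"] == pytest.approx(follow.mean(), abs=1e-12)

    def test_matching_distributions_recover_plain_mean(self):
        rng = np.random.default_rng(1)
        site = rng.normal(0.4, 0.05, 4000)
        ctrl = rng.normal(0.4, 0.05, 4000)
        res = synthetic_control(ctrl, site, {"at_planting": ctrl}, n_buckets=10)
        assert res.control_means_by_period["at_planting"] == pytest.approx(
            ctrl.mean(), abs=0.005
        )

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = synthetic_control(rng.random(100), rng.random(100),
                                {"plus1": rng.random(100)}, n_buckets=7)
        assert res.bucket_weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.bucket_weights >= 0)

    def test_empty_bucket_reweighted_with_warning(self, caplog):
        import logging

        site = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        ctrl = np.full(60, 0.1)  # nothing lands in the upper buckets
        with caplog.at_level(logging.WARNING):
            res = synthetic_control(ctrl, site, {"plus1": ctrl}, n_buckets=4)
        assert any("re-weighted" in r.message for r in caplog.records)
        assert res.bucket_weights.sum() == pytest.approx(1.0)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            synthetic_control([], [0.4], {"plus1": []})
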