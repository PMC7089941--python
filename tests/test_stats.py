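import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from scipy.stats import chi2

from hgsoc_strat.stats import (
    _fisher_2xc_exact,
    apply_horizon,
    bh_adjust,
    cox_fit,
    fisher_exact,
    km_curve,
    logrank,
    pairwise_logrank_bh,
)
from hgsoc_strat.types import SurvivalRecord


def hypergeom_two_sided_oracle(table):
    """Full enumeration of the 2x2 conditional distribution: two-sided p is
    the sum of point probabilities <= the observed one (point-probability
    convention, with a small relative tolerance)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point(x):
        return comb(c1, x, exact=True) * comb(n - c1, r1 - x, exact=True)

    denom = comb(n, r1, exact=True)
    p_obs = point(a)
    total = sum(p for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
                if (p := point(x)) <= p_obs * (1 + 1e-7))
    return total / denom


def make_records(times, events, prefix="s"):
    return [SurvivalRecord(f"{prefix}{i}", float(t), int(e))
            for i, (t, e) in enumerate(zip(times, events))]


class TestFisher2x2:
    def test_table2_stage_row(self):
        # non-Fibrosis vs Fibrosis x stage II vs III-IV
        res = fisher_exact(np.array([[20, 260], [4, 195]]))
        assert round(res.p_value, 2) == 0.01

    def test_symmetric_table_p_one(self):
        assert fisher_exact(np.array([[5, 5], [5, 5]])).p_value == pytest.approx(1.0)

    def test_hand_enumerated_value(self):
        # 2*(1 + 100 + 2025) / C(20,10) = 4252/184756
        res = fisher_exact(np.array([[2, 8], [8, 2]]))
        assert res.p_value == pytest.approx(4252 / 184756, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.tuples(*[st.integers(0, 10)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        table = [[a + 1, b], [c, d + 1]]  # +1 keeps margins nonzero
        p = fisher_exact(np.array(table)).p_value
        assert p == pytest.approx(hypergeom_two_sided_oracle(table), rel=1e-8)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            fisher_exact(np.array([[0, 0], [3, 4]]))


class TestFisherRxC:
    def test_2xc_enumeration_reduces_to_2x2(self):
        table = np.array([[12, 5], [7, 18]])
        assert _fisher_2xc_exact(table) == pytest.approx(
            fisher_exact(table).p_value, rel=1e-9
        )

    def test_2x4_matches_r_fisher_test(self):
        """Independent oracle: R's fisher.test on the same 2x4 table."""
        table = np.array([[5, 12, 1, 6], [129, 92, 101, 126]])
        p = fisher_exact(table).p_value
        script = (
            "cat(fisher.test(matrix(c(5,129,12,92,1,101,6,126), nrow=2))$p.value)"
        )
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        assert p == pytest.approx(float(out.stdout.strip()), rel=1e-6)

    def test_4x2_transposed_handled(self):
        table = np.array([[5, 129], [12, 92], [1, 101], [6, 126]])
        assert fisher_exact(table).p_value == pytest.approx(
            fisher_exact(table.T).p_value, rel=1e-12
        )

    def test_montecarlo_agrees_with_exact(self):
        table = np.array([[8, 3, 6], [2, 9, 4]])
        exact = fisher_exact(table).p_value
        mc = fisher_exact(table, exact_max_n=0, mc_draws=200_000, seed=11).p_value
        assert mc == pytest.approx(exact, abs=0.01)
        assert "montecarlo" in fisher_exact(table, exact_max_n=0,
                                            mc_draws=1000).method


class TestKaplanMeier:
    def test_no_events_flat_one(self):
        curve = km_curve(make_records([5, 8, 12], [0, 0, 0]), horizon_months=None)
        assert curve.times.size == 0
        assert curve.survival_at(100) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # event at 1 (3 at risk), censored at 2, event at 3 (1 at risk)
        curve = km_curve(make_records([1, 2, 3], [1, 0, 1]), horizon_months=None)
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_four_distinct_events_steps(self):
        curve = km_curve(make_records([1, 2, 3, 4], [1, 1, 1, 1]),
                         horizon_months=None)
        assert np.allclose(curve.survival, [0.75, 0.50, 0.25, 0.0])
        assert np.array_equal(curve.n_at_risk, [4, 3, 2, 1])

    def test_no_censoring_equals_empirical_sf(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 60).round(2) + 0.01
        curve = km_curve(make_records(times, np.ones(60)), horizon_months=None)
        for t in (1.0, 5.0, 12.0):
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_horizon_censors_late_followup(self):
        recs = make_records([50, 200], [1, 1])
        curve = km_curve(recs, horizon_months=120)
        assert curve.survival_at(119) == pytest.approx(0.5)  # second event gone

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_curve([])


def logrank_oracle(times, events, groups):
    """Brute-force two-group log-rank from the at-risk table."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        recs = make_records([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        labels = {r.sample_id: ("A" if i < 3 else "B")
                  for i, r in enumerate(recs)}
        res = logrank(recs, labels, horizon_months=None)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        times = [3, 5, 7, 2, 4, 9]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["A", "A", "A", "B", "B", "B"]
        recs = make_records(times, events)
        labels = {r.sample_id: g for r, g in zip(recs, groups)}
        res = logrank(recs, labels, horizon_months=None)
        assert res.statistic == pytest.approx(
            logrank_oracle(times, events, groups), rel=1e-9
        )

    def test_p_is_chisq_tail_at_df(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 30) + 0.1
        events = rng.integers(0, 2, 30)
        events[0] = 1
        recs = make_records(times, events)
        labels = {r.sample_id: f"g{i % 3}" for i, r in enumerate(recs)}
        res = logrank(recs, labels, horizon_months=None)
        assert res.df == 2
        assert res.p_value == pytest.approx(chi2.sf(res.statistic, 2), rel=1e-9)

    def test_single_group_rejected(self):
        recs = make_records([1, 2], [1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            logrank(recs, {r.sample_id: "A" for r in recs}, None)


class TestPairwiseBH:
    def test_identical_groups_all_one(self):
        base_t, base_e = [1, 2, 3, 4], [1, 1, 0, 1]
        recs, labels = [], {}
        for g in ("A", "B", "C"):
            part = make_records(base_t, base_e, prefix=g)
            recs += part
            labels.update({r.sample_id: g for r in part})
        mat = pairwise_logrank_bh(recs, labels, horizon_months=None)
        off = mat.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matrix_shape_and_symmetry(self, synthetic_cohort):
        truth = synthetic_cohort.truth["stratum_true"]
        mat = pairwise_logrank_bh(synthetic_cohort.clinical, truth.to_dict())
        assert mat.shape == (4, 4)
        arr = mat.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.isnan(np.diag(arr)).all()
        # exactly 6 distinct off-diagonal adjusted p-values
        assert np.isfinite(arr[~np.eye(4, dtype=bool)]).sum() == 12

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        recs, labels = [], {}
        for g in ("A", "B", "C"):
            t = rng.exponential(20 if g == "A" else 10, 25)
            part = make_records(t + 0.1, np.ones(25), prefix=g)
            recs += part
            labels.update({r.sample_id: g for r in part})
        mat = pairwise_logrank_bh(recs, labels, horizon_months=None)
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            sub = {s: g for s, g in labels.items() if g in (a, b)}
            raw = logrank([r for r in recs if r.sample_id in sub], sub, None).p_value
            assert mat.loc[a, b] >= raw - 1e-12


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_clipping_at_one(self):
        assert np.allclose(bh_adjust([0.5, 1.0]), [1.0, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_matches_closed_form_and_monotone(self, pvals):
        adj = bh_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * m / rank)
            expected[i] = running
        assert np.allclose(adj, expected)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        # adjustment preserves the rank order of the raw p-values
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def efron_loglik(beta, times, events, x):
    """Efron partial log-likelihood for one binary covariate."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        d = tied.sum()
        risk = times >= t
        sum_risk = np.exp(beta * x[risk]).sum()
        sum_tied = np.exp(beta * x[tied]).sum()
        ll += beta * x[tied].sum()
        for l in range(d):
            ll -= math.log(sum_risk - (l / d) * sum_tied)
    return ll


class TestCox:
    def test_matches_efron_grid_search_on_fixture(self):
        times = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 9.0, 12.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1, 1, 0, 1, 0, 1, 0, 0])
        recs = [SurvivalRecord(f"s{i}", t, int(e), {"g": "hi" if xi else "lo"})
                for i, (t, e, xi) in enumerate(zip(times, events, x))]
        res = cox_fit(recs, ["g"], reference_levels={"g": "lo"})[0]
        grid = np.arange(-3, 3, 1e-4)
        lls = [efron_loglik(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert math.log(res.hazard_ratio) == pytest.approx(beta_star, abs=1e-3)

    def test_null_limit_two_exchangeable_groups(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(30, 2000)
        recs = [SurvivalRecord(f"s{i}", float(ti) + 0.01, 1,
                               {"g": "A" if i % 2 else "B"})
                for i, ti in enumerate(t)]
        res = cox_fit(recs, ["g"])[0]
        assert abs(math.log(res.hazard_ratio)) < 0.1
        assert res.ci95_low < 1.0 < res.ci95_high

    def test_single_level_factor_rejected(self):
        recs = [SurvivalRecord(f"s{i}", float(i + 1), 1, {"g": "A"})
                for i in range(5)]
        with pytest.raises(ValueError, match="fewer than 2"):
            cox_fit(recs, ["g"])

    def test_missing_covariates_dropped_complete_case(self):
        from hgsoc_strat.types import MISSING
        rng = np.random.default_rng(1)
        recs = []
        for i in range(60):
            g = "A" if i % 2 else "B"
            stage = MISSING if i < 6 else ("II" if i % 3 else "III")
            recs.append(SurvivalRecord(
                f"s{i}", float(rng.exponential(20) + 0.1), 1,
                {"g": g, "stage": stage}))
        uni = cox_fit(recs, ["g"])
        multi = cox_fit(recs, ["g", "stage"])
        assert len(uni) == 1 and len(multi) == 2  # g[.] + stage[.]


class TestHorizon:
    def test_truncation_censors_at_horizon(self):
        recs = make_records([50, 130, 200], [1, 1, 0])
        out = apply_horizon(recs, 120)
        assert [(r.time, r.event) for r in out] == [(50, 1), (120, 0), (120, 0)]

    def test_disabled_horizon_identity(self):
        recs = make_records([50, 130], [1, 1])
        assert apply_horizon(recs, None) == recs
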