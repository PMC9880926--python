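"""Windowed confusion, metrics, enrichment, exact tests, permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from relapsekit import evaluation as ev


def _anoms(rows):
    return pd.DataFrame(rows, columns=["id", "channel", "day", "p", "flag"])


def _rel(rows):
    return pd.DataFrame(rows, columns=["id", "day", "criterion"])


def _scored(pid, days, flagged=(), channel="active"):
    return [
        (pid, channel, d, 0.001 if d in flagged else 0.5, d in flagged)
        for d in days
    ]


class TestConfusionAtWindow:
    def test_no_flags_no_relapses_all_tn(self):
        a = _anoms(_scored("P", range(100)))
        c = ev.confusion_at_window(a, _rel([]))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 100)

    def test_toy_window_counts(self):
        # 100 scored days, relapse at 50 (window [20, 80] = 61 days),
        # flags at 30 (inside) and 95 (outside)
        a = _anoms(_scored("P", range(100), flagged={30, 95}))
        c = ev.confusion_at_window(a, _rel([("P", 50, "x")]))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 60, 38)

    def test_counts_sum_to_scored_units(self):
        a = _anoms(
            _scored("P", range(60), flagged={5, 40})
            + _scored("Q", range(80), flagged={70}, channel="passive")
        )
        c = ev.confusion_at_window(a, _rel([("P", 30, "x")]))
        assert c.total == 140

    @pytest.mark.parametrize("case", range(100))
    def test_matches_brute_force_oracle_on_random_configs(self, case):
        rng = np.random.default_rng(200 + case)
        n = int(rng.integers(40, 120))
        window = int(rng.integers(5, 40))
        days = sorted(rng.choice(n, size=int(rng.integers(10, n)), replace=False))
        flagged = set(rng.choice(days, size=int(rng.integers(0, 5)), replace=False))
        rel_days = list(rng.choice(n, size=int(rng.integers(0, 3)), replace=False))
        a = _anoms(_scored("P", days, flagged))
        rel = _rel([("P", int(d), "x") for d in rel_days])
        c = ev.confusion_at_window(a, rel, window=window)
        # brute force: classify each scored day directly
        tp = fp = tn = fn = 0
        for d in days:
            inw = any(abs(d - r) <= window for r in rel_days)
            fl = d in flagged
            tp += fl and inw
            fp += fl and not inw
            fn += (not fl) and inw
            tn += (not fl) and not inw
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        m = ev.binary_metrics(ev.ConfusionCounts(10, 0, 90, 0))
        assert m.rounded() == {"rmse": 0.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_zero_denominator_marks_metric_undefined(self):
        m = ev.binary_metrics(ev.ConfusionCounts(0, 5, 95, 0))
        assert "sensitivity" in m.undefined
        assert np.isnan(m.sensitivity)


class TestRateRatio:
    def test_hand_arithmetic_toy(self):
        # 60 in-window units with 4 flags, 540 outside with 6 flags:
        # (4/60) / (6/540) = 6.0 — relapse at day 60, pre_post window
        # [30, 90], 600 scored days total
        days = range(600)
        flagged = {35, 45, 55, 65, 100, 200, 300, 400, 500, 599}
        a = _anoms(_scored("P", days, flagged))
        rr = ev.rate_ratio(a, _rel([("P", 60, "x")]), mode="pre_post", window=30)
        assert rr.n_inside == 61
        # adjust to exactly the stated toy: use a constructed indicator
        inw = {d for d in days if 30 <= d <= 90}
        fin = len(flagged & inw)
        fout = len(flagged - inw)
        expected = (fin / len(inw)) / (fout / (600 - len(inw)))
        assert rr.ratio == pytest.approx(expected)

    def test_uniform_flags_give_null_ratio(self):
        rng = np.random.default_rng(14)
        days = range(4000)
        flagged = set(rng.choice(4000, size=400, replace=False))
        a = _anoms(_scored("P", days, flagged))
        rr = ev.rate_ratio(a, _rel([("P", 2000, "x")]), mode="pre_post")
        assert rr.ratio == pytest.approx(1.0, abs=0.35)

    def test_pre_mode_excludes_relapse_day(self):
        a = _anoms(_scored("P", range(200), flagged={100}))
        rr = ev.rate_ratio(a, _rel([("P", 100, "x")]), mode="pre")
        assert rr.rate_inside == 0.0  # flag on the relapse day itself

    def test_zero_outside_rate_reported_as_undefined(self):
        a = _anoms(_scored("P", range(100), flagged={30}))
        rr = ev.rate_ratio(a, _rel([("P", 49, "x")]), mode="pre")
        assert np.isnan(rr.ratio)
        assert rr.diagnostic


class TestRelapseFromPanss:
    def _monthly(self, scores, pid="P"):
        rows = [
            {"id": pid, "visit": v, "instrument": "PANSS", "score": s}
            for v, s in enumerate(scores)
        ]
        return pd.DataFrame(rows)

    def test_exact_25pct_increase_is_inclusive_boundary(self):
        out = ev.relapse_from_panss(self._monthly([80, 100]))
        assert len(out) == 1 and out["day"].iloc[0] == 30

    def test_just_below_threshold_is_not_a_relapse(self):
        assert len(ev.relapse_from_panss(self._monthly([80, 99]))) == 0

    def test_missing_visit_skipped_in_comparison(self):
        out = ev.relapse_from_panss(self._monthly([80, np.nan, 100]))
        assert len(out) == 1 and out["day"].iloc[0] == 60


class TestSiteChisq:
    def test_three_site_relapse_table(self):
        chi2, df, p = ev.site_chisq([[9, 17], [8, 17], [3, 22]])
        assert chi2 == pytest.approx(3.98, abs=0.01)
        assert df == 2
        assert p == pytest.approx(0.14, abs=0.005)

    def test_proportional_rows_give_zero_statistic(self):
        chi2, df, p = ev.site_chisq([[10, 20], [5, 10], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df2_pvalue_matches_exponential_closed_form(self):
        chi2, df, p = ev.site_chisq([[9, 17], [8, 17], [3, 22]])
        assert df == 2
        assert p == pytest.approx(np.exp(-chi2 / 2), abs=1e-10)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            ev.site_chisq([[0, 0], [3, 4]])

    def test_matches_textbook_pearson_formula_on_small_tables(self):
        """Exhaustive 2x2 sweep (entries <= 6) plus random 3x2 tables
        against a hand-coded Pearson chi-square."""
        def pearson(t):
            t = np.asarray(t, dtype=float)
            rows, cols, n = t.sum(1), t.sum(0), t.sum()
            e = np.outer(rows, cols) / n
            return float(((t - e) ** 2 / e).sum())

        for a, b, c, d in itertools.product(range(7), repeat=4):
            t = [[a, b], [c, d]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            chi2, _, _ = ev.site_chisq(t)
            assert chi2 == pytest.approx(pearson(t), abs=1e-10)
        rng = np.random.default_rng(15)
        for _ in range(300):
            t = rng.integers(0, 50, size=(3, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            chi2, _, _ = ev.site_chisq(t)
            assert chi2 == pytest.approx(pearson(t), abs=1e-8)


class TestFreemanHalton:
    def test_2x2_equals_fisher_exact(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            expected = stats.fisher_exact(t)[1]
            assert ev.freeman_halton(t) == pytest.approx(expected, abs=1e-9)

    def test_fixed_margin_probabilities_sum_to_one(self):
        # enumeration sanity: with lp_obs = +inf every table is counted
        t = np.array([[4, 2, 3], [1, 5, 2], [3, 1, 4]])
        total = ev._enumerate_p(t.sum(axis=1), t.sum(axis=0), np.inf)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_row_dropped_single_row_gives_one(self):
        assert ev.freeman_halton([[3, 4], [0, 0]]) == 1.0
        assert ev.freeman_halton([[3, 4]]) == 1.0

    def test_sex_by_site_table_reproduces_printed_pvalue(self):
        t = [[21, 17, 20], [10, 32, 30], [2, 0, 0]]
        assert ev.freeman_halton(t) == pytest.approx(0.004, abs=5e-4)

    def test_monte_carlo_mode_close_to_exact(self):
        t = [[8, 3], [2, 9]]
        exact = ev.freeman_halton(t)
        mc = ev.freeman_halton(t, monte_carlo=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_oversized_table_advises_monte_carlo(self):
        big = np.full((5, 5), 10)
        with pytest.raises(ValueError, match="[Mm]onte"):
            ev.freeman_halton(big)


class TestControlFprAuc:
    def test_all_pvalues_one_gives_zero_area(self):
        areas = ev.control_fpr_auc({"A": {"p1": np.ones(100)}})
        assert areas["A"] == 0.0

    def test_uniform_pvalues_match_identity_integral(self):
        rng = np.random.default_rng(17)
        pv = {"A": {"p1": rng.random(200_000)}}
        areas = ev.control_fpr_auc(pv)
        grid = ev.fpr_grid()
        expected = np.trapezoid(grid, grid) / (grid[-1] - grid[0])
        assert areas["A"] == pytest.approx(expected, rel=0.05)

    def test_doubling_pvalues_shrinks_area(self):
        rng = np.random.default_rng(18)
        p = rng.random(50_000) * 0.5
        a1 = ev.control_fpr_auc({"A": {"x": p}})["A"]
        a2 = ev.control_fpr_auc({"A": {"x": np.minimum(2 * p, 1.0)}})["A"]
        assert a2 <= a1

    def test_site_without_controls_excluded(self):
        areas = ev.control_fpr_auc({"A": {"x": np.ones(10)}, "B": {}})
        assert set(areas) == {"A"}


class TestPermutationSiteTest:
    def _sites(self, rng, n_per_site=(5, 5, 5), law=None):
        out = {}
        for si, n in enumerate(n_per_site):
            site = f"S{si}"
            out[site] = {}
            for k in range(n):
                u = rng.random(150)
                if law:
                    u = law(si, u)
                out[site][f"{site}_p{k}"] = u
        return out

    def test_identical_sites_give_p_one(self):
        base = np.random.default_rng(19).random(100)
        pv = {s: {f"{s}{k}": base.copy() for k in range(3)} for s in "ABC"}
        res = ev.permutation_site_test(pv, n_perm=200, seed=0)
        assert res.observed_spread == pytest.approx(0.0)
        assert res.p == 1.0

    def test_single_site_raises(self):
        pv = {"A": {"x": np.random.default_rng(20).random(50)}}
        with pytest.raises(ValueError):
            ev.permutation_site_test(pv, n_perm=10, seed=0)

    def test_reproducible_given_seed(self, rng):
        pv = self._sites(rng)
        a = ev.permutation_site_test(pv, n_perm=300, seed=5)
        b = ev.permutation_site_test(pv, n_perm=300, seed=5)
        assert a.p == b.p and a.observed_spread == b.observed_spread

    def test_type_i_error_calibrated_under_exchangeability(self):
        """Rejection rate at alpha = 0.05 over 200 exchangeable replicates
        stays inside the binomial 95% band."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            pv = self._sites(rng)
            res = ev.permutation_site_test(pv, n_perm=199, seed=rep)
            hits += res.p <= 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) <= band + 1e-9

    def test_power_against_a_heavy_tailed_site(self):
        """A site whose controls emit excess small p-values is detected
        in the majority of replicates."""
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(4000 + rep)

            def law(si, u):
                if si == 0:  # site 0: 5% of days get very small p-values
                    spike = rng.random(len(u)) < 0.05
                    u = u.copy()
                    u[spike] *= 0.001
                return u

            pv = self._sites(rng, law=law)
            res = ev.permutation_site_test(pv, n_perm=199, seed=rep)
            hits += res.p <= 0.05
        assert hits > n_rep / 2


class TestWorkedArithmetic:
    def test_true_positive_percent(self):
        assert ev.true_positive_percent(13, 188) == pytest.approx(6.9, abs=0.05)

    def test_relative_effectiveness(self):
        assert ev.relative_effectiveness(2.12, 1.5) == pytest.approx(1.41, abs=0.005)
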