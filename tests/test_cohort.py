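"""Synthetic cohort generator: composition, streams, missingness, injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import relapsekit as rk
from relapsekit.cohort import (
    DEFAULT_STREAM_SPECS,
    ConfigError,
    RelapseEffect,
    truncated_normal_mean,
)
from relapsekit.streams import ACTIVE_FEATURES, PASSIVE_FEATURES


class TestGenerateCohort:
    def test_default_composition_matches_three_site_design(self):
        cohort = rk.generate_cohort(rk.CohortConfig(), seed=0)
        by_site = cohort.participants.groupby("site").size()
        assert by_site["Boston"] == 33
        assert by_site["Bangalore"] == 49
        assert by_site["Bhopal"] == 50
        assert len(cohort.participants) == 132
        r = cohort.participants[cohort.participants.group == "R"]
        assert r.groupby("site").size().to_dict() == {
            "Boston": 9, "Bangalore": 8, "Bhopal": 3,
        }

    def test_empty_config_yields_empty_cohort(self):
        cfg = rk.CohortConfig(
            site_specs={"Boston": {"R": 0, "NR": 0, "C": 0}}
        )
        cohort = rk.generate_cohort(cfg, seed=0)
        assert len(cohort.participants) == 0
        assert len(cohort.relapses) == 0

    def test_controls_never_carry_relapses(self, small_cohort):
        controls = set(
            small_cohort.participants.loc[
                small_cohort.participants.group == "C", "id"
            ]
        )
        assert not set(small_cohort.relapses["id"]) & controls
        assert not set(small_cohort.episodes["id"]) & controls

    def test_relapse_days_within_enrollment(self, small_cohort):
        enroll = small_cohort.participants.set_index("id")["enrollment_days"]
        for _, ev in small_cohort.relapses.iterrows():
            assert 0 <= ev["day"] < enroll[ev["id"]]

    def test_same_seed_bit_identical(self, small_config):
        a = rk.generate_cohort(small_config, seed=3)
        b = rk.generate_cohort(small_config, seed=3)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.relapses, b.relapses)
        pd.testing.assert_frame_equal(a.monthly, b.monthly)
        ma = rk.simulate_cohort_features(a)
        mb = rk.simulate_cohort_features(b)
        for pid in ma:
            pd.testing.assert_frame_equal(ma[pid].data, mb[pid].data)

    def test_invalid_config_names_offending_field(self):
        with pytest.raises(ConfigError, match="active_quality_target"):
            rk.CohortConfig(active_quality_target=1.5).validate()
        with pytest.raises(ConfigError, match="enrollment_sd_days"):
            rk.CohortConfig(enrollment_sd_days=-1).validate()

    def test_enrollment_mean_matches_truncated_normal_formula(self):
        # Monte-Carlo over many small cohorts vs the closed-form mean of
        # a normal truncated below at the 30-day minimum
        cfg = rk.CohortConfig(
            site_specs={"Boston": {"R": 0, "NR": 15, "C": 15}},
            relapses_per_R=0,
        )
        draws = []
        for seed in range(400):
            c = rk.generate_cohort(cfg, seed=seed)
            draws.append(c.participants["enrollment_days"].to_numpy())
        draws = np.concatenate(draws)
        expected = truncated_normal_mean(156.0, 65.0, 30.0)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se + 0.5  # 0.5 for int rounding


class TestSimulateDays:
    def test_zero_active_quality_blanks_every_active_value(self, rng):
        cfg = rk.CohortConfig(active_quality_target=0.0)
        p = {"id": "X", "enrollment_days": 50}
        m = rk.simulate_participant_days(p, cfg, rng)
        assert m.data[list(ACTIVE_FEATURES)].isna().all().all()
        assert (m.data["active_quality"] == 0).all()

    def test_passive_completeness_hits_target_within_binomial_ci(self, rng):
        cfg = rk.CohortConfig()
        p = {"id": "X", "enrollment_days": 10_000}
        m = rk.simulate_participant_days(p, cfg, rng)
        obs = m.data[list(PASSIVE_FEATURES)].notna().to_numpy()
        n = obs.size
        rate = obs.mean()
        half = 2.576 * np.sqrt(0.574 * (1 - 0.574) / n)
        assert abs(rate - 0.574) < half

    def test_lag1_autocorrelation_matches_phi(self, rng):
        cfg = rk.CohortConfig(
            active_quality_target=1.0, passive_quality_target=1.0
        )
        p = {"id": "X", "enrollment_days": 5000}
        m = rk.simulate_participant_days(p, cfg, rng)
        x = m.data["home_time"].to_numpy()
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r - cfg.stream_specs["home_time"].phi) < 0.05

    def test_day_index_is_gap_free(self, small_matrices):
        for m in small_matrices.values():
            assert list(m.data.index) == list(range(m.n_days))
            q = m.data[["active_quality", "passive_quality"]]
            assert ((q >= 0) & (q <= 1)).all().all()


class TestInjectSignature:
    def _matrix(self, rng, n=120):
        cfg = rk.CohortConfig(active_quality_target=1.0, passive_quality_target=1.0)
        return rk.simulate_participant_days({"id": "X", "enrollment_days": n}, cfg, rng)

    def test_null_effect_is_identity(self, rng):
        m = self._matrix(rng)
        eff = RelapseEffect(
            shifts={"home_time": 0.0}, variance_inflation=1.0, spike_rate=0.0
        )
        out = rk.inject_relapse_signature(m, {"id": "X", "day": 60}, eff)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_mean_shift_recovered_by_difference_of_means(self, rng):
        # delta = 2 SD over a +/-14-day window; spikes off so the
        # difference-of-means oracle applies exactly
        sd = DEFAULT_STREAM_SPECS["home_time"].sd
        eff = RelapseEffect(
            shifts={"home_time": 2.0}, window_days=14,
            variance_inflation=1.0, spike_rate=0.0,
        )
        diffs = []
        for seed in range(40):
            m = self._matrix(np.random.default_rng(seed))
            out = rk.inject_relapse_signature(m, {"id": "X", "day": 60}, eff)
            inside = out.data.loc[46:74, "home_time"].mean()
            outside = pd.concat(
                [out.data.loc[:45, "home_time"], out.data.loc[75:, "home_time"]]
            ).mean()
            diffs.append((inside - outside) / sd)
        assert abs(np.mean(diffs) - 2.0) < 0.25

    def test_event_day_out_of_bounds_raises(self, rng):
        m = self._matrix(rng, n=50)
        with pytest.raises(IndexError):
            rk.inject_relapse_signature(
                m, {"id": "X", "day": 50}, RelapseEffect()
            )

    def test_panss_raised_by_at_least_25pct_at_containing_visit(self):
        monthly = pd.DataFrame(
            {
                "id": ["X"] * 3,
                "visit": [0, 1, 2],
                "instrument": ["PANSS"] * 3,
                "score": [80.0, 80.0, 80.0],
            }
        )
        m = self._matrix(np.random.default_rng(1))
        rk.inject_relapse_signature(
            m, {"id": "X", "day": 35}, RelapseEffect(), monthly=monthly
        )
        assert monthly.loc[monthly.visit == 2, "score"].iloc[0] >= 100.0

    def test_cells_outside_window_unchanged(self, rng):
        m = self._matrix(rng)
        eff = RelapseEffect(window_days=10)
        out = rk.inject_relapse_signature(m, {"id": "X", "day": 60}, eff)
        pd.testing.assert_frame_equal(out.data.loc[:49], m.data.loc[:49])
        pd.testing.assert_frame_equal(out.data.loc[71:], m.data.loc[71:])

    def test_control_windows_show_no_spurious_signal(self):
        """Window-vs-rest mean comparison in control participants is
        non-significant in nearly all replicates (t-test with AR(1)
        effective-sample-size correction, alpha = 0.01)."""
        cfg = rk.CohortConfig(active_quality_target=1.0, passive_quality_target=1.0)
        phi = cfg.stream_specs["home_time"].phi
        ess_factor = (1 - phi) / (1 + phi)
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            m = rk.simulate_participant_days(
                {"id": "C", "enrollment_days": 120}, cfg, rng
            )
            day = int(rng.integers(30, 90))
            x = m.data["home_time"].to_numpy()
            win = x[day - 14 : day + 15]
            rest = np.r_[x[: day - 14], x[day + 15 :]]
            t, _ = stats.ttest_ind(win, rest, equal_var=False)
            df = (len(win) + len(rest) - 2) * ess_factor
            p = 2 * stats.t.sf(abs(t) * np.sqrt(ess_factor), df)
            hits += p < 0.01
        assert hits <= np.ceil(0.05 * n_rep)


class TestCohortIO:
    def test_roundtrip_through_delimited_files(self, tmp_path, small_cohort,
                                               small_matrices):
        rk.cohort.write_cohort(small_cohort, tmp_path, small_matrices)
        cohort2, mats2 = rk.cohort.read_cohort(tmp_path)
        pd.testing.assert_frame_equal(cohort2.participants, small_cohort.participants)
        pd.testing.assert_frame_equal(cohort2.relapses, small_cohort.relapses)
        for pid, m in small_matrices.items():
            pd.testing.assert_frame_equal(
                mats2[pid].data, m.data, check_names=False
            )

    def test_missing_file_error_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="participants.csv"):
            rk.cohort.read_cohort(tmp_path)

    def test_config_loads_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "enrollment_mean_days: 100\n"
            "stream_specs:\n  phq9: {mean: 5, sd: 2, phi: 0.1}\n"
        )
        cfg = rk.cohort.load_cohort_config(path)
        assert cfg.enrollment_mean_days == 100
        assert cfg.stream_specs["phq9"].sd == 2
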