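"""Behavioral indices, binning, tertile grouping, rank-sum test, trends."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bitrl.behavior import (
    assign_ss_groups,
    bin_trajectory,
    cohort_metrics,
    summarize_session,
    trial_trend_regression,
    wilcoxon_rank_sum,
)
from bitrl.cohort import Cohort, Session, SubjectProfile, simulate_sss_scores
from bitrl.task import default_config


def session_from_pct(pct, subject_id=1):
    pct = np.asarray(pct, dtype=float)
    return Session(
        subject_id=subject_id,
        trial=np.arange(1, pct.size + 1),
        option=(pct / 10).astype(int),
        inflation_pct=pct,
        burst=np.zeros(pct.size, dtype=bool),
        reward=pct.copy(),
    )


class TestSummarizeSession:
    def test_constant_fifty_percent_chooser(self):
        s = summarize_session(session_from_pct([50.0] * 60))
        assert (s.mean_choice_pct, s.choice_sd_pct, s.count_choice_50) == (
            50.0,
            0.0,
            60,
        )

    def test_alternating_extremes(self):
        pct = np.tile([10.0, 90.0], 30)
        s = summarize_session(session_from_pct(pct))
        assert s.mean_choice_pct == 50.0
        # sample SD (n-1): population SD 40 inflated by sqrt(n/(n-1))
        assert s.choice_sd_pct == pytest.approx(40.0 * np.sqrt(60 / 59))

    def test_matches_independent_recomputation(self, kl_cohort_small, tmp_path):
        df = kl_cohort_small.to_trials_frame()
        path = tmp_path / "trials.csv"
        df.to_csv(path, index=False)
        raw = pd.read_csv(path)
        for subj, sess in zip(
            kl_cohort_small.subjects, kl_cohort_small.sessions
        ):
            got = summarize_session(sess)
            col = raw.loc[raw.subject_id == subj.subject_id, "inflation_pct"]
            assert got.mean_choice_pct == pytest.approx(col.mean())
            assert got.choice_sd_pct == pytest.approx(col.std(ddof=1))
            assert got.count_choice_50 == int((col == 50).sum())

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            summarize_session(session_from_pct([]))


class TestBinTrajectory:
    def test_sixty_trials_make_twelve_bins(self):
        t = bin_trajectory(session_from_pct(np.tile([30.0], 60)))
        assert len(t.table) == 12 and not t.partial_final_bin
        assert (t.table["sd"] == 0).all()
        assert (t.table["mean"] == 30.0).all()

    def test_weighted_bin_means_conserve_session_mean(self, rng):
        pct = rng.choice(np.arange(10, 100, 10), size=60).astype(float)
        t = bin_trajectory(session_from_pct(pct)).table
        weighted = (t["mean"] * t["n_trials"]).sum() / t["n_trials"].sum()
        assert weighted == pytest.approx(pct.mean())

    def test_partial_final_bin_flagged(self):
        t = bin_trajectory(session_from_pct(np.tile([20.0], 13)), bin_width=5)
        assert t.partial_final_bin and t.table["n_trials"].iloc[-1] == 3

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            bin_trajectory(session_from_pct([10.0] * 10), bin_width=0)


class TestGroupAssignment:
    def test_exact_tertiles_split_evenly(self):
        labels = assign_ss_groups(np.arange(1, 10))
        assert list(labels) == ["LSS"] * 3 + ["MSS"] * 3 + ["HSS"] * 3

    def test_degenerate_scores_all_medium(self):
        assert set(assign_ss_groups(np.full(10, 99.0))) == {"MSS"}

    def test_ties_share_one_label(self):
        scores = np.array([90, 90, 90, 100, 100, 100, 110, 110, 110])
        labels = assign_ss_groups(scores)
        for v in (90, 100, 110):
            assert len({l for s, l in zip(scores, labels) if s == v}) == 1

    def test_paper_sized_cohort_gets_three_nonempty_groups(self):
        scores = simulate_sss_scores(80, randomness=2024)
        labels = assign_ss_groups(scores)
        counts = pd.Series(labels).value_counts()
        assert set(counts.index) == {"LSS", "MSS", "HSS"}
        assert counts.sum() == 80  # partition: nobody unlabeled


def brute_force_rank_sum_p(x, y):
    """Exact two-sided p by enumerating all assignments of the pooled
    sample to the two groups (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = [
        sum(comb)
        for comb in itertools.combinations(ranks, n1)
    ]
    ws = np.array(ws)
    mean_w = ws.mean()
    p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-9)
    return min(1.0, float(p))


class TestWilcoxonRankSum:
    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_most_extreme_four_point_configuration(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_exact_p_matches_enumeration_five_vs_five(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.permutation(20)[:5].astype(float)
            y = rng.permutation(40)[:5].astype(float) + 0.5
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def linear_trend_cohort(rng, slope, n_subjects=10, noise_sd=10.0, groups=None):
    subjects, sessions = [], []
    cfg = default_config()
    for i in range(n_subjects):
        trial = np.arange(1, 61)
        pct = np.clip(
            50 + slope * trial + rng.normal(0, noise_sd, 60), 10, 90
        )
        # snap onto the option grid
        pct = np.round(pct / 10).astype(int) * 10.0
        sessions.append(session_from_pct(pct, subject_id=i + 1))
        label = groups[i % len(groups)] if groups else None
        subjects.append(
            SubjectProfile(subject_id=i + 1, sss_score=100, group_label=label)
        )
    return Cohort(subjects=subjects, sessions=sessions, task=cfg)


class TestTrialTrendRegression:
    def test_injected_decline_recovered_with_negative_sign(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(300 + rep)
            cohort = linear_trend_cohort(rng, slope=-0.3)
            table = trial_trend_regression(cohort).set_index("term")
            hits += table.loc["trial", "estimate"] < 0
        assert hits >= 95

    def test_null_slope_p_values_uniform(self):
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(7000 + rep)
            cohort = linear_trend_cohort(rng, slope=0.0, n_subjects=6)
            table = trial_trend_regression(cohort).set_index("term")
            ps.append(table.loc["trial", "p"])
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_matches_ols_when_no_subject_heterogeneity(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(55)
        cohort = linear_trend_cohort(rng, slope=-0.2, n_subjects=8)
        table = trial_trend_regression(cohort).set_index("term")
        rows = []
        for subj, sess in zip(cohort.subjects, cohort.sessions):
            rows.append(
                pd.DataFrame(
                    {"trial": sess.trial, "inflation_pct": sess.inflation_pct}
                )
            )
        data = pd.concat(rows, ignore_index=True)
        ols = smf.ols("inflation_pct ~ trial", data=data).fit()
        # balanced design: the mixed-model slope equals the OLS slope
        assert table.loc["trial", "estimate"] == pytest.approx(
            ols.params["trial"], abs=1e-6
        )

    def test_group_fixed_effects_reported(self):
        rng = np.random.default_rng(9)
        cohort = linear_trend_cohort(
            rng, slope=0.0, n_subjects=9, groups=["LSS", "MSS", "HSS"]
        )
        table = trial_trend_regression(cohort)
        assert any("MSS" in t for t in table["term"])

    def test_metrics_table_has_one_row_per_subject(self, kl_cohort_small):
        m = cohort_metrics(kl_cohort_small)
        assert len(m) == kl_cohort_small.n_subjects
        assert {"mean_choice_pct", "choice_sd_pct", "count_choice_50"} <= set(
            m.columns
        )
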