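"""Moderation pipeline: table construction, standardization, mixed model."""

import numpy as np
import pandas as pd
import pytest

from bitrl.cohort import Cohort, KLParams, Session, SubjectProfile
from bitrl.moderation import (
    ModerationModel,
    ModerationTable,
    build_moderation_table,
    fit_moderation,
    standardize,
)
from bitrl.task import default_config


def make_cohort(pcts_by_subject, groups, rs_values):
    subjects, sessions = [], []
    for i, (pct, grp, rs) in enumerate(
        zip(pcts_by_subject, groups, rs_values)
    ):
        pct = np.asarray(pct, dtype=float)
        sessions.append(
            Session(
                subject_id=i + 1,
                trial=np.arange(1, pct.size + 1),
                option=(pct / 10).astype(int),
                inflation_pct=pct,
                burst=np.zeros(pct.size, dtype=bool),
                reward=pct.copy(),
            )
        )
        subjects.append(
            SubjectProfile(
                subject_id=i + 1,
                sss_score=100,
                group_label=grp,
                params=KLParams(0.5, 1.0, 0.5, 1.0),
                rs_proxy=rs,
            )
        )
    return Cohort(subjects=subjects, sessions=sessions, task=default_config())


def synthetic_table(rng, n=40, interaction=0.0, resid_sd=5.0, rs=None):
    """Directly built moderation table with known generative structure."""
    sizes = [n // 3, n - 2 * (n // 3), n // 3]
    grp = ["LSS"] * sizes[0] + ["MSS"] * sizes[1] + ["HSS"] * sizes[2]
    rs = rng.standard_normal(n) if rs is None else rs
    gamma = rng.normal(0, 2.0, 10)
    ge = {"LSS": -1.0, "MSS": -4.0, "HSS": 0.0}
    rows = []
    for i in range(n):
        inter = interaction * rs[i] if grp[i] == "LSS" else 0.0
        for b in range(10):
            y = (
                48
                + ge[grp[i]]
                + 0.5 * rs[i]
                + inter
                + gamma[b]
                + rng.normal(0, resid_sd)
            )
            rows.append((i + 1, b + 1, y, grp[i], rs[i]))
    return ModerationTable(
        pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "bin",
                "choice_degree",
                "ss_group",
                "rs_measure",
            ],
        )
    )


class TestBuildTable:
    def test_constant_chooser_gives_constant_degree(self):
        cohort = make_cohort(
            [[50.0] * 60] * 3, ["LSS", "MSS", "HSS"], [0.1, 0.2, 0.3]
        )
        table = build_moderation_table(cohort, rs_column="rs_proxy")
        assert len(table.data) == 30
        assert (table.data["choice_degree"] == 50.0).all()

    def test_row_count_is_ten_per_subject(self):
        rng = np.random.default_rng(0)
        pcts = rng.choice(np.arange(10, 100, 10), size=(6, 60)).astype(float)
        cohort = make_cohort(pcts, ["LSS", "MSS", "HSS"] * 2, np.arange(6) / 6)
        table = build_moderation_table(cohort, rs_column="rs_proxy")
        assert len(table.data) == 60

    def test_bin_mean_matches_hand_computation(self):
        # first 6-trial bin of a printed toy sequence
        seq = [10, 20, 30, 40, 50, 60] + [50] * 54
        cohort = make_cohort(
            [seq, [50] * 60, [50] * 60], ["LSS", "MSS", "HSS"], [0.1, 0.2, 0.3]
        )
        table = build_moderation_table(cohort, rs_column="rs_proxy").data
        first = table[(table.subject_id == 1) & (table.bin == 1)]
        assert first["choice_degree"].iloc[0] == pytest.approx(
            (10 + 20 + 30 + 40 + 50 + 60) / 6
        )

    def test_missing_rs_measure_names_subjects(self):
        cohort = make_cohort(
            [[50.0] * 60] * 3, ["LSS", "MSS", "HSS"], [0.1, None, 0.3]
        )
        with pytest.raises(ValueError, match="2"):
            build_moderation_table(cohort, rs_column="rs_proxy")

    def test_model_parameter_as_rs_measure(self):
        cohort = make_cohort(
            [[50.0] * 60] * 3, ["LSS", "MSS", "HSS"], [0.1, 0.2, 0.3]
        )
        table = build_moderation_table(cohort, rs_column="innovation_var")
        assert (table.data["rs_measure"] == 0.5).all()


class TestStandardize:
    def test_unit_scale_and_idempotence(self):
        rng = np.random.default_rng(1)
        table = synthetic_table(rng)
        std = standardize(table)
        per_subj = std.data.drop_duplicates("subject_id")["rs_measure"]
        assert per_subj.mean() == pytest.approx(0.0, abs=1e-10)
        assert per_subj.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        again = standardize(std)
        pd.testing.assert_frame_equal(std.data, again.data)

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(2)
        table = synthetic_table(rng, rs=np.zeros(40))
        with pytest.raises(ValueError):
            standardize(table)

    def test_slopes_rescale_with_rs_sd(self):
        rng = np.random.default_rng(3)
        table = synthetic_table(rng, interaction=-1.0)
        sd = float(
            table.data.drop_duplicates("subject_id")["rs_measure"].std(ddof=1)
        )
        raw = ModerationModel(
            ModerationTable(table.data, standardized=True)
        ).fit()
        std = fit_moderation(table)
        assert std["rs"]["estimate"] == pytest.approx(
            raw["rs"]["estimate"] * sd, rel=1e-6
        )


class TestFitModeration:
    def test_reference_group_is_hss(self):
        rng = np.random.default_rng(4)
        res = fit_moderation(synthetic_table(rng))
        terms = set(res.table["term"])
        assert {"group(LSS)", "group(MSS)", "rs"} <= terms
        assert res.reference == "HSS"

    def test_equals_ols_with_bin_dummies_in_balanced_design(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        table = synthetic_table(rng, interaction=-1.0)
        res = fit_moderation(table)
        df = standardize(table).data
        ols = smf.ols(
            "choice_degree ~ C(ss_group, Treatment('HSS')) * rs_measure"
            " + C(bin)",
            data=df,
        ).fit()
        # balanced bins are orthogonal to subject-level predictors
        key = "C(ss_group, Treatment('HSS'))[T.LSS]:rs_measure"
        assert res["group(LSS) x rs"]["estimate"] == pytest.approx(
            ols.params[key], abs=1e-5
        )

    def test_changing_reference_preserves_fitted_cell_structure(self):
        rng = np.random.default_rng(6)
        table = synthetic_table(rng, interaction=-1.0)
        res_hss = fit_moderation(table, reference="HSS")
        res_lss = fit_moderation(table, reference="LSS")

        def cell_slope(res, ref, grp):
            t = res.table.set_index("term")
            base = t.loc["rs", "estimate"]
            if grp == ref:
                return base
            return base + t.loc[f"group({grp}) x rs", "estimate"]

        for grp in ("LSS", "MSS", "HSS"):
            assert cell_slope(res_hss, "HSS", grp) == pytest.approx(
                cell_slope(res_lss, "LSS", grp), abs=1e-5
            )

    def test_saturated_design_reproduces_cell_means(self):
        # binary RS, no bin effects, tiny noise: fitted coefficients must
        # reproduce the 3x2 cell means exactly
        rng = np.random.default_rng(7)
        rows = []
        means = {
            ("HSS", -1): 50.0,
            ("HSS", 1): 54.0,
            ("LSS", -1): 47.0,
            ("LSS", 1): 45.0,
            ("MSS", -1): 44.0,
            ("MSS", 1): 46.0,
        }
        sid = 0
        for grp in ("HSS", "LSS", "MSS"):
            for rs in (-1, 1):
                for _ in range(4):
                    sid += 1
                    for b in range(10):
                        rows.append(
                            (
                                sid,
                                b + 1,
                                means[(grp, rs)] + rng.normal(0, 0.01),
                                grp,
                                float(rs),
                            )
                        )
        table = ModerationTable(
            pd.DataFrame(
                rows,
                columns=[
                    "subject_id",
                    "bin",
                    "choice_degree",
                    "ss_group",
                    "rs_measure",
                ],
            ),
            standardized=True,
        )
        res = fit_moderation(table)
        t = res.table.set_index("term")["estimate"]
        got_hss_hi = t["Intercept"] + t["rs"]
        assert got_hss_hi == pytest.approx(means[("HSS", 1)], abs=0.05)
        got_lss_lo = (
            t["Intercept"]
            + t["group(LSS)"]
            - (t["rs"] + t["group(LSS) x rs"])
        )
        assert got_lss_lo == pytest.approx(means[("LSS", -1)], abs=0.05)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(8)
        table = synthetic_table(rng)
        only = ModerationTable(
            table.data[table.data.ss_group == "MSS"].copy()
        )
        with pytest.raises(ValueError):
            fit_moderation(only)
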