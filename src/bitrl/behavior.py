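"""Behavioral indices, binned trajectories, SSS grouping and group tests.

Summaries follow the study's descriptive conventions: mean and sample SD
(n-1 denominator) of the chosen inflation percentage, the count of 50%
choices, and the mean reaction time when present. Trial trajectories are
grouped into bins of five trials (12 bins for a 60-trial session).
Sensation-seeking groups are tertiles at the 33rd/66th percentiles (linear
interpolation); tied scores always share one label. Parameter contrasts
between groups use the Wilcoxon rank-sum test, exact for small samples
without ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehaviorSummary",
    "BinTrajectory",
    "summarize_session",
    "bin_trajectory",
    "assign_ss_groups",
    "wilcoxon_rank_sum",
    "trial_trend_regression",
    "cohort_metrics",
]


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-subject behavioral indices."""

    mean_choice_pct: float
    choice_sd_pct: float
    count_choice_50: int
    mean_rt_ms: Optional[float] = None


@dataclass
class BinTrajectory:
    """Per-bin mean/SD of the chosen inflation percentage."""

    table: pd.DataFrame  # columns: bin, mean, sd, n_trials
    bin_width: int
    partial_final_bin: bool


def summarize_session(session) -> BehaviorSummary:
    """Mean/SD (ddof=1) of chosen inflation % and the exact count of 50%
    choices."""
    pct = np.asarray(session.inflation_pct, dtype=float)
    if pct.size == 0:
        raise ValueError("empty session")
    sd = float(np.std(pct, ddof=1)) if pct.size > 1 else 0.0
    rt = None
    if getattr(session, "rt_ms", None) is not None:
        rt = float(np.mean(session.rt_ms))
    return BehaviorSummary(
        mean_choice_pct=float(np.mean(pct)),
        choice_sd_pct=sd,
        count_choice_50=int(np.sum(pct == 50)),
        mean_rt_ms=rt,
    )


def bin_trajectory(session, bin_width: int = 5) -> BinTrajectory:
    """Trajectory of choices in consecutive bins of ``bin_width`` trials.

    A final partial bin (when the trial count is not divisible by the width)
    is kept and flagged.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    pct = np.asarray(session.inflation_pct, dtype=float)
    if pct.size == 0:
        raise ValueError("empty session")
    n_bins = int(np.ceil(pct.size / bin_width))
    rows = []
    for b in range(n_bins):
        chunk = pct[b * bin_width : (b + 1) * bin_width]
        rows.append(
            {
                "bin": b + 1,
                "mean": float(np.mean(chunk)),
                "sd": float(np.std(chunk, ddof=1)) if chunk.size > 1 else 0.0,
                "n_trials": int(chunk.size),
            }
        )
    return BinTrajectory(
        table=pd.DataFrame(rows),
        bin_width=bin_width,
        partial_final_bin=bool(pct.size % bin_width),
    )


def assign_ss_groups(scores) -> np.ndarray:
    """Tertile labels LSS/MSS/HSS at the 33rd/66th percentiles.

    Percentiles use linear interpolation (numpy default). A score above the
    66th percentile is HSS; a score at or below the 33rd percentile is LSS
    unless it also reaches the 66th percentile (degenerate, e.g. all scores
    equal), in which case it is MSS. The rule depends only on the score, so
    ties never straddle groups.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("grouping needs >= 3 subjects")
    p33, p66 = np.percentile(scores, [33, 66])
    labels = np.full(scores.shape, "MSS", dtype=object)
    labels[scores > p66] = "HSS"
    labels[(scores <= p33) & (scores < p66)] = "LSS"
    return labels


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of ``x`` with midranks for ties.
    The null distribution is exact when min(n) <= 8 and there are no ties,
    otherwise a normal approximation with continuity correction is used.
    Identical samples give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: x.size].sum())
    if np.array_equal(np.sort(x), np.sort(y)):
        return w, 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w, float(min(res.pvalue, 1.0))


def cohort_metrics(cohort) -> pd.DataFrame:
    """One row of behavioral indices per subject, with SSS and group."""
    rows = []
    for subj, sess in zip(cohort.subjects, cohort.sessions):
        s = summarize_session(sess)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "sss_score": subj.sss_score,
                "group_label": subj.group_label,
                "mean_choice_pct": s.mean_choice_pct,
                "choice_sd_pct": s.choice_sd_pct,
                "count_choice_50": s.count_choice_50,
                "mean_rt_ms": s.mean_rt_ms,
            }
        )
    return pd.DataFrame(rows)


def trial_trend_regression(cohort) -> pd.DataFrame:
    """Trial-order effect on chosen inflation %, with group fixed effects
    and a per-subject random intercept.

    Fits ``inflation_pct ~ trial + C(group)`` (group dummies only when at
    least two groups are present) by maximum likelihood with a random
    intercept per subject. Returns one row per fixed effect: estimate, SE,
    z, p.
    """
    import statsmodels.formula.api as smf

    rows = []
    for subj, sess in zip(cohort.subjects, cohort.sessions):
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subj.subject_id,
                    "trial": sess.trial,
                    "inflation_pct": sess.inflation_pct,
                    "group": subj.group_label or "all",
                }
            )
        )
    if len(rows) < 2:
        raise ValueError("need >= 2 subjects")
    data = pd.concat(rows, ignore_index=True)
    groups_present = data["group"].nunique()
    formula = "inflation_pct ~ trial"
    if groups_present > 1:
        formula += " + C(group, Treatment('HSS'))" if "HSS" in set(
            data["group"]
        ) else " + C(group)"
    exog = smf.ols(formula, data=data).exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = smf.ols(formula, data=data).exog_names
        # identify a column whose removal restores full rank
        for j, name in enumerate(names):
            if (
                np.linalg.matrix_rank(np.delete(exog, j, axis=1)) == rank
            ):
                raise ValueError(f"singular design: column {name!r} is collinear")
        raise ValueError("singular design")
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = smf.mixedlm(formula, data=data, groups=data["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        fit = model.fit(reml=False)
    out = []
    for name in fit.fe_params.index:
        out.append(
            {
                "term": name,
                "estimate": float(fit.fe_params[name]),
                "se": float(fit.bse[name]),
                "z": float(fit.tvalues[name]),
                "p": float(fit.pvalues[name]),
            }
        )
    return pd.DataFrame(out)
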