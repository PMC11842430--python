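"""Moderation of risk adjustment by sensation seeking and reward sensitivity.

Risk adjustment is operationalized as the choice degree (mean chosen
inflation %) in 10 ordered bins of 6 trials. A linear mixed model predicts
it from sensation-seeking group (HSS reference), a standardized continuous
reward-sensitivity (RS) measure, and their interaction, with a random
intercept for the choice-order bin:

    choice_degree ~ b0 + b1*group + b2*rs + b3*(group x rs) + gamma_bin + e

fitted by maximum likelihood. The RS measure is pluggable: an
individual-level model parameter (e.g. the innovation variance) or an
external proxy (FRN-like). Confidence intervals are Wald-type at 95%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ModerationTable",
    "ModerationResult",
    "ModerationModel",
    "build_moderation_table",
    "standardize",
    "fit_moderation",
    "N_BINS",
]

#: Choice order is categorized into 10 bins (6 trials each for 60 trials).
N_BINS = 10

_COLUMNS = ["subject_id", "bin", "choice_degree", "ss_group", "rs_measure"]


@dataclass
class ModerationTable:
    """Long-format table: one row per subject x choice-order bin."""

    data: pd.DataFrame
    rs_column: str = "rs_measure"
    standardized: bool = False

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"moderation table missing columns: {missing}")


@dataclass
class ModerationResult:
    """Fixed-effect table (estimate, 95% CI, p), random-intercept variance
    and residual variance, with HSS as the reference group."""

    table: pd.DataFrame
    random_intercept_var: float
    residual_var: float
    reference: str
    converged: bool

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]


def build_moderation_table(
    cohort, rs_column: str = "innovation_var", n_bins: int = N_BINS
) -> ModerationTable:
    """Collapse each session into ``n_bins`` ordered bins and attach the
    subject's group label and RS measure.

    ``rs_column`` may be "rs_proxy" (the subject covariate) or the name of a
    true generative parameter carried by a simulated cohort.
    """
    rows = []
    missing = []
    for subj, sess in zip(cohort.subjects, cohort.sessions):
        if rs_column == "rs_proxy":
            rs = subj.rs_proxy
        else:
            rs = getattr(subj.params, rs_column, None) if subj.params else None
        if rs is None:
            missing.append(subj.subject_id)
            continue
        if subj.group_label is None:
            missing.append(subj.subject_id)
            continue
        pct = np.asarray(sess.inflation_pct, dtype=float)
        if pct.size % n_bins:
            raise ValueError(
                f"subject {subj.subject_id}: {pct.size} trials do not split "
                f"into {n_bins} equal bins"
            )
        width = pct.size // n_bins
        for b in range(n_bins):
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "bin": b + 1,
                    "choice_degree": float(
                        np.mean(pct[b * width : (b + 1) * width])
                    ),
                    "ss_group": subj.group_label,
                    "rs_measure": float(rs),
                }
            )
    if missing:
        raise ValueError(
            f"subjects missing group label or RS measure {rs_column!r}: "
            f"{missing}"
        )
    return ModerationTable(data=pd.DataFrame(rows), rs_column=rs_column)


def standardize(table: ModerationTable) -> ModerationTable:
    """Center and scale the RS measure to unit SD (idempotent); group
    dummies are untouched."""
    df = table.data.copy()
    per_subject = df.drop_duplicates("subject_id")["rs_measure"]
    sd = float(per_subject.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("rs_measure has zero variance; cannot standardize")
    mean = float(per_subject.mean())
    df["rs_measure"] = (df["rs_measure"] - mean) / sd
    return ModerationTable(
        data=df, rs_column=table.rs_column, standardized=True
    )


class ModerationModel:
    """Mixed model of binned choice degree on group x RS.

    ``fit()`` standardizes the RS measure (unless already standardized) and
    returns a :class:`ModerationResult`.
    """

    def __init__(self, table: ModerationTable, reference: str = "HSS"):
        groups = set(table.data["ss_group"])
        if len(groups) < 2:
            raise ValueError("need >= 2 sensation-seeking groups")
        if reference not in groups:
            raise ValueError(f"reference group {reference!r} absent from data")
        self.table = table
        self.reference = reference

    @classmethod
    def from_cohort(cls, cohort, rs_column: str = "innovation_var", **kw):
        return cls(build_moderation_table(cohort, rs_column=rs_column), **kw)

    def fit(self) -> ModerationResult:
        import warnings

        import statsmodels.formula.api as smf
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        table = (
            self.table if self.table.standardized else standardize(self.table)
        )
        df = table.data
        formula = (
            f"choice_degree ~ C(ss_group, Treatment('{self.reference}')) "
            "* rs_measure"
        )
        design = smf.ols(formula, data=df)
        if np.linalg.matrix_rank(design.exog) < design.exog.shape[1]:
            raise ValueError("rank-deficient moderation design")
        model = smf.mixedlm(formula, data=df, groups=df["bin"])
        with warnings.catch_warnings():
            # a near-zero random-intercept variance routinely trips the
            # optimizer's gradient check; the flag below records it
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            fit = model.fit(reml=False)
        z = 1.959963984540054  # Phi^{-1}(0.975)
        rows = []
        for name in fit.fe_params.index:
            est = float(fit.fe_params[name])
            se = float(fit.bse[name])
            rows.append(
                {
                    "term": _clean_term(name, self.reference),
                    "estimate": est,
                    "se": se,
                    "ci_low": est - z * se,
                    "ci_high": est + z * se,
                    "p": float(fit.pvalues[name]),
                }
            )
        return ModerationResult(
            table=pd.DataFrame(rows),
            random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
            residual_var=float(fit.scale),
            reference=self.reference,
            converged=bool(getattr(fit, "converged", True)),
        )


def _clean_term(name: str, reference: str) -> str:
    out = name.replace(
        f"C(ss_group, Treatment('{reference}'))", "group"
    ).replace("[T.", "(").replace("]", ")")
    return out.replace(":rs_measure", " x rs").replace("rs_measure", "rs")


def fit_moderation(
    table: ModerationTable, reference: str = "HSS"
) -> ModerationResult:
    """Fit the group x RS moderation mixed model on a moderation table."""
    return ModerationModel(table, reference=reference).fit()
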