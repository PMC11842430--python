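"""PSIS-LOO model comparison.

Approximate leave-one-out cross-validation from posterior draws: per
observation, importance ratios 1/p(y_i | theta^s) are tail-smoothed with a
generalized-Pareto fit (Pareto-smoothed importance sampling), giving the
expected log pointwise predictive density (elpd) and its standard error.
LOOIC = -2 * elpd, lower is better. Observations here are subject-trials.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["LooResult", "psis_loo", "compare_models"]

#: Below this many draws the generalized-Pareto tail fit is undefined; plain
#: (unsmoothed) importance sampling is used instead.
MIN_DRAWS_FOR_PSIS = 10


@dataclass
class LooResult:
    """elpd estimate with SE, LOOIC (= -2*elpd exactly), and per-observation
    Pareto-k diagnostics."""

    elpd: float
    se: float
    looic: float
    pareto_k: np.ndarray
    pointwise_elpd: np.ndarray
    n_obs: int
    n_draws: int
    name: str = ""
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        assert np.isclose(self.looic, -2.0 * self.elpd, rtol=0, atol=0), (
            "looic must equal -2*elpd identically"
        )


def psis_loo(loglik: np.ndarray, name: str = "") -> LooResult:
    """PSIS-LOO from a pointwise log-likelihood array.

    Parameters
    ----------
    loglik : array (n_draws, n_obs) of per-draw, per-observation log
        likelihoods.

    Returns
    -------
    LooResult with a warning attached when more than 1% of the Pareto-k
    diagnostics exceed 0.7 (unreliable tail fits).
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik must be 2-D (n_draws, n_obs)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik contains non-finite values")
    n_draws, n_obs = ll.shape

    if n_draws >= MIN_DRAWS_FOR_PSIS:
        import arviz as az

        # az.psislw expects (n_obs, n_draws) raw log importance weights
        lw, k = az.psislw(-ll.T)
        lw = np.asarray(lw)
        k = np.asarray(k, dtype=float)
        pointwise = logsumexp(ll.T + lw, axis=1)
    else:
        pointwise = logsumexp(ll, axis=0) - np.log(n_draws)
        k = np.zeros(n_obs)

    elpd = float(pointwise.sum())
    se = (
        float(np.sqrt(n_obs) * np.std(pointwise, ddof=1)) if n_obs > 1 else 0.0
    )
    warns = []
    frac_bad = float(np.mean(k > 0.7))
    if frac_bad > 0.01:
        msg = (
            f"{100 * frac_bad:.1f}% of Pareto-k diagnostics exceed 0.7; "
            "the PSIS-LOO estimate may be unreliable"
        )
        warns.append(msg)
        _warnings.warn(msg, stacklevel=2)
    return LooResult(
        elpd=elpd,
        se=se,
        looic=-2.0 * elpd,
        pareto_k=k,
        pointwise_elpd=pointwise,
        n_obs=n_obs,
        n_draws=n_draws,
        name=name,
        warnings=warns,
    )


def compare_models(results) -> pd.DataFrame:
    """Rank LooResults by LOOIC (ascending = best first).

    Accepts a list of LooResult or a dict name -> LooResult, all computed on
    the same observations. Reports each model's elpd/LOOIC and the pairwise
    difference to the best model with the paired standard error
    sqrt(n) * sd(elpd_i difference).
    """
    if isinstance(results, dict):
        items = [(k, v) for k, v in results.items()]
    else:
        items = [(r.name or f"model{i}", r) for i, r in enumerate(results)]
    if not items:
        raise ValueError("no results to compare")
    n_obs = {r.n_obs for _, r in items}
    if len(n_obs) != 1:
        raise ValueError(
            f"results cover different observation counts: {sorted(n_obs)}"
        )
    items = sorted(items, key=lambda kv: kv[1].looic)
    best = items[0][1]
    rows = []
    for name, r in items:
        d = best.pointwise_elpd - r.pointwise_elpd
        if r is best or r.n_obs < 2:
            se_diff = 0.0
        else:
            se_diff = float(np.sqrt(r.n_obs) * np.std(d, ddof=1))
        rows.append(
            {
                "model": name,
                "looic": r.looic,
                "elpd": r.elpd,
                "se": r.se,
                "delta_looic": r.looic - best.looic,
                "se_delta": 2.0 * se_diff,
            }
        )
    return pd.DataFrame(rows)
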