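"""Hierarchical Bayesian estimation of the RW and lazy-Kalman learners.

Model
-----
For each subject s and parameter p, the individual value is

    theta_ps = link_p(mu_p + zeta_p * nu_ps)      (non-centered)

with link_p the standard-normal CDF for (0,1)-bounded parameters (learning
rate, gain-bias) and exp for positive ones (inverse temperature, variances).
Priors: mu_alpha ~ N(-1,1), mu_tau ~ N(0,1), mu_innovation ~ N(0,1),
mu_initial ~ N(2,1), mu_eta ~ N(1,1); zeta_p ~ Half-Normal(0,1);
nu_ps ~ N(0,1). The likelihood is the per-trial categorical choice rule of
:mod:`bitrl.learning`.

Sampling
--------
The posterior is sampled with an affine-invariant / differential-evolution
ensemble (emcee), initialized in a small ball around the MAP found by L-BFGS
with batched finite-difference gradients. The ensemble is split into
pseudo-chains for split-R-hat and ESS diagnostics (arviz). A centered
parameterization (theta_ps = link_p(phi_ps), phi_ps ~ N(mu_p, zeta_p)) is
available for cross-checks; both target the same posterior.

Pointwise log-likelihoods (one entry per subject-trial) are recomputed for
the retained draws and feed PSIS-LOO model comparison (:mod:`bitrl.loo`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .cohort import Cohort, PARAM_NAMES, PARAM_TRANSFORMS, PRIOR_MU_MEAN
from .learning import normalize_reward, replay_loglik
from .loo import LooResult, psis_loo
from .task import TaskConfig, default_config

__all__ = [
    "McmcConfig",
    "HierarchicalModel",
    "HierarchicalResults",
    "RecoveryReport",
    "fit_hierarchical",
    "recover_parameters",
    "summarize_posterior",
]

# bound on the unconstrained scale before exp() to keep the likelihood finite
_CLIP = 30.0


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    chains : pseudo-chain count for split diagnostics (>= 2).
    warmup : discarded ensemble steps.
    draws : retained posterior draws per pseudo-chain.
    thin : ensemble-step spacing between retained draws.
    seed : seed for initialization jitter and the ensemble moves.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("need >= 2 chains for split diagnostics")
        if min(self.warmup, self.draws, self.thin) < 1:
            raise ValueError("warmup, draws and thin must be positive")


def _link(name: str, x: np.ndarray) -> np.ndarray:
    if PARAM_TRANSFORMS[name] == "probit":
        return ndtr(x)
    return np.exp(np.clip(x, -_CLIP, _CLIP))


class HierarchicalModel:
    """Hierarchical model of a cohort's choice data under one learner.

    Parameters
    ----------
    sessions : list of Session, all with the same trial count.
    task : TaskConfig the sessions were played on.
    model : "rw" or "kl".
    rule : choice rule, "logit" (default) or "softmax".
    parameterization : "noncentered" (default) or "centered".
    """

    def __init__(
        self,
        sessions,
        task: Optional[TaskConfig] = None,
        model: str = "kl",
        rule: str = "logit",
        parameterization: str = "noncentered",
    ):
        if model not in PARAM_NAMES:
            raise ValueError(f"unknown model {model!r}")
        if parameterization not in ("noncentered", "centered"):
            raise ValueError(f"unknown parameterization {parameterization!r}")
        if len(sessions) < 2:
            raise ValueError("hierarchical fit needs >= 2 subjects")
        lengths = {s.n_trials for s in sessions}
        if len(lengths) != 1:
            raise ValueError(f"sessions differ in length: {sorted(lengths)}")
        self.task = task or default_config()
        self.model = model
        self.rule = rule
        self.parameterization = parameterization
        self.subject_ids = [s.subject_id for s in sessions]
        self.choices = np.stack([s.option for s in sessions])
        self.rewards = normalize_reward(
            np.stack([s.reward for s in sessions]), self.task
        )
        self.param_names = PARAM_NAMES[model]
        self.n_params = len(self.param_names)
        self.n_subjects = len(sessions)
        self.n_trials = int(self.choices.shape[1])
        self.prior_mu_mean = np.array(
            [PRIOR_MU_MEAN[p] for p in self.param_names]
        )
        # theta layout: [mu (P), log zeta (P), deviates (P*S)]
        self.ndim = 2 * self.n_params + self.n_params * self.n_subjects

    @classmethod
    def from_cohort(cls, cohort: Cohort, model: Optional[str] = None, **kw):
        return cls(
            cohort.sessions,
            task=cohort.task,
            model=model or cohort.model or "kl",
            **kw,
        )

    @classmethod
    def from_dataframe(
        cls, trials: pd.DataFrame, task: Optional[TaskConfig] = None, **kw
    ):
        from .io import sessions_from_frame

        return cls(sessions_from_frame(trials), task=task, **kw)

    # -- posterior ---------------------------------------------------------
    def _unpack(self, theta: np.ndarray):
        P, S = self.n_params, self.n_subjects
        mu = theta[:, :P]
        log_zeta = np.clip(theta[:, P : 2 * P], -_CLIP, _CLIP)
        dev = theta[:, 2 * P :].reshape(-1, P, S)
        return mu, log_zeta, dev

    def constrained_params(self, theta: np.ndarray) -> dict:
        """Individual parameters on their natural scales, per draw.

        theta : (W, ndim) -> dict name -> (W, S).
        """
        theta = np.atleast_2d(theta)
        mu, log_zeta, dev = self._unpack(theta)
        zeta = np.exp(log_zeta)
        out = {}
        for j, name in enumerate(self.param_names):
            if self.parameterization == "noncentered":
                x = mu[:, j, None] + zeta[:, j, None] * dev[:, j, :]
            else:
                x = dev[:, j, :]
            out[name] = _link(name, x)
        return out

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        mu, log_zeta, dev = self._unpack(theta)
        zeta = np.exp(log_zeta)
        lp = -0.5 * np.sum((mu - self.prior_mu_mean) ** 2, axis=1)
        # Half-Normal(0,1) on zeta, with the log-scale Jacobian
        lp += np.sum(-0.5 * zeta**2 + log_zeta, axis=1)
        if self.parameterization == "noncentered":
            lp += -0.5 * np.sum(dev**2, axis=(1, 2))
        else:
            z = (dev - mu[:, :, None]) / zeta[:, :, None]
            lp += np.sum(-0.5 * z**2 - log_zeta[:, :, None], axis=(1, 2))
        return lp

    def log_likelihood_pointwise(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial log-likelihood array (W, S, T) for draws theta."""
        params = self.constrained_params(np.atleast_2d(theta))
        return replay_loglik(
            self.choices, self.rewards, params, self.model, rule=self.rule
        )

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = self.log_prior(theta)
        ll = self.log_likelihood_pointwise(theta).sum(axis=(1, 2))
        out = lp + ll
        return np.where(np.isfinite(out), out, -np.inf)

    # -- estimation --------------------------------------------------------
    def _initial_point(self) -> np.ndarray:
        P, S = self.n_params, self.n_subjects
        x0 = np.zeros(self.ndim)
        x0[:P] = self.prior_mu_mean
        x0[P : 2 * P] = np.log(0.5)
        if self.parameterization == "centered":
            x0[2 * P :] = np.tile(self.prior_mu_mean[:, None], (1, S)).ravel()
        return x0

    def map_estimate(self, maxiter: int = 300) -> np.ndarray:
        """Posterior mode via L-BFGS with batched central-difference
        gradients (one vectorized likelihood call per gradient)."""
        eye = np.eye(self.ndim)
        eps = 1e-5

        def neg_logpost(x):
            return -float(self.log_posterior(x[None, :])[0])

        def grad(x):
            pts = np.concatenate([x + eps * eye, x - eps * eye])
            vals = -self.log_posterior(pts)
            return (vals[: self.ndim] - vals[self.ndim :]) / (2 * eps)

        res = minimize(
            neg_logpost,
            self._initial_point(),
            jac=grad,
            method="L-BFGS-B",
            options={"maxiter": maxiter},
        )
        return res.x

    def fit(self, mcmc: Optional[McmcConfig] = None) -> "HierarchicalResults":
        """Sample the posterior and package draws, pointwise log-likelihoods
        and convergence diagnostics."""
        import emcee

        mcmc = mcmc or McmcConfig()
        rng = np.random.default_rng(mcmc.seed)
        xmap = self.map_estimate()
        # a multiple of 2*chains that is at least 2*ndim+2, so the ensemble
        # splits evenly into pseudo-chains and red/blue halves
        base = max(2 * self.ndim + 2, 8 * mcmc.chains)
        step = 2 * mcmc.chains
        nwalkers = ceil(base / step) * step
        init = xmap[None, :] + 0.05 * rng.standard_normal((nwalkers, self.ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers,
            self.ndim,
            self.log_posterior,
            vectorize=True,
            moves=[
                (emcee.moves.DEMove(), 0.8),
                (emcee.moves.DESnookerMove(), 0.2),
            ],
        )
        state = emcee.State(
            init, random_state=np.random.RandomState(mcmc.seed).get_state()
        )
        state = sampler.run_mcmc(state, mcmc.warmup, progress=False)
        sampler.reset()
        n_keep_steps = max(ceil(mcmc.chains * mcmc.draws / nwalkers), 1)
        sampler.run_mcmc(state, n_keep_steps * mcmc.thin, progress=False)
        chain = sampler.get_chain(thin=mcmc.thin)  # (steps, walkers, ndim)
        accept = float(np.mean(sampler.acceptance_fraction))

        # walkers -> pseudo-chains: (chains, draws_per_chain, ndim)
        steps, _, _ = chain.shape
        per_chain = nwalkers // mcmc.chains
        arr = (
            chain.transpose(1, 0, 2)
            .reshape(mcmc.chains, per_chain * steps, self.ndim)
        )
        return HierarchicalResults(self, arr, mcmc, xmap, accept)


class HierarchicalResults:
    """Posterior draws, diagnostics and derived quantities of one fit."""

    def __init__(self, model, chain, mcmc, map_estimate, acceptance):
        self.model = model
        self.chain = chain  # (chains, draws, ndim)
        self.mcmc = mcmc
        self.map_estimate = map_estimate
        self.acceptance = acceptance
        P = model.n_params
        flat = chain.reshape(-1, model.ndim)
        self.mu = chain[:, :, :P]
        self.zeta = np.exp(np.clip(chain[:, :, P : 2 * P], -_CLIP, _CLIP))
        pars = model.constrained_params(flat)
        # name -> (chains, draws, subjects)
        self.params = {
            k: v.reshape(chain.shape[0], chain.shape[1], -1)
            for k, v in pars.items()
        }
        self._pointwise = None
        self._diagnostics = None

    # -- draws -------------------------------------------------------------
    @property
    def param_names(self):
        return self.model.param_names

    def param_draws(self, name: str) -> np.ndarray:
        """Flattened draws (n_draws_total, n_subjects) for one parameter."""
        v = self.params[name]
        return v.reshape(-1, v.shape[-1])

    @property
    def pointwise_loglik(self) -> np.ndarray:
        """(n_draws_total, n_subjects * n_trials), subject-major; the LOO
        observation unit is the subject-trial."""
        if self._pointwise is None:
            flat = self.chain.reshape(-1, self.model.ndim)
            ll = self.model.log_likelihood_pointwise(flat)
            self._pointwise = ll.reshape(ll.shape[0], -1)
        return self._pointwise

    # -- diagnostics -------------------------------------------------------
    def diagnostics(self) -> dict:
        """Split-R-hat and bulk ESS of the group-level parameters."""
        if self._diagnostics is None:
            import arviz as az

            names = self.model.param_names
            data = {f"mu_{p}": self.mu[:, :, j] for j, p in enumerate(names)}
            data.update(
                {f"zeta_{p}": self.zeta[:, :, j] for j, p in enumerate(names)}
            )
            idata = az.from_dict(posterior=data)
            rhat = az.rhat(idata)
            ess = az.ess(idata)
            self._diagnostics = {
                "rhat": {k: float(rhat[k].values) for k in data},
                "ess": {k: float(ess[k].values) for k in data},
                "acceptance": self.acceptance,
            }
        return self._diagnostics

    @property
    def converged(self) -> bool:
        """True when every group-level split-R-hat <= 1.1 and ESS >= 100."""
        d = self.diagnostics()
        rhats = np.array(list(d["rhat"].values()))
        esss = np.array(list(d["ess"].values()))
        rhats = rhats[np.isfinite(rhats)]
        esss = esss[np.isfinite(esss)]
        return bool(np.all(rhats <= 1.1) and np.all(esss >= 100))

    # -- summaries ---------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """One row per group-level and per individual parameter: posterior
        mean, median, central 90% interval, and (group level) R-hat/ESS."""
        d = self.diagnostics()
        rows = []

        def _row(name, draws, rhat=np.nan, ess=np.nan):
            q5, q50, q95 = np.percentile(draws, [5, 50, 95])
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(draws)),
                    "median": float(q50),
                    "q5": float(q5),
                    "q95": float(q95),
                    "rhat": rhat,
                    "ess": ess,
                }
            )

        names = self.model.param_names
        for j, p in enumerate(names):
            # group location reported on the constrained scale
            _row(
                f"group_{p}",
                _link(p, self.mu[:, :, j].ravel()),
                d["rhat"][f"mu_{p}"],
                d["ess"][f"mu_{p}"],
            )
            _row(
                f"zeta_{p}",
                self.zeta[:, :, j].ravel(),
                d["rhat"][f"zeta_{p}"],
                d["ess"][f"zeta_{p}"],
            )
        for j, p in enumerate(names):
            draws = self.param_draws(p)
            for s, sid in enumerate(self.model.subject_ids):
                _row(f"{p}[{sid}]", draws[:, s])
        return pd.DataFrame(rows)

    def subject_posterior_means(self) -> pd.DataFrame:
        out = {"subject_id": self.model.subject_ids}
        for p in self.model.param_names:
            out[p] = self.param_draws(p).mean(axis=0)
        return pd.DataFrame(out)

    def loo(self, name: str = "") -> LooResult:
        return psis_loo(self.pointwise_loglik, name=name or self.model.model)


@dataclass
class RecoveryReport:
    """True-vs-recovered statistics per parameter: Pearson correlation of
    true values with posterior means, mean bias, RMSE, and coverage of the
    central 90% posterior intervals."""

    table: pd.DataFrame

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.set_index("parameter").loc[param]


def fit_hierarchical(
    cohort: Cohort,
    model: str = "kl",
    mcmc: Optional[McmcConfig] = None,
    by_group: bool = False,
    **kw,
):
    """Fit the hierarchy to a cohort; with ``by_group=True`` each
    sensation-seeking group (LSS/MSS/HSS) is fitted separately and a dict of
    results is returned."""
    if not by_group:
        return HierarchicalModel.from_cohort(cohort, model=model, **kw).fit(mcmc)
    out = {}
    for label in ("LSS", "MSS", "HSS"):
        idx = [
            i for i, s in enumerate(cohort.subjects) if s.group_label == label
        ]
        if len(idx) < 2:
            continue
        sub = Cohort(
            subjects=[cohort.subjects[i] for i in idx],
            sessions=[cohort.sessions[i] for i in idx],
            task=cohort.task,
            model=cohort.model,
        )
        out[label] = HierarchicalModel.from_cohort(sub, model=model, **kw).fit(
            mcmc
        )
    return out


def recover_parameters(cohort: Cohort, fit) -> RecoveryReport:
    """Compare a cohort's true generative parameters with the fit's
    posterior; requires the cohort to carry true parameters."""
    truths = cohort.true_params_frame()
    rows = []
    for p in fit.param_names:
        true = truths[p].to_numpy(dtype=float)
        draws = fit.param_draws(p)
        post_mean = draws.mean(axis=0)
        lo, hi = np.percentile(draws, [5, 95], axis=0)
        if np.std(true) == 0 or np.std(post_mean) == 0:
            corr = 1.0 if np.allclose(post_mean, true) else np.nan
        else:
            corr = float(np.corrcoef(true, post_mean)[0, 1])
        rows.append(
            {
                "parameter": p,
                "correlation": corr,
                "bias": float(np.mean(post_mean - true)),
                "rmse": float(np.sqrt(np.mean((post_mean - true) ** 2))),
                "coverage90": float(np.mean((true >= lo) & (true <= hi))),
            }
        )
    return RecoveryReport(table=pd.DataFrame(rows))


def summarize_posterior(fit: HierarchicalResults) -> pd.DataFrame:
    """Posterior summary table (mean, median, central 90% interval, R-hat,
    ESS) on the constrained scale."""
    return fit.summary()
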