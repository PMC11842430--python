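"""Synthetic cohorts: subjects, parameters, sensation-seeking scores, sessions.

Generates simulated participants for the Balloon Inflation Test. Individual
model parameters are drawn from the hierarchical structure used for fitting:
an unconstrained group location mu and scale zeta per parameter, a
standard-normal individual deviate nu, and a link function mapping
mu + zeta * nu onto the constrained scale — the standard-normal CDF (probit
inverse) for parameters bounded in (0, 1) (learning rate alpha, gain-bias
eta) and exp for positive parameters (inverse temperature tau, variances).

Default group locations are the hierarchical prior means (alpha: -1, tau: 0,
innovation variance: 0, initial variance: 2, eta: 1) and the default scale is
the half-normal(0, 1) prior mean sqrt(2/pi). Sensation-seeking totals emulate
the SSS-V instrument: normal with mean 99.63 and SD 13.23, truncated to the
instrument's possible range [40, 160] and rounded to integers.

An optional ``LinkSpec`` ties standardized SSS scores to parameters on the
unconstrained scale and generates a continuous reward-sensitivity proxy
(FRN-like: more negative = larger feedback response) for moderation tests.
The link is a testing device for the moderation pipeline, not a mechanistic
claim about how sensation seeking relates to learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

from .task import TaskConfig, default_config, sample_outcome
from .learning import (
    choice_probabilities,
    initial_state,
    kl_update,
    normalize_reward,
    rw_update,
)

__all__ = [
    "RWParams",
    "KLParams",
    "GroupHyper",
    "SubjectProfile",
    "Session",
    "Cohort",
    "LinkSpec",
    "default_hyper",
    "draw_subject_params",
    "simulate_sss_scores",
    "simulate_session",
    "simulate_cohort",
    "PARAM_NAMES",
    "PARAM_TRANSFORMS",
    "SSS_MEAN",
    "SSS_SD",
    "SSS_RANGE",
]

SSS_MEAN = 99.63
SSS_SD = 13.23
SSS_RANGE = (40, 160)  # 40 items scored 1..4

#: Parameter names per model, in canonical order.
PARAM_NAMES = {
    "rw": ("alpha", "tau"),
    "kl": ("innovation_var", "initial_var", "eta", "tau"),
}

#: Link from the unconstrained (mu + zeta*nu) scale to the parameter scale.
PARAM_TRANSFORMS = {
    "alpha": "probit",
    "eta": "probit",
    "tau": "exp",
    "innovation_var": "exp",
    "initial_var": "exp",
}

#: Group-location prior means (used as simulation defaults).
PRIOR_MU_MEAN = {
    "alpha": -1.0,
    "tau": 0.0,
    "innovation_var": 0.0,
    "initial_var": 2.0,
    "eta": 1.0,
}

#: Half-normal(0, 1) mean, the default group scale.
HALFNORMAL_MEAN = float(np.sqrt(2.0 / np.pi))


def _transform(name: str, x):
    if PARAM_TRANSFORMS[name] == "probit":
        return ndtr(x)
    return np.exp(x)


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner parameters: learning rate in (0,1), inverse
    temperature > 0."""

    alpha: float
    tau: float

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


@dataclass(frozen=True)
class KLParams:
    """Lazy-Kalman/Pearce-Hall parameters.

    innovation_var : assumed trial-to-trial diffusion of the latent mean.
    initial_var : initial posterior variance of every option; also the
        (constant) observation variance entering the gain.
    eta : gain-bias in (0,1); eta = 1 is the standard Pearce-Hall update,
        smaller values make the filter lazy.
    tau : inverse temperature, >= 0.
    """

    innovation_var: float
    initial_var: float
    eta: float
    tau: float

    def __post_init__(self):
        if self.innovation_var < 0 or self.initial_var < 0:
            raise ValueError("variances must be non-negative")
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")


@dataclass(frozen=True)
class GroupHyper:
    """Group-level location (mu) and non-negative scale (zeta) per parameter,
    on the unconstrained scale."""

    mu: dict
    zeta: dict

    def __post_init__(self):
        if set(self.mu) != set(self.zeta):
            raise ValueError("mu and zeta must cover the same parameters")
        if any(z < 0 for z in self.zeta.values()):
            raise ValueError("zeta must be non-negative")


def default_hyper(model: str) -> GroupHyper:
    """Simulation defaults: prior means for mu, half-normal mean for zeta."""
    names = PARAM_NAMES[model]
    return GroupHyper(
        mu={p: PRIOR_MU_MEAN[p] for p in names},
        zeta={p: HALFNORMAL_MEAN for p in names},
    )


@dataclass
class Session:
    """One subject's ordered trial records."""

    subject_id: Union[int, str]
    trial: np.ndarray  # 1..n_trials, contiguous
    option: np.ndarray  # 1..n_options
    inflation_pct: np.ndarray
    burst: np.ndarray  # bool
    reward: np.ndarray  # points
    rt_ms: Optional[np.ndarray] = None

    def __post_init__(self):
        self.trial = np.asarray(self.trial, dtype=int)
        self.option = np.asarray(self.option, dtype=int)
        self.inflation_pct = np.asarray(self.inflation_pct, dtype=float)
        self.burst = np.asarray(self.burst, dtype=bool)
        self.reward = np.asarray(self.reward, dtype=float)
        n = self.trial.size
        if not np.array_equal(self.trial, np.arange(1, n + 1)):
            raise ValueError(
                f"subject {self.subject_id}: trial indices must be 1..{n} contiguous"
            )
        for name in ("option", "inflation_pct", "burst", "reward"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"subject {self.subject_id}: ragged column {name}")

    @property
    def n_trials(self) -> int:
        return self.trial.size


@dataclass
class SubjectProfile:
    """Subject-level record: SSS total, group label, generative parameters
    (when simulated) and the optional reward-sensitivity proxy."""

    subject_id: Union[int, str]
    sss_score: Optional[float] = None
    group_label: Optional[str] = None
    params: Optional[Union[RWParams, KLParams]] = None
    rs_proxy: Optional[float] = None

    def __post_init__(self):
        if self.sss_score is not None and not (
            SSS_RANGE[0] <= self.sss_score <= SSS_RANGE[1]
        ):
            raise ValueError("sss_score outside the instrument range 40..160")


@dataclass
class Cohort:
    """Subjects plus their sessions and the task they played."""

    subjects: list
    sessions: list
    task: TaskConfig = field(default_factory=default_config)
    model: Optional[str] = None

    def __post_init__(self):
        if len(self.subjects) != len(self.sessions):
            raise ValueError("subjects and sessions must align")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_trials_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sessions:
            df = pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "trial": s.trial,
                    "option": s.option,
                    "inflation_pct": s.inflation_pct,
                    "burst": s.burst.astype(int),
                    "reward": s.reward,
                }
            )
            df["rt_ms"] = s.rt_ms if s.rt_ms is not None else np.nan
            rows.append(df)
        if not rows:
            return pd.DataFrame(
                columns=[
                    "subject_id",
                    "trial",
                    "option",
                    "inflation_pct",
                    "burst",
                    "reward",
                    "rt_ms",
                ]
            )
        return pd.concat(rows, ignore_index=True)

    def to_subjects_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "sss_score": s.sss_score,
                "group_label": s.group_label,
                "rs_proxy": s.rs_proxy,
            }
            if s.params is not None:
                for name in PARAM_NAMES[self.model or _model_of(s.params)]:
                    row[f"true_{name}"] = getattr(s.params, name)
            rows.append(row)
        cols = ["subject_id", "sss_score", "group_label", "rs_proxy"]
        return pd.DataFrame(rows, columns=None if rows else cols)

    def true_params_frame(self) -> pd.DataFrame:
        if any(s.params is None for s in self.subjects):
            raise ValueError("cohort does not carry true generative parameters")
        model = self.model or _model_of(self.subjects[0].params)
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                **{
                    p: [getattr(s.params, p) for s in self.subjects]
                    for p in PARAM_NAMES[model]
                },
            }
        )


def _model_of(params) -> str:
    return "rw" if isinstance(params, RWParams) else "kl"


def _as_rng(randomness) -> np.random.Generator:
    if isinstance(randomness, np.random.Generator):
        return randomness
    return np.random.default_rng(randomness)


def draw_subject_params(
    hyper: GroupHyper, n: int, model: str, randomness
) -> list:
    """Draw ``n`` subjects' parameters under the non-centered hierarchy:
    parameter = transform(mu + zeta * nu) with nu ~ Normal(0, 1)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(randomness)
    names = PARAM_NAMES[model]
    cls = RWParams if model == "rw" else KLParams
    out = []
    for _ in range(n):
        vals = {}
        for p in names:
            nu = rng.standard_normal()
            vals[p] = float(_transform(p, hyper.mu[p] + hyper.zeta[p] * nu))
        out.append(cls(**vals))
    return out


def simulate_sss_scores(
    n: int,
    mean: float = SSS_MEAN,
    sd: float = SSS_SD,
    randomness=None,
    bounds: tuple = SSS_RANGE,
) -> np.ndarray:
    """Integer SSS totals from a truncated normal on the instrument range."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(randomness)
    lo, hi = bounds
    if sd == 0:
        scores = np.full(n, float(np.clip(mean, lo, hi)))
    else:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        scores = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(scores), lo, hi).astype(int)


def simulate_session(
    params,
    config: TaskConfig,
    model: str,
    randomness,
    rule: str = "logit",
    subject_id=0,
    rt_median_s: float = 1.0,
    rt_log_sd: float = 0.4,
) -> Session:
    """Simulate one full session of the task under an RW or KL learner.

    Each trial: choice probabilities from the current state, sample a choice,
    sample the balloon outcome, update the state. Reaction times are
    log-normal window dressing for the behavioral-metrics stage; they feed
    no model.
    """
    rng = _as_rng(randomness)
    n_trials = config.n_trials
    state = initial_state(model, params, n_options=config.n_options)
    option = np.empty(n_trials, dtype=int)
    burst = np.empty(n_trials, dtype=bool)
    reward = np.empty(n_trials)
    for t in range(n_trials):
        probs = choice_probabilities(state.values, params.tau, rule=rule)
        c = int(rng.choice(config.n_options, p=probs)) + 1
        outcome = sample_outcome(config, c, rng)
        option[t] = c
        burst[t] = outcome.burst
        reward[t] = outcome.reward
        r = float(normalize_reward(outcome.reward, config))
        if model == "rw":
            state = rw_update(state, c, r, params.alpha)
        else:
            state = kl_update(state, c, r, params)
    rt = 1000.0 * rt_median_s * np.exp(rt_log_sd * rng.standard_normal(n_trials))
    return Session(
        subject_id=subject_id,
        trial=np.arange(1, n_trials + 1),
        option=option,
        inflation_pct=np.asarray(config.inflation_pct)[option - 1],
        burst=burst,
        reward=reward,
        rt_ms=rt,
    )


@dataclass(frozen=True)
class LinkSpec:
    """Optional linear links from standardized SSS to the unconstrained
    parameter scale, and from a subject's feedback responsiveness to the
    reward-sensitivity proxy.

    param_slopes : dict parameter -> slope (per SD of SSS, unconstrained
        scale). Empty dict = independence.
    rs_slope : slope of rs_proxy on the standardized responsiveness score
        (the unconstrained innovation variance for KL, learning rate for RW).
        The proxy is sign-flipped (FRN-like: more negative = stronger
        feedback response).
    rs_noise_sd : SD of the proxy's additive noise.
    """

    param_slopes: dict = field(default_factory=dict)
    rs_slope: float = 0.0
    rs_noise_sd: float = 1.0


def simulate_cohort(
    n_subjects: int,
    hyper: Optional[GroupHyper] = None,
    model: str = "kl",
    link_spec: Optional[LinkSpec] = None,
    randomness=None,
    task: Optional[TaskConfig] = None,
    rule: str = "logit",
    assign_groups: bool = True,
) -> Cohort:
    """Simulate a full cohort: SSS scores, parameters, sessions, RS proxy.

    The whole pipeline is reproducible from one integer seed. With an
    all-zero ``link_spec`` the SSS scores are independent of everything else.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    hyper = hyper or default_hyper(model)
    link = link_spec or LinkSpec()
    task = task or default_config()
    names = PARAM_NAMES[model]
    cls = RWParams if model == "rw" else KLParams
    unknown = set(link.param_slopes) - set(names)
    if unknown:
        raise ValueError(f"link_spec names unknown parameters: {sorted(unknown)}")

    seq = np.random.SeedSequence(
        randomness if isinstance(randomness, (int, np.integer)) else None
    )
    if isinstance(randomness, np.random.Generator):
        seq = randomness.bit_generator.seed_seq.spawn(1)[0]
    rng_subj, rng_sess = [np.random.default_rng(s) for s in seq.spawn(2)]

    sss = simulate_sss_scores(n_subjects, randomness=rng_subj)
    z_sss = (sss - SSS_MEAN) / SSS_SD

    subjects, sessions = [], []
    resp_name = "innovation_var" if model == "kl" else "alpha"
    sess_rngs = [np.random.default_rng(s) for s in seq.spawn(max(n_subjects, 1))]
    for i in range(n_subjects):
        raw = {}
        for p in names:
            nu = rng_subj.standard_normal()
            raw[p] = (
                hyper.mu[p]
                + hyper.zeta[p] * nu
                + link.param_slopes.get(p, 0.0) * z_sss[i]
            )
        params = cls(**{p: float(_transform(p, raw[p])) for p in names})
        resp_z = (raw[resp_name] - hyper.mu[resp_name]) / max(
            hyper.zeta[resp_name], 1e-12
        )
        rs_proxy = float(
            -link.rs_slope * resp_z + link.rs_noise_sd * rng_subj.standard_normal()
        )
        session = simulate_session(
            params, task, model, sess_rngs[i], rule=rule, subject_id=i + 1
        )
        subjects.append(
            SubjectProfile(
                subject_id=i + 1,
                sss_score=int(sss[i]),
                params=params,
                rs_proxy=rs_proxy,
            )
        )
        sessions.append(session)

    cohort = Cohort(subjects=subjects, sessions=sessions, task=task, model=model)
    if assign_groups and n_subjects >= 3:
        from .behavior import assign_ss_groups

        labels = assign_ss_groups(np.array([s.sss_score for s in cohort.subjects]))
        for subj, lab in zip(cohort.subjects, labels):
            subj.group_label = lab
    return cohort
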