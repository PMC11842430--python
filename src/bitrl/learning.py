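"""Trial-level learning rules and choice likelihoods.

Two learners over the 9-option value vector V_t (initialized at 0):

* Rescorla-Wagner (RW): V_{t+1}(c) = V_t(c) + alpha * PE, with
  PE = R_t - V_t(c), only the chosen option updated.

* Lazy-Kalman / Pearce-Hall (KL): V_{t+1}(c) = V_t(c) + k_t * alpha_t * PE,
  where the Kalman gain k_t = (S_t + s_inno) / (S_t + s_inno + s_obs) tracks
  the posterior variance S_t of the chosen option's mean reward, and the
  dynamic learning rate follows the Pearce-Hall associability rule
  alpha_{t+1} = eta * |PE| + (1 - eta) * alpha_t. The gain-bias eta < 1 makes
  the filter "lazy" (slower effective learning). The observation variance is
  the initial-variance parameter held constant across trials, which also
  seeds S_1 for every option. Unchosen options keep their values but diffuse:
  S += s_inno per trial.

Choices follow a categorical distribution over Phi(tau * V_t) where Phi is
the elementwise inverse logit, normalized to a simplex (default rule), or a
standard softmax (``rule="softmax"``). tau = 0 gives uniform random choice.

Rewards are normalized to [0, 1] (division by the task's maximum reward)
inside all learning computations so |PE| <= 1 and the associability stays in
[0, 1]; the inverse temperature absorbs the scale change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import log_expit, logsumexp

from .task import TaskConfig

__all__ = [
    "LearnerState",
    "normalize_reward",
    "denormalize_reward",
    "rw_update",
    "pearce_hall_alpha",
    "kalman_gain",
    "kl_update",
    "choice_probabilities",
    "session_loglik",
    "replay_loglik",
    "initial_state",
    "INITIAL_ASSOCIABILITY",
]

#: Associability on trial 1 (maximal surprise at the start); configurable via
#: ``initial_state(alpha0=...)``.
INITIAL_ASSOCIABILITY = 1.0


@dataclass
class LearnerState:
    """Per-trial learner state.

    values : value estimate per option (unit reward scale), starts at 0.
    post_var : posterior variance per option (KL model only, else None).
    alpha_t : current Pearce-Hall associability, in [0, 1].
    k_t : Kalman gain applied on the last update, in [0, 1].
    """

    values: np.ndarray
    post_var: Optional[np.ndarray] = None
    alpha_t: float = INITIAL_ASSOCIABILITY
    k_t: float = 0.0

    def copy(self) -> "LearnerState":
        return LearnerState(
            values=self.values.copy(),
            post_var=None if self.post_var is None else self.post_var.copy(),
            alpha_t=self.alpha_t,
            k_t=self.k_t,
        )


def initial_state(
    model: str,
    params=None,
    n_options: int = 9,
    alpha0: float = INITIAL_ASSOCIABILITY,
) -> LearnerState:
    """Fresh learner state: values at 0; for the KL model the posterior
    variance of every option starts at the initial-variance parameter."""
    values = np.zeros(n_options)
    if model == "kl":
        if params is None:
            raise ValueError("KL initial state needs params (initial_var)")
        post_var = np.full(n_options, float(params.initial_var))
        return LearnerState(values=values, post_var=post_var, alpha_t=alpha0)
    if model == "rw":
        return LearnerState(values=values, alpha_t=alpha0)
    raise ValueError(f"unknown model {model!r}")


def normalize_reward(reward, config: TaskConfig):
    """Map a reward in points onto the unit scale (divide by the maximum)."""
    return np.asarray(reward, dtype=float) / config.max_reward


def denormalize_reward(reward, config: TaskConfig):
    """Inverse of :func:`normalize_reward`, for reporting."""
    return np.asarray(reward, dtype=float) * config.max_reward


def rw_update(
    state: LearnerState, choice: int, reward: float, alpha: float
) -> LearnerState:
    """Rescorla-Wagner delta-rule update of the chosen option (1-based).

    Returns a new state; unchosen values are untouched.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    new = state.copy()
    pe = reward - new.values[choice - 1]
    new.values[choice - 1] += alpha * pe
    return new


def pearce_hall_alpha(alpha_t: float, pe: float, eta: float) -> float:
    """Associability update: eta * |PE| + (1 - eta) * alpha_t."""
    return eta * abs(pe) + (1.0 - eta) * alpha_t


def kalman_gain(post_var_i: float, innovation_var: float, obs_var: float) -> float:
    """Kalman gain (S + s_inno) / (S + s_inno + s_obs), in [0, 1]."""
    num = post_var_i + innovation_var
    den = num + obs_var
    if den <= 0:
        raise ZeroDivisionError(
            "degenerate gain: posterior, innovation and observation "
            "variances are all zero"
        )
    return num / den


def kl_update(
    state: LearnerState, choice: int, reward: float, params
) -> LearnerState:
    """Lazy-Kalman / Pearce-Hall update of the chosen option (1-based).

    The chosen option's value moves by gain x associability x PE; its
    posterior variance contracts to (1 - k)(S + s_inno) while every unchosen
    option's variance diffuses by +s_inno. The associability then follows the
    Pearce-Hall rule with gain-bias eta.
    """
    new = state.copy()
    c = choice - 1
    pe = reward - new.values[c]
    k = kalman_gain(new.post_var[c], params.innovation_var, params.initial_var)
    new.values[c] += k * new.alpha_t * pe
    new.post_var = new.post_var + params.innovation_var
    new.post_var[c] *= 1.0 - k
    new.alpha_t = pearce_hall_alpha(new.alpha_t, pe, params.eta)
    new.k_t = k
    return new


def choice_probabilities(
    values: np.ndarray, tau: float, rule: str = "logit"
) -> np.ndarray:
    """Probability of choosing each option given the current values.

    rule="logit" (default): elementwise inverse-logit of tau*values,
    normalized to sum to 1 — the categorical form. Not invariant to adding a
    constant to all values. rule="softmax": standard softmax, shift-invariant.
    tau=0 yields the uniform distribution under both rules.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    v = np.asarray(values, dtype=float)
    if rule == "logit":
        logf = log_expit(tau * v)
    elif rule == "softmax":
        logf = tau * v
    else:
        raise ValueError(f"unknown choice rule {rule!r}")
    return np.exp(logf - logsumexp(logf))


def session_loglik(
    session,
    params,
    model: str,
    config: TaskConfig,
    rule: str = "logit",
) -> tuple[float, np.ndarray]:
    """Log-likelihood of a session under RW or KL parameters.

    Replays the session deterministically, accumulating the log probability
    of each realized choice under the evolving learner state. Returns the
    total and the per-trial vector (which sums to the total).
    """
    options = np.asarray(session.option, dtype=int)
    if options.size == 0:
        raise ValueError("empty session")
    if np.any((options < 1) | (options > config.n_options)):
        raise ValueError("choice outside 1..n_options")
    rewards = normalize_reward(np.asarray(session.reward, dtype=float), config)
    state = initial_state(model, params, n_options=config.n_options)
    per_trial = np.empty(options.size)
    for t, (c, r) in enumerate(zip(options, rewards)):
        probs = choice_probabilities(state.values, params.tau, rule=rule)
        per_trial[t] = np.log(probs[c - 1])
        if model == "rw":
            state = rw_update(state, c, r, params.alpha)
        else:
            state = kl_update(state, c, r, params)
    return float(per_trial.sum()), per_trial


def replay_loglik(
    choices: np.ndarray,
    rewards: np.ndarray,
    params: dict,
    model: str,
    rule: str = "logit",
) -> np.ndarray:
    """Vectorized per-trial log-likelihood over parameter sets and subjects.

    This is the computational core of the hierarchical fit: it replays every
    subject's session simultaneously for a whole batch of parameter draws.

    Parameters
    ----------
    choices : int array (S, T), options 1..9.
    rewards : float array (S, T), already on the unit reward scale.
    params : dict of arrays, each broadcastable to shape (W, S) —
        RW: alpha, tau; KL: innovation_var, initial_var, eta, tau.
    model : "rw" or "kl".

    Returns
    -------
    loglik : array (W, S, T) of per-trial log choice probabilities.
    """
    choices = np.asarray(choices, dtype=int) - 1
    rewards = np.asarray(rewards, dtype=float)
    S, T = choices.shape
    n_opt = 9
    # params may be scalars, per-subject (S,) vectors, or full (W, S) arrays
    arrs = {k: np.asarray(v, dtype=float) for k, v in params.items()}
    W = max((a.shape[0] for a in arrs.values() if a.ndim == 2), default=1)
    bcast = {k: np.broadcast_to(a, (W, S)) for k, a in arrs.items()}
    tau = bcast["tau"]
    sub = np.arange(S)

    V = np.zeros((W, S, n_opt))
    if model == "rw":
        alpha = bcast["alpha"]
    elif model == "kl":
        s_inno = bcast["innovation_var"]
        s_obs = bcast["initial_var"]
        eta = bcast["eta"]
        Svar = np.empty((W, S, n_opt))
        Svar[:] = s_obs[:, :, None]
        alpha_t = np.full((W, S), INITIAL_ASSOCIABILITY)
    else:
        raise ValueError(f"unknown model {model!r}")

    out = np.empty((W, S, T))
    tauv = tau[:, :, None]
    for t in range(T):
        c = choices[:, t]
        r = rewards[:, t]
        u = tauv * V
        if rule == "logit":
            logf = log_expit(u)
        else:
            logf = u
        out[:, :, t] = logf[:, sub, c] - logsumexp(logf, axis=2)
        pe = r[None, :] - V[:, sub, c]
        if model == "rw":
            V[:, sub, c] += alpha * pe
        else:
            num = Svar[:, sub, c] + s_inno
            k = num / (num + s_obs)
            V[:, sub, c] += k * alpha_t * pe
            Svar += s_inno[:, :, None]
            Svar[:, sub, c] *= 1.0 - k
            alpha_t = eta * np.abs(pe) + (1.0 - eta) * alpha_t
    return out
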