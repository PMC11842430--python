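"""Balloon Inflation Test (BIT) environment.

The BIT is a single-shot variant of the Balloon Analogue Risk Task: on each of
60 trials the participant picks one of 9 inflation levels (10% .. 90%). Larger
inflations pay more points but burst with higher probability; a burst pays
nothing. In the canonical configuration the reward in points equals the
inflation percentage and the burst probability equals inflation/100, which
makes the expected value of option ``i``

    EV_i = reward_i * (1 - burst_prob_i)

a symmetric inverted-U over options, [9, 16, 21, 24, 25, 24, 21, 16, 9],
maximal at the 50% option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "TaskConfig",
    "TrialOutcome",
    "TaskConfigError",
    "default_config",
    "expected_values",
    "optimal_option",
    "sample_outcome",
    "CANONICAL_REWARD_SD",
]

#: Per-option reward standard deviations of the canonical task, stored as
#: printed constants. They are close to, but not equal to, the binomial
#: reward SD reward*sqrt(p*(1-p)) of the canonical reward/burst mapping, so
#: they are never recomputed.
CANONICAL_REWARD_SD = (3.12, 4.22, 4.83, 5.16, 5.27, 5.16, 4.83, 4.22, 3.12)


class TaskConfigError(ValueError):
    """Raised for invalid task configurations."""


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome of one balloon inflation: burst flag and reward in points."""

    burst: bool
    reward: float

    def __post_init__(self) -> None:
        if self.reward < 0:
            raise TaskConfigError("reward must be non-negative")
        if self.burst and self.reward != 0:
            raise TaskConfigError("a burst trial pays 0 points")


@dataclass(frozen=True)
class TaskConfig:
    """The 9-option BIT environment.

    Options are indexed 1..n_options throughout the package (matching the
    value vector V_t(1)..V_t(9)).

    Parameters
    ----------
    inflation_pct : array of inflation percentages, strictly increasing.
    reward_points : points paid for a successful inflation of each option.
    burst_prob : burst probability of each option, in [0, 1], non-decreasing.
    reward_sd : per-option reward SD constants (reporting only; no model
        consumes them).
    n_trials : trials per session (default 60).
    """

    inflation_pct: tuple = tuple(range(10, 100, 10))
    reward_points: tuple = tuple(range(10, 100, 10))
    burst_prob: tuple = tuple(i / 100 for i in range(10, 100, 10))
    reward_sd: Optional[tuple] = CANONICAL_REWARD_SD
    n_trials: int = 60

    def __post_init__(self) -> None:
        inf = np.asarray(self.inflation_pct, dtype=float)
        rew = np.asarray(self.reward_points, dtype=float)
        prob = np.asarray(self.burst_prob, dtype=float)
        if not (inf.size == rew.size == prob.size):
            raise TaskConfigError("option vectors must have equal length")
        if inf.size < 1:
            raise TaskConfigError("need at least one option")
        if np.any(np.diff(inf) <= 0):
            raise TaskConfigError("inflation_pct must be strictly increasing")
        if np.any((prob < 0) | (prob > 1)):
            raise TaskConfigError("burst_prob entries must lie in [0, 1]")
        if np.any(np.diff(prob) < 0):
            raise TaskConfigError("burst_prob must be non-decreasing")
        if np.any(rew < 0):
            raise TaskConfigError("reward_points must be non-negative")
        if self.reward_sd is not None and len(self.reward_sd) != inf.size:
            raise TaskConfigError("reward_sd length mismatch")
        if self.n_trials < 1:
            raise TaskConfigError("n_trials must be positive")
        # freeze as tuples so the config is hashable
        object.__setattr__(self, "inflation_pct", tuple(inf))
        object.__setattr__(self, "reward_points", tuple(rew))
        object.__setattr__(self, "burst_prob", tuple(prob))

    @property
    def n_options(self) -> int:
        return len(self.inflation_pct)

    @property
    def expected_value(self) -> np.ndarray:
        return expected_values(self)

    @property
    def max_reward(self) -> float:
        return float(max(self.reward_points))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "inflation_pct": [float(x) for x in self.inflation_pct],
            "reward_points": [float(x) for x in self.reward_points],
            "burst_prob": [float(x) for x in self.burst_prob],
            "reward_sd": (
                [float(x) for x in self.reward_sd] if self.reward_sd else None
            ),
            "n_trials": int(self.n_trials),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        """Build a config from a dict; omitted keys fall back to defaults."""
        kwargs = {}
        for key in ("inflation_pct", "reward_points", "burst_prob", "reward_sd"):
            if d.get(key) is not None:
                kwargs[key] = tuple(d[key])
        if d.get("n_trials") is not None:
            kwargs["n_trials"] = int(d["n_trials"])
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_config() -> TaskConfig:
    """The canonical 9-option task: rewards equal the inflation percentage,
    burst probability equals inflation/100, 60 trials per session."""
    return TaskConfig()


def expected_values(config: TaskConfig) -> np.ndarray:
    """Expected value in points of each option: reward x survival probability."""
    rew = np.asarray(config.reward_points, dtype=float)
    prob = np.asarray(config.burst_prob, dtype=float)
    # round away binary-fraction noise (e.g. 30*0.7) so the canonical task
    # reproduces its printed utilities exactly
    return np.round(rew * (1.0 - prob), 12)


def optimal_option(config: TaskConfig) -> tuple[int, float]:
    """Index (1-based) and inflation percentage of the EV-maximal option.

    Ties are broken toward the lower-risk (smaller) option, i.e. the first
    argmax.
    """
    ev = expected_values(config)
    idx = int(np.argmax(ev))  # np.argmax returns the first maximum
    return idx + 1, float(config.inflation_pct[idx])


def sample_outcome(
    config: TaskConfig, option: int, rng: np.random.Generator
) -> TrialOutcome:
    """Sample one trial outcome for a 1-based ``option``.

    The balloon bursts with probability ``burst_prob[option]``; a burst pays
    0 points, otherwise the option's full reward is paid.
    """
    if not 1 <= option <= config.n_options:
        raise IndexError(
            f"option {option} outside 1..{config.n_options}"
        )
    p = config.burst_prob[option - 1]
    burst = bool(rng.random() < p)
    reward = 0.0 if burst else float(config.reward_points[option - 1])
    return TrialOutcome(burst=burst, reward=reward)
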