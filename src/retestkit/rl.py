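"""Q-learning on a probabilistic reversal task: simulator and likelihood.

Two options A and B; the chosen option's action value moves toward the
binary outcome with learning rate alpha, the unchosen value is unchanged,
and choice follows a softmax on the value difference with inverse
temperature beta.  A low beta means near-random choice and therefore poor
identifiability of alpha — the mechanism behind the low-precision group in
the reliability simulations.

Estimation works on the transformed scale (logit alpha, log beta), which
unbounds both parameters and is where the Gaussian group-level priors live.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import _kernels

__all__ = [
    "RLParams",
    "TaskConfig",
    "ChoiceData",
    "q_update",
    "choice_prob",
    "simulate_session",
    "negloglik",
    "choice_data_to_frame",
    "choice_data_from_frame",
]


@dataclass(frozen=True)
class RLParams:
    """Q-learning parameters: learning rate alpha in (0,1), inverse temperature beta >= 0."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    @property
    def alpha_logit(self) -> float:
        return float(logit(self.alpha))

    @property
    def beta_log(self) -> float:
        return float(np.log(self.beta))

    @classmethod
    def from_transformed(cls, alpha_logit: float, beta_log: float) -> "RLParams":
        return cls(float(expit(alpha_logit)), float(np.exp(beta_log)))


@dataclass(frozen=True)
class TaskConfig:
    """Probabilistic reversal task.

    The better option pays with probability ``p_good``, the worse with
    ``p_bad``; identities swap at each 1-based trial index in
    ``reversal_trials`` (the swap takes effect from that trial on).  Defaults:
    200 trials, 0.8/0.2 reward probabilities, a reversal every 50 trials.
    """

    n_trials: int = 200
    p_good: float = 0.8
    p_bad: float = 0.2
    reversal_trials: tuple[int, ...] = (51, 101, 151)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bad < self.p_good <= 1.0:
            raise ValueError("need 0 <= p_bad < p_good <= 1")
        rev = self.reversal_trials
        if any(r2 <= r1 for r1, r2 in zip(rev, rev[1:])):
            raise ValueError("reversal trials must be strictly increasing")
        if rev and not (1 <= rev[0] and rev[-1] <= self.n_trials):
            raise ValueError("reversal trials must lie within [1, n_trials]")

    def good_is_a(self) -> np.ndarray:
        """Per-trial indicator: 1 where option A is the better option."""
        good = np.ones(self.n_trials, dtype=np.int64)
        flip = 1
        prev = 0
        for r in self.reversal_trials:
            good[prev : r - 1] = flip
            flip = 1 - flip
            prev = r - 1
        good[prev:] = flip
        return good


@dataclass
class ChoiceData:
    """One individual-session of trial-level data (choices 0=A, 1=B; outcomes 0/1)."""

    choices: np.ndarray
    outcomes: np.ndarray
    session: str = "T1"
    individual: int = 0

    def __post_init__(self) -> None:
        self.choices = np.ascontiguousarray(self.choices, dtype=np.int64)
        self.outcomes = np.ascontiguousarray(self.outcomes, dtype=np.int64)
        if self.choices.shape != self.outcomes.shape:
            raise ValueError("choices and outcomes must have equal length")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be binary")
        if not np.isin(self.choices, (0, 1)).all():
            raise ValueError("choices must be 0 (A) or 1 (B)")

    @property
    def n_trials(self) -> int:
        return int(self.choices.shape[0])


def q_update(q: tuple[float, float], choice: int, outcome: float, alpha: float):
    """One prediction-error update: chosen value moves toward the outcome."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    q0, q1 = q
    if choice == 0:
        return (q0 + alpha * (outcome - q0), q1)
    return (q0, q1 + alpha * (outcome - q1))


def choice_prob(q: tuple[float, float], beta: float) -> float:
    """Softmax probability of choosing option A given the value pair."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return float(expit(beta * (q[0] - q[1])))


def simulate_session(
    params: RLParams,
    task: TaskConfig = TaskConfig(),
    seed: int = 0,
    session: str = "T1",
    individual: int = 0,
) -> ChoiceData:
    """Simulate one session of the reversal task (bit-reproducible per seed)."""
    rng = np.random.default_rng(seed)
    u = rng.random((2, task.n_trials))
    choices, outcomes = _kernels.simulate_core(
        params.alpha, params.beta, task.good_is_a(), task.p_good, task.p_bad, u[0], u[1]
    )
    return ChoiceData(choices, outcomes, session=session, individual=individual)


def negloglik(params: RLParams, data: ChoiceData) -> float:
    """Negative log-likelihood of a session under the Q-learning model."""
    if params.alpha in (0.0, 1.0) or params.beta == 0.0:
        # boundary values are valid for the likelihood even though the
        # transformed scale cannot represent them
        return float(_nll_natural(params.alpha, params.beta, data))
    return float(
        _kernels.nll_session(params.alpha_logit, params.beta_log, data.choices, data.outcomes)
    )


def _nll_natural(alpha: float, beta: float, data: ChoiceData) -> float:
    q = (0.5, 0.5)
    total = 0.0
    for c, r in zip(data.choices, data.outcomes):
        p_a = choice_prob(q, beta)
        p = p_a if c == 0 else 1.0 - p_a
        total -= np.log(p)
        q = q_update(q, int(c), float(r), alpha)
    return total


def choice_data_to_frame(sessions: list[ChoiceData]) -> pd.DataFrame:
    """Long-format export: id, session, trial (1-based), choice (A/B), outcome."""
    frames = []
    for d in sessions:
        frames.append(
            pd.DataFrame(
                {
                    "id": d.individual,
                    "session": d.session,
                    "trial": np.arange(1, d.n_trials + 1),
                    "choice": np.where(d.choices == 0, "A", "B"),
                    "outcome": d.outcomes,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def choice_data_from_frame(frame: pd.DataFrame) -> list[ChoiceData]:
    out = []
    for (ind, sess), grp in frame.groupby(["id", "session"], sort=True):
        grp = grp.sort_values("trial")
        out.append(
            ChoiceData(
                (grp["choice"].to_numpy() == "B").astype(np.int64),
                grp["outcome"].to_numpy(dtype=np.int64),
                session=str(sess),
                individual=int(ind),
            )
        )
    return out
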