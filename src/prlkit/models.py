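"""Reinforcement-learning model family for probabilistic reversal learning.

The family contains six nested Q-learning models.  All share the
Rescorla–Wagner value update

    Q_{t+1}(c_t) = Q_t(c_t) + alpha * (r_t - Q_t(c_t)),

where ``c_t`` is the chosen stimulus and ``r_t`` in {0, 1} the reinforcement,
and a softmax (logistic) choice rule over the two on-screen stimuli whose
logit may be augmented with outcome-independent "stickiness" terms:

    P(left) = logistic( beta * (Q(left) - Q(right))
                        + kappa_stim * (I[prev stim == left stim]
                                        - I[prev stim == right stim])
                        + kappa_side * (I[prev side == left]
                                        - I[prev side == right]) ).

Models differ in which parameters are free: a single learning rate ``alpha``
versus separate reward/punishment rates (``alpha_rew``, ``alpha_pun``), and
the presence of stimulus stickiness ``kappa_stim`` and side stickiness
``kappa_side``.  Model 6 frees all five parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PARAM_NAMES = ("alpha_rew", "alpha_pun", "beta", "kappa_stim", "kappa_side")

#: transform of each natural parameter to the unconstrained (sampling) scale
PARAM_TRANSFORMS = {
    "alpha": "logit",
    "alpha_rew": "logit",
    "alpha_pun": "logit",
    "beta": "log",
    "kappa_stim": "identity",
    "kappa_side": "identity",
}


def to_unconstrained(name: str, value: float) -> float:
    """Map a natural-scale parameter value to the unconstrained scale."""
    kind = PARAM_TRANSFORMS[name]
    if kind == "logit":
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name}={value} must lie strictly in (0, 1)")
        return float(np.log(value) - np.log1p(-value))
    if kind == "log":
        if value <= 0.0:
            raise ValueError(f"{name}={value} must be positive")
        return float(np.log(value))
    return float(value)


def to_natural(name: str, value: float) -> float:
    """Inverse of :func:`to_unconstrained`."""
    kind = PARAM_TRANSFORMS[name]
    if kind == "logit":
        return float(1.0 / (1.0 + np.exp(-value)))
    if kind == "log":
        return float(np.exp(value))
    return float(value)


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of which parameters are free in one candidate model."""

    model_id: int
    split_learning_rates: bool
    use_stim_stickiness: bool
    use_side_stickiness: bool

    def __post_init__(self) -> None:
        if not 1 <= self.model_id <= 6:
            raise ValueError(f"model_id must be in 1..6, got {self.model_id}")

    @property
    def free_params(self) -> tuple[str, ...]:
        """Names of the free parameters, in canonical order.

        A shared learning rate is reported as ``alpha``; split rates as
        ``alpha_rew`` / ``alpha_pun``.
        """
        names: list[str] = (
            ["alpha_rew", "alpha_pun"] if self.split_learning_rates else ["alpha"]
        )
        names.append("beta")
        if self.use_stim_stickiness:
            names.append("kappa_stim")
        if self.use_side_stickiness:
            names.append("kappa_side")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def constrain(self, params: "ParameterSet") -> "ParameterSet":
        """Force parameters absent from this model to their null values."""
        out = params
        if not self.split_learning_rates:
            out = replace(out, alpha_pun=out.alpha_rew)
        if not self.use_stim_stickiness:
            out = replace(out, kappa_stim=0.0)
        if not self.use_side_stickiness:
            out = replace(out, kappa_side=0.0)
        return out


#: the six candidate models, keyed by model id
MODEL_REGISTRY: dict[int, ModelSpec] = {
    1: ModelSpec(1, split_learning_rates=False, use_stim_stickiness=False, use_side_stickiness=False),
    2: ModelSpec(2, split_learning_rates=False, use_stim_stickiness=True, use_side_stickiness=False),
    3: ModelSpec(3, split_learning_rates=False, use_stim_stickiness=False, use_side_stickiness=True),
    4: ModelSpec(4, split_learning_rates=False, use_stim_stickiness=True, use_side_stickiness=True),
    5: ModelSpec(5, split_learning_rates=True, use_stim_stickiness=False, use_side_stickiness=False),
    6: ModelSpec(6, split_learning_rates=True, use_stim_stickiness=True, use_side_stickiness=True),
}


def get_model(model_id: int) -> ModelSpec:
    try:
        return MODEL_REGISTRY[int(model_id)]
    except KeyError:
        raise KeyError(f"unknown model id {model_id}; registry holds {sorted(MODEL_REGISTRY)}") from None


@dataclass(frozen=True)
class ParameterSet:
    """Subject-level parameter values on the natural scale.

    ``alpha_rew``/``alpha_pun`` in [0, 1]; ``beta`` >= 0; stickiness
    parameters unbounded.  For models without split learning rates set
    ``alpha_pun == alpha_rew``.
    """

    alpha_rew: float
    alpha_pun: float
    beta: float
    kappa_stim: float = 0.0
    kappa_side: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha_rew", "alpha_pun"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0.0:
            raise ValueError(f"beta={self.beta} must be non-negative")
        for name in PARAM_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def single_alpha(cls, alpha: float, beta: float,
                     kappa_stim: float = 0.0, kappa_side: float = 0.0) -> "ParameterSet":
        return cls(alpha, alpha, beta, kappa_stim, kappa_side)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ParameterSet":
        return cls(*(float(v) for v in values))


@dataclass
class LearnerState:
    """Q-values and one-back choice history of a learner."""

    q_values: dict[str, float]
    prev_stim: Optional[str] = None
    prev_side: Optional[str] = None

    @classmethod
    def fresh(cls, stimuli: Sequence[str], q0: float = 0.5) -> "LearnerState":
        return cls(q_values={s: q0 for s in stimuli})


def update_q(state: LearnerState, choice_stim: str, choice_side: str, r: int,
             params: ParameterSet) -> LearnerState:
    """Apply one Rescorla–Wagner update to the chosen stimulus.

    The learning rate is ``alpha_rew`` after reward (r = 1) and ``alpha_pun``
    after punishment (r = 0); the unchosen stimulus is untouched.  Returns a
    new state with the one-back history advanced.
    """
    if r not in (0, 1):
        raise ValueError(f"reinforcement must be 0 or 1, got {r!r}")
    if choice_stim not in state.q_values:
        raise KeyError(f"choice {choice_stim!r} not among tracked stimuli")
    alpha = params.alpha_rew if r == 1 else params.alpha_pun
    q = dict(state.q_values)
    q[choice_stim] = q[choice_stim] + alpha * (r - q[choice_stim])
    return LearnerState(q_values=q, prev_stim=choice_stim, prev_side=choice_side)


def choice_probability(state: LearnerState, stim_left: str, stim_right: str,
                       params: ParameterSet) -> float:
    """Probability of choosing the left stimulus under the stickiness softmax.

    Stickiness indicators refer to the immediately preceding trial only and
    are zero when there is no history (first trial of a run).
    """
    q_l = state.q_values[stim_left]
    q_r = state.q_values[stim_right]
    x = params.beta * (q_l - q_r)
    if state.prev_stim is not None:
        x += params.kappa_stim * (
            (state.prev_stim == stim_left) - (state.prev_stim == stim_right)
        )
    if state.prev_side is not None:
        x += params.kappa_side * (
            (state.prev_side == "left") - (state.prev_side == "right")
        )
    return float(1.0 / (1.0 + np.exp(-x)))


def _pack_subject_trials(trials: pd.DataFrame,
                         reset_between_blocks: bool = True
                         ) -> dict[str, np.ndarray]:
    """Encode one subject's tidy trial log as flat integer arrays.

    Within each block the two stimuli are indexed 0/1 (lexicographic).
    Returns arrays: ``chosen`` (stimulus index), ``left`` (index of the
    left-hand stimulus), ``side`` (0 = left chosen), ``reward``, ``reset``
    (1 where the learner state re-initialises).  Carrying state across
    blocks (``reset_between_blocks=False``) requires a single stimulus pair
    shared by all blocks.
    """
    n = len(trials)
    chosen = np.empty(n, dtype=np.int64)
    left = np.empty(n, dtype=np.int64)
    side = np.empty(n, dtype=np.int64)
    reward = trials["reinforced"].to_numpy(dtype=np.int64)
    reset = np.zeros(n, dtype=np.int64)

    if not reset_between_blocks:
        pair = sorted(set(trials["stim_left"]) | set(trials["stim_right"]))
        if len(pair) != 2:
            raise ValueError(
                "carrying learner state across blocks requires a single "
                f"stimulus pair; found {len(pair)} distinct stimuli")

    blocks = trials["block"].to_numpy()
    prev_block = None
    stim_index: dict[str, int] = {}
    for i, (blk, sl, sr, cs, csd) in enumerate(
        zip(blocks, trials["stim_left"], trials["stim_right"],
            trials["choice_stim"], trials["choice_side"])
    ):
        if blk != prev_block:
            if reset_between_blocks or prev_block is None:
                pair = sorted({sl, sr})
                stim_index = {pair[0]: 0, pair[-1]: 1}
                reset[i] = 1
            prev_block = blk
        if cs not in (sl, sr):
            raise ValueError(
                f"choice_stim {cs!r} not among displayed stimuli at row {i}"
            )
        chosen[i] = stim_index[cs]
        left[i] = stim_index[sl]
        side[i] = 0 if csd == "left" else 1
    return {"chosen": chosen, "left": left, "side": side,
            "reward": reward, "reset": reset}


def sequence_log_likelihood(trials: pd.DataFrame, params: ParameterSet,
                            spec: ModelSpec, q0: float = 0.5,
                            reset_between_blocks: bool = True) -> float:
    """Log-likelihood of one subject's observed choice sequence.

    Trials must be sorted by (block, trial) and unique.  The learner state
    (Q-values and one-back history) is re-initialised at block boundaries by
    default, since each block used a fresh pair of stimuli.
    """
    key = trials[["block", "trial"]].to_numpy()
    order = np.lexsort((key[:, 1], key[:, 0]))
    if not np.array_equal(order, np.arange(len(trials))):
        raise ValueError("trials must be sorted by (block, trial)")
    if len(np.unique(key, axis=0)) != len(key):
        raise ValueError("duplicate (block, trial) rows")
    params = spec.constrain(params)
    packed = _pack_subject_trials(trials, reset_between_blocks)
    from ._likelihood import subject_loglik

    return float(
        subject_loglik(
            params.alpha_rew, params.alpha_pun, params.beta,
            params.kappa_stim, params.kappa_side,
            packed["chosen"], packed["left"], packed["side"],
            packed["reward"], packed["reset"], q0,
        )
    )
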