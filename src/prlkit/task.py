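"""Probabilistic reversal learning task: schedules, agents, synthetic cohorts.

The task presents two stimuli left/right; one (the CS+) is rewarded on 85%
of trials, the other (CS-) on 15%.  After 10-15 correct responses the
contingencies reverse.  "Correct" means choosing the CS+, regardless of the
probabilistic feedback actually delivered; by default correct responses are
counted cumulatively within a discrimination (``criterion_consecutive=True``
instead requires an unbroken streak, resetting on an incorrect choice).  A
block comprises 10 such discriminations (9 reversals); a block that
exhausts its trial budget mid-discrimination is truncated.

Synthetic cohorts mirror the study design: 18 controls, 18 gambling
disorder, 20 cocaine use disorder, behaviour generated by the five-parameter
winning model with subject parameters drawn from group-level distributions
on the unconstrained scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import (
    MODEL_REGISTRY,
    LearnerState,
    ModelSpec,
    ParameterSet,
    choice_probability,
    get_model,
    to_natural,
    update_q,
)

GROUPS = ("control", "gambling", "cud")

#: canonical column order of the tidy trial table (the interchange schema)
TRIAL_COLUMNS = (
    "subject_id", "group", "block", "trial", "stim_left", "stim_right",
    "correct_stim", "choice_stim", "choice_side", "reinforced",
    "reversal_onset",
)


class SchemaError(ValueError):
    """A trial table violates the interchange schema."""


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the reversal task.

    Defaults encode the study design: 85%/15% feedback contingencies,
    reversal after 10-15 correct responses, 3 blocks of 10 discriminations.
    A block ends when its last discrimination completes;
    ``trials_per_block`` is a safety budget after which an unfinished block
    is truncated.
    """

    reward_prob_cs_plus: float = 0.85
    reward_prob_cs_minus: float = 0.15
    criterion_min: int = 10
    criterion_max: int = 15
    criterion_consecutive: bool = False
    discriminations_per_block: int = 10
    n_blocks: int = 3
    trials_per_block: int = 360
    q0: float = 0.5
    reset_between_blocks: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reward_prob_cs_minus < self.reward_prob_cs_plus <= 1.0:
            raise ValueError(
                "need 0 <= reward_prob_cs_minus < reward_prob_cs_plus <= 1, got "
                f"{self.reward_prob_cs_minus}, {self.reward_prob_cs_plus}"
            )
        if not (1 <= self.criterion_min <= self.criterion_max):
            raise ValueError(
                f"need 1 <= criterion_min <= criterion_max, got "
                f"{self.criterion_min}, {self.criterion_max}"
            )
        for name in ("discriminations_per_block", "n_blocks", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def reversals_per_block(self) -> int:
        return self.discriminations_per_block - 1


@dataclass
class BlockSchedule:
    """Latent template for one block: stimuli, criteria, randomisation."""

    block: int
    stimuli: tuple[str, str]
    initial_cs_plus: str
    criteria: np.ndarray        # consecutive-correct criterion per discrimination
    left_stim_index: np.ndarray  # which stimulus appears on the left, per trial
    feedback_u: np.ndarray       # uniform draws deciding probabilistic feedback


def build_schedule(config: TaskConfig, rng_seed: int) -> list[BlockSchedule]:
    """Draw the latent per-block task templates.

    The reversal criterion for each discrimination is uniform on
    {criterion_min..criterion_max}; stimulus side is randomised
    independently per trial with p = 0.5.  Exactly
    ``discriminations_per_block - 1`` reversal events can occur per
    completed block.
    """
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    schedule = []
    for b in range(config.n_blocks):
        stimuli = (f"b{b}s0", f"b{b}s1")
        schedule.append(
            BlockSchedule(
                block=b,
                stimuli=stimuli,
                initial_cs_plus=stimuli[rng.integers(0, 2)],
                criteria=rng.integers(
                    config.criterion_min, config.criterion_max + 1,
                    size=config.discriminations_per_block,
                ),
                left_stim_index=rng.integers(0, 2, size=config.trials_per_block),
                feedback_u=rng.random(config.trials_per_block),
            )
        )
    return schedule


def simulate_agent(params: ParameterSet, spec: ModelSpec, config: TaskConfig,
                   rng_seed: int, subject_id: str = "sim",
                   group: str = "control") -> pd.DataFrame:
    """Simulate one agent through the full task; returns a tidy trial table.

    The agent chooses via the stickiness softmax, receives probabilistic
    feedback per the contingencies, and updates Q-values by the
    Rescorla–Wagner rule.  Deterministic given (config, params, seed).
    """
    params = spec.constrain(params)
    ss = np.random.SeedSequence(rng_seed)
    sched_ss, choice_ss = ss.spawn(2)
    schedule = build_schedule(config, _seed_int(sched_ss))
    rng = np.random.default_rng(choice_ss)

    rows: list[tuple] = []
    state: Optional[LearnerState] = None
    for blk in schedule:
        if state is None or config.reset_between_blocks:
            state = LearnerState.fresh(blk.stimuli, q0=config.q0)
        else:
            for s in blk.stimuli:
                state.q_values.setdefault(s, config.q0)
        cs_plus = blk.initial_cs_plus
        streak = 0
        disc = 0
        criterion = int(blk.criteria[disc])
        reversal_pending = False
        for t in range(config.trials_per_block):
            li = blk.left_stim_index[t]
            stim_left, stim_right = blk.stimuli[li], blk.stimuli[1 - li]
            p_left = choice_probability(state, stim_left, stim_right, params)
            chose_left = rng.random() < p_left
            choice_stim = stim_left if chose_left else stim_right
            choice_side = "left" if chose_left else "right"
            correct = choice_stim == cs_plus
            p_rew = (config.reward_prob_cs_plus if correct
                     else config.reward_prob_cs_minus)
            r = int(blk.feedback_u[t] < p_rew)
            rows.append((subject_id, group, blk.block, t, stim_left, stim_right,
                         cs_plus, choice_stim, choice_side, r,
                         int(reversal_pending)))
            reversal_pending = False
            state = update_q(state, choice_stim, choice_side, r, params)
            if correct:
                streak += 1
            elif config.criterion_consecutive:
                streak = 0
            if streak >= criterion:
                disc += 1
                if disc >= config.discriminations_per_block:
                    break  # block complete: all discriminations solved
                cs_plus = blk.stimuli[0] if cs_plus == blk.stimuli[1] else blk.stimuli[1]
                streak = 0
                criterion = int(blk.criteria[disc])
                reversal_pending = True
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return df


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``group_means`` / ``group_sds`` give, per group, the location and spread
    of subject parameters on the unconstrained scale (logit for learning
    rates, log for beta, identity for stickiness), in the order of
    ``generating_model.free_params``.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 18, "gambling": 18, "cud": 20})
    group_means: dict[str, tuple[float, ...]] = field(default_factory=dict)
    group_sds: dict[str, tuple[float, ...]] = field(default_factory=dict)
    generating_model: ModelSpec = field(
        default_factory=lambda: MODEL_REGISTRY[6])
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")
        k = self.generating_model.n_free
        means = dict(self.group_means)
        sds = dict(self.group_sds)
        for g in self.group_sizes:
            means.setdefault(g, _default_means_for(self.generating_model))
            sds.setdefault(g, _default_sds_for(self.generating_model))
            if len(means[g]) != k or len(sds[g]) != k:
                raise ValueError(
                    f"group {g!r}: expected {k} parameter values "
                    f"({self.generating_model.free_params})")
            if any(s < 0 for s in sds[g]):
                raise ValueError("group SDs must be >= 0")
        object.__setattr__(self, "group_means", means)
        object.__setattr__(self, "group_sds", sds)

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


# Cohort-level generative defaults on the unconstrained scale, in model-6
# parameter order (alpha_rew, alpha_pun, beta, kappa_stim, kappa_side).
# They correspond to natural-scale group medians alpha_rew ~ 0.40,
# alpha_pun ~ 0.30, beta ~ 3, kappa_stim ~ 0.25, kappa_side ~ 0.10 --
# magnitudes typical of stickiness-softmax fits to reversal learning.
DEFAULT_GROUP_MEANS: tuple[float, ...] = (
    -0.4055, -0.8473, 1.0986, 0.25, 0.10)
DEFAULT_GROUP_SDS: tuple[float, ...] = (0.5, 0.5, 0.4, 0.3, 0.3)

_DEFAULTS_BY_NAME = dict(zip(
    ("alpha_rew", "alpha_pun", "beta", "kappa_stim", "kappa_side"),
    zip(DEFAULT_GROUP_MEANS, DEFAULT_GROUP_SDS)))
_DEFAULTS_BY_NAME["alpha"] = _DEFAULTS_BY_NAME["alpha_rew"]


def _default_means_for(spec: ModelSpec) -> tuple[float, ...]:
    return tuple(_DEFAULTS_BY_NAME[n][0] for n in spec.free_params)


def _default_sds_for(spec: ModelSpec) -> tuple[float, ...]:
    return tuple(_DEFAULTS_BY_NAME[n][1] for n in spec.free_params)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0])


def _params_from_free(spec: ModelSpec, free_unconstrained: np.ndarray) -> ParameterSet:
    values = {"alpha_rew": 0.5, "alpha_pun": 0.5, "beta": 1.0,
              "kappa_stim": 0.0, "kappa_side": 0.0}
    for name, u in zip(spec.free_params, free_unconstrained):
        if name == "alpha":
            a = to_natural("alpha", float(u))
            values["alpha_rew"] = values["alpha_pun"] = a
        else:
            values[name] = to_natural(name, float(u))
    return spec.constrain(ParameterSet(**values))


def generate_cohort(cohort: CohortSpec, config: TaskConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, ground-truth parameters).

    Subject parameters are drawn from their group's unconstrained-scale
    normal distribution and transformed to the natural scale.  Each subject
    runs on an independent RNG stream keyed by (master seed, subject index),
    so cohorts are reproducible and order-independent.
    """
    spec = cohort.generating_model
    trial_frames = []
    truth_rows = []
    idx = 0
    for group, n in cohort.group_sizes.items():
        mu = np.asarray(cohort.group_means[group], dtype=float)
        sd = np.asarray(cohort.group_sds[group], dtype=float)
        for i in range(n):
            subject_id = f"{group}{i + 1:02d}"
            ss = np.random.SeedSequence((cohort.rng_seed, idx))
            param_ss, task_ss = ss.spawn(2)
            z = np.random.default_rng(param_ss).standard_normal(spec.n_free)
            params = _params_from_free(spec, mu + sd * z)
            trial_frames.append(
                simulate_agent(params, spec, config, _seed_int(task_ss),
                               subject_id=subject_id, group=group))
            truth_rows.append(
                {"subject_id": subject_id, "group": group,
                 **{n_: getattr(params, n_) for n_ in
                    ("alpha_rew", "alpha_pun", "beta", "kappa_stim", "kappa_side")}})
            idx += 1
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the interchange schema.

    Raises :class:`SchemaError` naming the offending column on failure;
    returns the table with canonical dtypes.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    out = df.copy()
    for col in ("reinforced", "reversal_onset", "block", "trial"):
        try:
            out[col] = out[col].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"column {col!r} is not integer-valued") from exc
    if not out["reinforced"].isin((0, 1)).all():
        raise SchemaError("column 'reinforced' must be 0 or 1")
    if not out["reversal_onset"].isin((0, 1)).all():
        raise SchemaError("column 'reversal_onset' must be 0 or 1")
    if not out["choice_side"].isin(("left", "right")).all():
        raise SchemaError("column 'choice_side' must be 'left' or 'right'")
    ok_stim = (out["choice_stim"] == out["stim_left"]) | (
        out["choice_stim"] == out["stim_right"])
    if not ok_stim.all():
        bad = int(np.flatnonzero(~ok_stim.to_numpy())[0])
        raise SchemaError(
            f"column 'choice_stim': value not among displayed stimuli (row {bad})")
    ok_correct = (out["correct_stim"] == out["stim_left"]) | (
        out["correct_stim"] == out["stim_right"])
    if not ok_correct.all():
        raise SchemaError("column 'correct_stim': value not among displayed stimuli")
    return out


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV in canonical column order."""
    validate_trials(df)[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    return validate_trials(pd.read_csv(path))
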