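"""Model-derived trial-level regressors for fMRI first-level models.

Replays the fitted Q-learning model deterministically over each subject's
observed choices and extracts, per trial, the pre-update expected value of
the chosen stimulus Q_t(c_t) and the signed prediction error
delta_t = r_t - Q_t(c_t).  Trials are classified into six mutually
exclusive model-based event classes plus one response/feedback class:

* stimulus presentation: ``reward_EV`` when Q_t(c_t) >= 0.5 (reward
  expectation), else ``punish_EV``; modulated by Q_t(c_t);
* feedback: reward-expectation trials yield ``pos_RPE`` (r = 1) or
  ``neg_RPE`` (r = 0); punishment-expectation trials yield ``pos_PPE``
  (r = 1) or ``neg_PPE`` (r = 0); modulated by delta_t.

Under this scheme rewarded-trial prediction errors lie in [0, 1] and
punished-trial prediction errors in [-1, 0].  Event files are written in
the FSL three-column format (onset, duration, amplitude), one file per
event type per run, plus a seventh all-events response/feedback file with
unit amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .models import (
    PARAM_NAMES,
    LearnerState,
    ModelSpec,
    ParameterSet,
    get_model,
    update_q,
)
from .task import validate_trials

STIM_EVENT_CLASSES = ("reward_EV", "punish_EV")
FEEDBACK_EVENT_CLASSES = ("pos_RPE", "neg_RPE", "pos_PPE", "neg_PPE")
RESPONSE_EVENT = "response_feedback"


@dataclass(frozen=True)
class TrialTiming:
    """Event timing metadata (seconds): 2 s stimulus, 0.5 s feedback,
    3.253 s inter-stimulus interval."""

    stimulus_s: float = 2.0
    feedback_s: float = 0.5
    isi_s: float = 3.253

    @property
    def trial_s(self) -> float:
        return self.stimulus_s + self.feedback_s + self.isi_s


def extract_trajectories(trials: pd.DataFrame, params: ParameterSet,
                         spec: ModelSpec, q0: float = 0.5,
                         reset_between_blocks: bool = True) -> pd.DataFrame:
    """Per-trial (Q_chosen, prediction error) for one subject's observed log.

    Q_chosen is recorded before the update; delta = r - Q_chosen.
    """
    trials = trials.sort_values(["block", "trial"]).reset_index(drop=True)
    params = spec.constrain(params)
    state: LearnerState | None = None
    prev_block = None
    q_chosen = np.empty(len(trials))
    pe = np.empty(len(trials))
    for i, row in enumerate(trials.itertuples(index=False)):
        stimuli = (row.stim_left, row.stim_right)
        if state is None or (reset_between_blocks and row.block != prev_block):
            state = LearnerState.fresh(stimuli, q0=q0)
        else:
            for s in stimuli:
                state.q_values.setdefault(s, q0)
        prev_block = row.block
        if row.choice_stim not in stimuli:
            raise ValueError(f"choice_stim not among displayed stimuli (row {i})")
        q = state.q_values[row.choice_stim]
        q_chosen[i] = q
        pe[i] = row.reinforced - q
        state = update_q(state, row.choice_stim, row.choice_side,
                         int(row.reinforced), params)
    out = trials[["subject_id", "block", "trial", "reinforced"]].copy()
    out["q_chosen"] = q_chosen
    out["pe"] = pe
    return out


def classify_events(trajectories: pd.DataFrame, threshold: float = 0.5,
                    timing: TrialTiming = TrialTiming()) -> pd.DataFrame:
    """Expand trajectories into per-event rows (two events per trial).

    ``Q_chosen >= threshold`` counts as reward expectation (the tie at
    exactly 0.5 goes to reward expectation).  Onsets place trial t of a run
    at ``t * trial_s``, with feedback following the stimulus period.
    """
    rows = []
    for row in trajectories.itertuples(index=False):
        reward_exp = row.q_chosen >= threshold
        stim_class = "reward_EV" if reward_exp else "punish_EV"
        if reward_exp:
            fb_class = "pos_RPE" if row.reinforced == 1 else "neg_RPE"
        else:
            fb_class = "pos_PPE" if row.reinforced == 1 else "neg_PPE"
        t0 = row.trial * timing.trial_s
        rows.append((row.subject_id, row.block, row.trial, stim_class,
                     row.q_chosen, t0, timing.stimulus_s))
        rows.append((row.subject_id, row.block, row.trial, fb_class,
                     row.pe, t0 + timing.stimulus_s, timing.feedback_s))
    return pd.DataFrame(rows, columns=[
        "subject_id", "block", "trial", "event_class", "modulator",
        "onset_s", "duration_s"])


def write_event_files(events: pd.DataFrame, out_dir, mean_center: bool = True
                      ) -> list[Path]:
    """Write FSL three-column event files, one per event type per run.

    Six model-based files carry the (optionally mean-centred, per file)
    modulator as amplitude; the seventh response/feedback file lists every
    feedback event with unit amplitude.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (subject, block), run in events.groupby(["subject_id", "block"],
                                                sort=False):
        for cls in (*STIM_EVENT_CLASSES, *FEEDBACK_EVENT_CLASSES):
            sel = run[run["event_class"] == cls]
            if sel.empty:
                continue
            amp = sel["modulator"].to_numpy(dtype=float)
            if mean_center:
                amp = amp - amp.mean()
            paths.append(_write_three_column(
                out_dir / f"{subject}_run{block + 1}_{cls}.txt",
                sel["onset_s"].to_numpy(), sel["duration_s"].to_numpy(), amp))
        fb = run[run["event_class"].isin(FEEDBACK_EVENT_CLASSES)]
        paths.append(_write_three_column(
            out_dir / f"{subject}_run{block + 1}_{RESPONSE_EVENT}.txt",
            fb["onset_s"].to_numpy(), fb["duration_s"].to_numpy(),
            np.ones(len(fb))))
    return paths


def _write_three_column(path: Path, onset, duration, amplitude) -> Path:
    with open(path, "w", encoding="utf-8") as fh:
        for o, d, a in zip(onset, duration, amplitude):
            # repr of a Python float round-trips the value exactly
            fh.write(f"{float(o)!r}\t{float(d)!r}\t{float(a)!r}\n")
    return path


def read_event_file(path) -> pd.DataFrame:
    """Parse a three-column event file back into a DataFrame."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["onset_s", "duration_s", "amplitude"],
                       float_precision="round_trip")


class RegressorExtractor(BaseEstimator):
    """Transformer from trial logs to fMRI event rows.

    ``fit`` accepts a per-subject parameter table (columns ``subject_id``
    plus the five natural-scale parameters; typically
    ``HierarchicalRLModel.subject_params_``); ``transform`` replays the
    model over a trial table and returns classified event rows.
    """

    def __init__(self, model_id: int = 6, threshold: float = 0.5,
                 q0: float = 0.5, reset_between_blocks: bool = True,
                 timing: TrialTiming = TrialTiming(),
                 mean_center: bool = True):
        self.model_id = model_id
        self.threshold = threshold
        self.q0 = q0
        self.reset_between_blocks = reset_between_blocks
        self.timing = timing
        self.mean_center = mean_center

    def fit(self, X: pd.DataFrame, y=None) -> "RegressorExtractor":
        missing = [c for c in ("subject_id", *PARAM_NAMES) if c not in X.columns]
        if missing:
            raise ValueError(f"parameter table missing columns: {missing}")
        self.params_ = X.set_index("subject_id")[list(PARAM_NAMES)]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "params_"):
            raise RuntimeError("extractor is not fitted; call fit() first")
        spec = get_model(self.model_id)
        trials = validate_trials(X)
        frames = []
        for subject, sub in trials.groupby("subject_id", sort=False):
            if subject not in self.params_.index:
                raise KeyError(f"no parameters for subject {subject!r}")
            p = ParameterSet(*(float(v) for v in self.params_.loc[subject]))
            traj = extract_trajectories(sub, p, spec, q0=self.q0,
                                        reset_between_blocks=self.reset_between_blocks)
            frames.append(classify_events(traj, threshold=self.threshold,
                                          timing=self.timing))
        return pd.concat(frames, ignore_index=True)

    def write(self, events: pd.DataFrame, out_dir) -> list[Path]:
        return write_event_files(events, out_dir, mean_center=self.mean_center)
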