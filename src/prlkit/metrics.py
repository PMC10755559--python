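"""Conventional reversal-learning measures and posterior-predictive checks.

Three raw-data measures per subject:

* ``prop_correct`` — fraction of trials on which the currently correct
  (majority-rewarded) stimulus was chosen;
* ``trials_to_criterion`` — mean trials per completed discrimination (a
  discrimination counts as completed when it was terminated by a reversal;
  the trailing, possibly unfinished discrimination of a block is excluded);
* ``perseverative_responses`` — after each reversal, the number of
  consecutive choices of the previously correct stimulus before the first
  choice of the newly correct one, summed over reversals.

The posterior-predictive check re-simulates the task from fitted subject
parameters and compares group means of these measures with the observed
data, flagging measures whose observed group mean falls outside the central
95% interval across simulation replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ParameterSet, PARAM_NAMES
from .task import TaskConfig, simulate_agent, validate_trials, _seed_int

MEASURES = ("prop_correct", "trials_to_criterion", "perseverative_responses")


def _summarize_one(sub: pd.DataFrame) -> dict:
    sub = sub.sort_values(["block", "trial"])
    correct = (sub["choice_stim"] == sub["correct_stim"]).to_numpy()
    prop_correct = float(correct.mean())

    trials_per_disc: list[int] = []
    persev = 0
    for _, block in sub.groupby("block", sort=False):
        rev = block["reversal_onset"].to_numpy().astype(bool)
        corr = (block["choice_stim"] == block["correct_stim"]).to_numpy()
        bounds = np.flatnonzero(rev)
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(block)]])
        # discriminations terminated by a reversal are complete
        for s, e in zip(starts[:-1], ends[:-1]):
            trials_per_disc.append(e - s)
        # perseveration: post-reversal run of old-stimulus choices
        prev_correct = block["correct_stim"].shift(1).to_numpy()
        choices = block["choice_stim"].to_numpy()
        for b in bounds:
            old = prev_correct[b]
            for t in range(b, len(block)):
                if choices[t] == old:
                    persev += 1
                else:
                    break
    return {
        "prop_correct": prop_correct,
        "trials_to_criterion": float(np.mean(trials_per_disc))
        if trials_per_disc else np.nan,
        "perseverative_responses": persev,
    }


def summarize_behaviour(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject conventional measures for a tidy trial table."""
    trials = validate_trials(trials)
    rows = []
    for subject, sub in trials.groupby("subject_id", sort=False):
        rows.append({"subject_id": subject, "group": sub["group"].iloc[0],
                     **_summarize_one(sub)})
    return pd.DataFrame(rows)


def posterior_predictive_check(fit, trials: pd.DataFrame, config: TaskConfig,
                               n_reps: int = 20, seed: int = 0) -> pd.DataFrame:
    """Observed versus simulated conventional measures, per group.

    Simulates ``n_reps`` replicate cohorts from the fitted subject
    posterior-mean parameters under ``config``, and reports for each group
    and measure the observed group mean, the mean across replicates, the
    central 95% simulation interval, and whether the observed value falls
    outside it.
    """
    observed = summarize_behaviour(trials)
    obs_group = observed.groupby("group", sort=False)[list(MEASURES)].mean()

    params = fit.subject_params_
    ss = np.random.SeedSequence(seed)
    rep_means = []
    for rep, rep_ss in enumerate(ss.spawn(n_reps)):
        frames = []
        for (row, sub_ss) in zip(params.itertuples(index=False),
                                 rep_ss.spawn(len(params))):
            p = ParameterSet(*(getattr(row, n) for n in PARAM_NAMES))
            frames.append(simulate_agent(
                p, fit.spec_, config, _seed_int(sub_ss),
                subject_id=row.subject_id, group=row.group))
        sim = summarize_behaviour(pd.concat(frames, ignore_index=True))
        m = sim.groupby("group", sort=False)[list(MEASURES)].mean()
        m["rep"] = rep
        rep_means.append(m)
    sims = pd.concat(rep_means)

    rows = []
    for group in obs_group.index:
        for measure in MEASURES:
            draws = sims.loc[group, measure]
            draws = np.atleast_1d(np.asarray(draws, dtype=float))
            lo, hi = np.percentile(draws, [2.5, 97.5])
            obs = float(obs_group.loc[group, measure])
            rows.append({
                "group": group, "measure": measure, "observed": obs,
                "simulated_mean": float(np.mean(draws)),
                "sim_lo_2.5": float(lo), "sim_hi_97.5": float(hi),
                "outside_interval": not (lo <= obs <= hi),
                "n_reps": n_reps,
            })
    return pd.DataFrame(rows)
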