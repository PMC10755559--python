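"""Independent step-through oracles used by the tests.

These re-derive choice probabilities, log-likelihoods and value/prediction-
error trajectories with explicit per-trial arithmetic on plain Python
floats, deliberately sharing no code with the package's likelihood kernels.
"""

import math


def step_through(trials, alpha_rew, alpha_pun, beta, kappa_stim, kappa_side,
                 q0=0.5, reset_between_blocks=True):
    """Replay one subject's trials; return (loglik, [(q_chosen, pe), ...]).

    ``trials`` is an iterable of dicts with keys block, stim_left,
    stim_right, choice_stim, choice_side, reinforced.
    """
    q = {}
    prev_stim = None
    prev_side = None
    prev_block = None
    loglik = 0.0
    traj = []
    for row in trials:
        if prev_block is None or (reset_between_blocks and row["block"] != prev_block):
            q = {row["stim_left"]: q0, row["stim_right"]: q0}
            prev_stim = None
            prev_side = None
        prev_block = row["block"]
        for s in (row["stim_left"], row["stim_right"]):
            q.setdefault(s, q0)
        x = beta * (q[row["stim_left"]] - q[row["stim_right"]])
        if prev_stim is not None:
            if prev_stim == row["stim_left"]:
                x += kappa_stim
            elif prev_stim == row["stim_right"]:
                x -= kappa_stim
            if prev_side == "left":
                x += kappa_side
            elif prev_side == "right":
                x -= kappa_side
        p_left = 1.0 / (1.0 + math.exp(-x))
        p_choice = p_left if row["choice_side"] == "left" else 1.0 - p_left
        loglik += math.log(p_choice)
        qc = q[row["choice_stim"]]
        r = row["reinforced"]
        traj.append((qc, r - qc))
        alpha = alpha_rew if r == 1 else alpha_pun
        q[row["choice_stim"]] = qc + alpha * (r - qc)
        prev_stim = row["choice_stim"]
        prev_side = row["choice_side"]
    return loglik, traj


def random_trial_log(rng, n_trials=12, n_blocks=2, shared_stimuli=False):
    """A random (not behaviourally coherent) but schema-valid trial log."""
    rows = []
    for b in range(n_blocks):
        stims = ("s0", "s1") if shared_stimuli else (f"b{b}s0", f"b{b}s1")
        cs_plus = stims[rng.integers(0, 2)]
        for t in range(n_trials):
            li = rng.integers(0, 2)
            left, right = stims[li], stims[1 - li]
            chose_left = bool(rng.integers(0, 2))
            rows.append({
                "subject_id": "s1", "group": "control", "block": b, "trial": t,
                "stim_left": left, "stim_right": right, "correct_stim": cs_plus,
                "choice_stim": left if chose_left else right,
                "choice_side": "left" if chose_left else "right",
                "reinforced": int(rng.integers(0, 2)), "reversal_onset": 0,
            })
    return rows
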