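"""Numba kernels: choice log-likelihoods and the hierarchical log-posterior.

The gradient of the log-posterior is derived analytically.  Q-values depend
on the learning rates only, so forward sensitivities ``dQ/dalpha_rew`` and
``dQ/dalpha_pun`` are propagated through the Rescorla–Wagner recursion;
``beta`` and the stickiness parameters enter the choice logit linearly.

Parameter-vector layout for a model with K free parameters, G groups and S
subjects (all on the unconstrained scale)::

    theta = [ mu[g, k]    : G*K   group means
              s_raw[g, k] : G*K   log group SDs (sigma = exp(s_raw))
              z[s, k]     : S*K   non-centred subject offsets ]

Subject-level unconstrained parameters are ``u = mu[g] + sigma[g] * z[s]``;
natural-scale parameters are ``inv_logit(u)`` for learning rates,
``exp(u)`` for beta, identity for stickiness.

Free-parameter roles are encoded as integers:
0 shared alpha, 1 alpha_rew, 2 alpha_pun, 3 beta, 4 kappa_stim, 5 kappa_side.
"""

import numpy as np
from numba import njit

KIND_ALPHA = 0
KIND_ALPHA_REW = 1
KIND_ALPHA_PUN = 2
KIND_BETA = 3
KIND_KAPPA_STIM = 4
KIND_KAPPA_SIDE = 5

_KIND_BY_NAME = {
    "alpha": KIND_ALPHA,
    "alpha_rew": KIND_ALPHA_REW,
    "alpha_pun": KIND_ALPHA_PUN,
    "beta": KIND_BETA,
    "kappa_stim": KIND_KAPPA_STIM,
    "kappa_side": KIND_KAPPA_SIDE,
}


def param_kinds(free_names) -> np.ndarray:
    return np.array([_KIND_BY_NAME[n] for n in free_names], dtype=np.int64)


@njit(cache=True)
def _log_sigmoid(m):
    # log(1/(1+exp(-m))), stable on both tails
    if m >= 0.0:
        return -np.log1p(np.exp(-m))
    return m - np.log1p(np.exp(m))


@njit(cache=True)
def subject_loglik(a_rew, a_pun, beta, k_stim, k_side,
                   chosen, left, side, reward, reset, q0):
    """Log-likelihood of one subject's choices under given natural parameters.

    ``chosen``/``left`` index the two per-block stimuli as 0/1; ``side`` is
    0 when the left side was chosen; ``reset`` marks trials at which the
    learner state re-initialises (block starts).
    """
    q0_, q1 = q0, q0
    prev_c = -1
    prev_s = -1
    ll = 0.0
    for t in range(chosen.shape[0]):
        if reset[t] == 1:
            q0_, q1 = q0, q0
            prev_c = -1
            prev_s = -1
        l = left[t]
        dq = q0_ - q1 if l == 0 else q1 - q0_
        x = beta * dq
        if prev_c >= 0:
            istim = 1.0 if prev_c == l else -1.0
            x += k_stim * istim
            iside = 1.0 if prev_s == 0 else -1.0
            x += k_side * iside
        zz = 1.0 if side[t] == 0 else -1.0
        ll += _log_sigmoid(zz * x)
        c = chosen[t]
        qc = q0_ if c == 0 else q1
        pe = reward[t] - qc
        alpha = a_rew if reward[t] == 1 else a_pun
        if c == 0:
            q0_ += alpha * pe
        else:
            q1 += alpha * pe
        prev_c = c
        prev_s = side[t]
    return ll


@njit(cache=True)
def cohort_pointwise_loglik(nat, sub_ptr, chosen, left, side, reward, reset, q0):
    """Per-subject log-likelihoods for a natural-scale parameter matrix.

    ``nat`` has one row per subject with columns
    (alpha_rew, alpha_pun, beta, kappa_stim, kappa_side); ``sub_ptr`` holds
    CSR-style offsets into the flat trial arrays.
    """
    n_sub = nat.shape[0]
    out = np.empty(n_sub)
    for s in range(n_sub):
        a, b = sub_ptr[s], sub_ptr[s + 1]
        out[s] = subject_loglik(
            nat[s, 0], nat[s, 1], nat[s, 2], nat[s, 3], nat[s, 4],
            chosen[a:b], left[a:b], side[a:b], reward[a:b], reset[a:b], q0,
        )
    return out


@njit(cache=True)
def hier_logp_grad(theta, kinds, group_idx, sub_ptr,
                   chosen, left, side, reward, reset,
                   n_groups, q0, mu_scale, sigma_scale):
    """Hierarchical log-posterior and its gradient.

    Priors: mu ~ Normal(0, mu_scale); sigma ~ half-Normal(sigma_scale)
    sampled as s_raw = log sigma with the Jacobian term included;
    z ~ Normal(0, 1).
    """
    K = kinds.shape[0]
    S = sub_ptr.shape[0] - 1
    G = n_groups
    lp = 0.0
    grad = np.zeros(theta.shape[0])

    # prior terms
    for i in range(G * K):
        mu = theta[i]
        lp += -0.5 * (mu / mu_scale) ** 2
        grad[i] += -mu / (mu_scale * mu_scale)
        sraw = theta[G * K + i]
        sig = np.exp(sraw)
        lp += -0.5 * (sig / sigma_scale) ** 2 + sraw
        grad[G * K + i] += -(sig * sig) / (sigma_scale * sigma_scale) + 1.0
    for i in range(S * K):
        zval = theta[2 * G * K + i]
        lp += -0.5 * zval * zval
        grad[2 * G * K + i] += -zval

    for s in range(S):
        g = group_idx[s]
        # natural-scale parameters for this subject
        a_rew = 0.5
        a_pun = 0.5
        beta = 1.0
        k_stim = 0.0
        k_side = 0.0
        u_vec = np.empty(K)
        sig_vec = np.empty(K)
        z_vec = np.empty(K)
        for p in range(K):
            mu = theta[g * K + p]
            sraw = theta[G * K + g * K + p]
            sig = np.exp(sraw)
            zval = theta[2 * G * K + s * K + p]
            u = mu + sig * zval
            u_vec[p] = u
            sig_vec[p] = sig
            z_vec[p] = zval
            k = kinds[p]
            if k == 0:
                a_rew = 1.0 / (1.0 + np.exp(-u))
                a_pun = a_rew
            elif k == 1:
                a_rew = 1.0 / (1.0 + np.exp(-u))
            elif k == 2:
                a_pun = 1.0 / (1.0 + np.exp(-u))
            elif k == 3:
                if u > 30.0:
                    u = 30.0
                beta = np.exp(u)
            elif k == 4:
                k_stim = u
            else:
                k_side = u

        # trial loop with forward sensitivities of Q wrt (alpha_rew, alpha_pun)
        q0_, q1 = q0, q0
        d0r = 0.0
        d0p = 0.0
        d1r = 0.0
        d1p = 0.0
        prev_c = -1
        prev_s = -1
        g_ar = 0.0
        g_ap = 0.0
        g_beta = 0.0
        g_ks = 0.0
        g_kd = 0.0
        for t in range(sub_ptr[s], sub_ptr[s + 1]):
            if reset[t] == 1:
                q0_, q1 = q0, q0
                d0r = d0p = d1r = d1p = 0.0
                prev_c = -1
                prev_s = -1
            l = left[t]
            if l == 0:
                dq = q0_ - q1
                ddq_r = d0r - d1r
                ddq_p = d0p - d1p
            else:
                dq = q1 - q0_
                ddq_r = d1r - d0r
                ddq_p = d1p - d0p
            x = beta * dq
            istim = 0.0
            iside = 0.0
            if prev_c >= 0:
                istim = 1.0 if prev_c == l else -1.0
                iside = 1.0 if prev_s == 0 else -1.0
                x += k_stim * istim + k_side * iside
            zz = 1.0 if side[t] == 0 else -1.0
            m = zz * x
            lp += _log_sigmoid(m)
            gx = zz / (1.0 + np.exp(m))  # d loglik / d x
            g_beta += gx * dq
            g_ks += gx * istim
            g_kd += gx * iside
            g_ar += gx * beta * ddq_r
            g_ap += gx * beta * ddq_p

            c = chosen[t]
            qc = q0_ if c == 0 else q1
            pe = reward[t] - qc
            if reward[t] == 1:
                alpha = a_rew
                if c == 0:
                    d0r = (1.0 - alpha) * d0r + pe
                    d0p = (1.0 - alpha) * d0p
                    q0_ += alpha * pe
                else:
                    d1r = (1.0 - alpha) * d1r + pe
                    d1p = (1.0 - alpha) * d1p
                    q1 += alpha * pe
            else:
                alpha = a_pun
                if c == 0:
                    d0p = (1.0 - alpha) * d0p + pe
                    d0r = (1.0 - alpha) * d0r
                    q0_ += alpha * pe
                else:
                    d1p = (1.0 - alpha) * d1p + pe
                    d1r = (1.0 - alpha) * d1r
                    q1 += alpha * pe
            prev_c = c
            prev_s = side[t]

        # chain natural-scale gradients back to unconstrained subject params
        for p in range(K):
            k = kinds[p]
            u = u_vec[p]
            if k == 0:
                a = 1.0 / (1.0 + np.exp(-u))
                gu = (g_ar + g_ap) * a * (1.0 - a)
            elif k == 1:
                a = 1.0 / (1.0 + np.exp(-u))
                gu = g_ar * a * (1.0 - a)
            elif k == 2:
                a = 1.0 / (1.0 + np.exp(-u))
                gu = g_ap * a * (1.0 - a)
            elif k == 3:
                gu = g_beta * np.exp(min(u, 30.0))
            elif k == 4:
                gu = g_ks
            else:
                gu = g_kd
            grad[g * K + p] += gu
            grad[G * K + g * K + p] += gu * sig_vec[p] * z_vec[p]
            grad[2 * G * K + s * K + p] += gu * sig_vec[p]
    return lp, grad
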