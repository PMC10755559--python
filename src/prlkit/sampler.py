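"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC backend for the hierarchical model.
Multinomial trajectory sampling, the classic u-turn criterion, Stan-style
warm-up windowing (fast step-size interval, expanding slow covariance
windows, final fast interval) and a divergence threshold of 1000 on the
energy error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["nuts_sample", "NutsResult"]

_DIVERGENCE_DELTA = 1000.0


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_samples, dim)
    logp: np.ndarray           # (n_samples,)
    divergent: np.ndarray      # (n_samples,) bool
    tree_depth: np.ndarray     # (n_samples,)
    accept_stat: np.ndarray    # (n_samples,)
    step_size: float
    inv_mass: np.ndarray


def _leapfrog(theta, p, grad, eps, inv_mass, logp_grad):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    lp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, lp, grad


def _energy(lp, p, inv_mass):
    return -lp + 0.5 * float(np.dot(p * p, inv_mass))


class _Tree:
    __slots__ = (
        "theta_m", "p_m", "grad_m", "theta_p", "p_p", "grad_p",
        "theta_prop", "lp_prop", "log_w", "sum_alpha", "n_alpha",
        "divergent", "turning",
    )


def _uturn(theta_p, theta_m, p_m, p_p, inv_mass):
    dt = theta_p - theta_m
    return (np.dot(dt, inv_mass * p_m) < 0.0) or (np.dot(dt, inv_mass * p_p) < 0.0)


def _build_tree(theta, p, grad, lp, direction, depth, eps, h0,
                inv_mass, logp_grad, rng):
    if depth == 0:
        theta1, p1, lp1, grad1 = _leapfrog(theta, p, grad, direction * eps, inv_mass, logp_grad)
        t = _Tree()
        t.theta_m = t.theta_p = t.theta_prop = theta1
        t.p_m = t.p_p = p1
        t.grad_m = t.grad_p = grad1
        t.lp_prop = lp1
        if np.isfinite(lp1):
            h1 = _energy(lp1, p1, inv_mass)
            delta = h0 - h1
        else:
            delta = -np.inf
        t.divergent = not np.isfinite(delta) or (-delta > _DIVERGENCE_DELTA)
        t.log_w = delta if np.isfinite(delta) else -np.inf
        t.sum_alpha = min(1.0, np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
        t.n_alpha = 1
        t.turning = False
        return t

    first = _build_tree(theta, p, grad, lp, direction, depth - 1, eps, h0,
                        inv_mass, logp_grad, rng)
    if first.divergent or first.turning:
        return first
    if direction == 1:
        second = _build_tree(first.theta_p, first.p_p, first.grad_p, first.lp_prop,
                             direction, depth - 1, eps, h0, inv_mass, logp_grad, rng)
        first.theta_p, first.p_p, first.grad_p = second.theta_p, second.p_p, second.grad_p
    else:
        second = _build_tree(first.theta_m, first.p_m, first.grad_m, first.lp_prop,
                             direction, depth - 1, eps, h0, inv_mass, logp_grad, rng)
        first.theta_m, first.p_m, first.grad_m = second.theta_m, second.p_m, second.grad_m

    total = np.logaddexp(first.log_w, second.log_w)
    if np.isfinite(second.log_w) and np.log(rng.uniform()) < second.log_w - total:
        first.theta_prop = second.theta_prop
        first.lp_prop = second.lp_prop
    first.log_w = total
    first.sum_alpha += second.sum_alpha
    first.n_alpha += second.n_alpha
    first.divergent = second.divergent
    first.turning = second.turning or _uturn(
        first.theta_p, first.theta_m, first.p_m, first.p_p, inv_mass
    )
    return first


def _nuts_step(theta, lp, grad, eps, inv_mass, logp_grad, rng, max_depth):
    p0 = rng.standard_normal(theta.shape[0]) / np.sqrt(inv_mass)
    h0 = _energy(lp, p0, inv_mass)
    theta_m = theta_p = theta
    p_m = p_p = p0
    grad_m = grad_p = grad
    lp_m = lp_p = lp
    theta_prop, lp_prop, grad_prop = theta, lp, grad
    log_w = 0.0
    sum_alpha = 0.0
    n_alpha = 0
    divergent = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(theta_p, p_p, grad_p, lp_p, 1, depth, eps, h0,
                              inv_mass, logp_grad, rng)
            theta_p, p_p, grad_p, lp_p = sub.theta_p, sub.p_p, sub.grad_p, sub.lp_prop
        else:
            sub = _build_tree(theta_m, p_m, grad_m, lp_m, -1, depth, eps, h0,
                              inv_mass, logp_grad, rng)
            theta_m, p_m, grad_m, lp_m = sub.theta_m, sub.p_m, sub.grad_m, sub.lp_prop
        sum_alpha += sub.sum_alpha
        n_alpha += sub.n_alpha
        if sub.divergent:
            divergent = True
            break
        if sub.turning:
            break
        # progressive multinomial: accept subtree proposal with prob w_sub/w_tot
        if np.isfinite(sub.log_w) and np.log(rng.uniform()) < sub.log_w - np.logaddexp(log_w, sub.log_w):
            theta_prop, lp_prop = sub.theta_prop, sub.lp_prop
        log_w = np.logaddexp(log_w, sub.log_w)
        depth += 1
        if _uturn(theta_p, theta_m, p_m, p_p, inv_mass):
            break
    accept = sum_alpha / max(n_alpha, 1)
    return theta_prop, lp_prop, accept, depth, divergent


def _find_initial_eps(theta, lp, grad, inv_mass, logp_grad, rng):
    eps = 1.0
    p0 = rng.standard_normal(theta.shape[0]) / np.sqrt(inv_mass)
    h0 = _energy(lp, p0, inv_mass)
    _, p1, lp1, _ = _leapfrog(theta, p0, grad, eps, inv_mass, logp_grad)
    delta = h0 - _energy(lp1, p1, inv_mass) if np.isfinite(lp1) else -np.inf
    direction = 1 if delta > np.log(0.8) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, lp1, _ = _leapfrog(theta, p0, grad, eps, inv_mass, logp_grad)
        delta = h0 - _energy(lp1, p1, inv_mass) if np.isfinite(lp1) else -np.inf
        if (direction == 1 and delta <= np.log(0.8)) or \
           (direction == -1 and delta >= np.log(0.8)):
            break
    return eps


def _warmup_windows(n_warmup):
    """(start, end, is_slow) warm-up intervals, Stan-style 15%/75%/10%."""
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.10 * n_warmup), 10)
    if init + term >= n_warmup:
        return [(0, n_warmup, False)]
    windows = [(0, init, False)]
    pos = init
    size = max(25 * n_warmup // 1000, 10)
    while pos < n_warmup - term:
        end = min(pos + size, n_warmup - term)
        # absorb a too-small trailing window
        if (n_warmup - term - end) < size:
            end = n_warmup - term
        windows.append((pos, end, True))
        pos = end
        size *= 2
    windows.append((n_warmup - term, n_warmup, False))
    return windows


def nuts_sample(logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
                theta0: np.ndarray, n_warmup: int, n_samples: int,
                rng: np.random.Generator, max_depth: int = 10,
                target_accept: float = 0.8) -> NutsResult:
    """Run one NUTS chain and return post-warm-up draws."""
    theta = np.asarray(theta0, dtype=float).copy()
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("non-finite log-density at the initial point")
    dim = theta.shape[0]
    inv_mass = np.ones(dim)

    eps = _find_initial_eps(theta, lp, grad, inv_mass, logp_grad, rng)
    mu_da = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    windows = _warmup_windows(n_warmup)
    for (start, end, is_slow) in windows:
        for _ in range(start, end):
            theta, lp, accept, _, _ = _nuts_step_cached(
                theta, lp, eps, inv_mass, logp_grad, rng, max_depth)
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            eta = da_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1.0 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if is_slow:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
        if is_slow and welford_n > 1:
            var = welford_m2 / (welford_n - 1)
            inv_mass = (welford_n / (welford_n + 5.0)) * var \
                + 1e-3 * (5.0 / (welford_n + 5.0))
            welford_n = 0
            welford_mean[:] = 0.0
            welford_m2[:] = 0.0
            eps = max(eps, 1e-8)
            mu_da = np.log(10.0 * eps)
            h_bar = 0.0
            log_eps_bar = np.log(eps)
            da_count = 0
    eps = float(np.exp(log_eps_bar)) if n_warmup > 0 else eps

    draws = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    divergent = np.zeros(n_samples, dtype=bool)
    depths = np.zeros(n_samples, dtype=np.int64)
    accepts = np.empty(n_samples)
    for i in range(n_samples):
        theta, lp, accept, depth, div = _nuts_step_cached(
            theta, lp, eps, inv_mass, logp_grad, rng, max_depth)
        draws[i] = theta
        logps[i] = lp
        divergent[i] = div
        depths[i] = depth
        accepts[i] = accept
    return NutsResult(draws, logps, divergent, depths, accepts, eps, inv_mass)


def _nuts_step_cached(theta, lp, eps, inv_mass, logp_grad, rng, max_depth):
    # recompute gradient at the current point (cheap relative to a trajectory)
    lp, grad = logp_grad(theta)
    return _nuts_step(theta, lp, grad, eps, inv_mass, logp_grad, rng, max_depth)
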