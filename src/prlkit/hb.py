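"""Hierarchical Bayesian estimation of the reinforcement-learning family.

Each group has its own mean and SD per free parameter on the unconstrained
scale; subjects are drawn from their group's distribution via a non-centred
parameterisation.  Priors are weakly informative: group means Normal(0, 1),
group SDs half-Normal(1), subject offsets Normal(0, 1).  With the log
transform for beta this puts the implied natural-scale prior median of beta
at ~1.  Sampling is by NUTS; convergence is summarised by the potential
scale reduction factor (R-hat, threshold 1.1) and effective sample size.
Model comparison uses approximate leave-one-out expected log predictive
density (PSIS-LOO, subject-wise pointwise likelihood), with WAIC as a
fallback, treating models as equiprobable a priori.  Group contrasts are
computed on the natural scale (transform each draw, then difference) and
summarised by 75% and 95% highest density intervals.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from . import sampler as _sampler
from ._likelihood import hier_logp_grad, cohort_pointwise_loglik, param_kinds
from .models import (
    PARAM_NAMES,
    ModelSpec,
    get_model,
    _pack_subject_trials,
)
from .task import validate_trials

__all__ = [
    "PriorConfig", "McmcConfig", "GroupContrast", "HierarchicalRLModel",
    "fit_model", "compare_models", "group_contrast", "hdi",
]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the weakly-informative hierarchical priors."""

    mu_scale: float = 1.0
    sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: 4 chains x 1000 warm-up + 1000 sampling by default."""

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    max_depth: int = 10
    target_accept: float = 0.8
    rhat_threshold: float = 1.1


@dataclass
class GroupContrast:
    """Posterior difference of two group means for one parameter."""

    parameter: str
    group_a: str
    group_b: str
    draws: np.ndarray
    hdi_75: tuple[float, float]
    hdi_95: tuple[float, float]
    excludes_zero_75: bool
    excludes_zero_95: bool

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))


def hdi(samples, mass: float) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally narrow windows are broken toward the lower one.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"hdi requires >= 100 samples, got {n}")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _natural(names: tuple[str, ...], u: np.ndarray) -> np.ndarray:
    """Transform unconstrained draws (..., param) to the natural scale."""
    out = np.empty_like(u)
    for j, name in enumerate(names):
        if name.startswith("alpha"):
            out[..., j] = expit(u[..., j])
        elif name == "beta":
            out[..., j] = np.exp(u[..., j])
        else:
            out[..., j] = u[..., j]
    return out


def _data_hash(trials: pd.DataFrame) -> str:
    buf = io.StringIO()
    trials.to_csv(buf, index=False)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


class HierarchicalRLModel(BaseEstimator):
    """Hierarchical Bayesian Q-learning model, scikit-learn style.

    Parameters
    ----------
    model_id : int
        Which of the six candidate models to fit (6 = five-parameter model
        with split learning rates and both stickiness terms).
    priors, mcmc : PriorConfig, McmcConfig
        Hyperparameters and sampler settings.
    q0 : float
        Initial Q-value of each stimulus at the start of a block.
    reset_between_blocks : bool
        Whether learner state re-initialises at block boundaries.

    After ``fit`` the posterior lives in ``posterior_`` (an ArviZ
    ``InferenceData``), subject-level posterior-mean parameters in
    ``subject_params_``, diagnostics in ``rhat_`` / ``max_rhat_`` /
    ``n_divergent_``, and the model-comparison criterion in ``loo_``.
    """

    def __init__(self, model_id: int = 6, priors: PriorConfig | None = None,
                 mcmc: McmcConfig | None = None, q0: float = 0.5,
                 reset_between_blocks: bool = True,
                 model_spec: ModelSpec | None = None):
        self.model_id = model_id
        self.priors = priors
        self.mcmc = mcmc
        self.q0 = q0
        self.reset_between_blocks = reset_between_blocks
        self.model_spec = model_spec  # overrides the registry lookup

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalRLModel":
        """Fit the hierarchical model to a tidy cohort trial table."""
        priors = self.priors or PriorConfig()
        mcmc = self.mcmc or McmcConfig()
        spec = (self.model_spec if self.model_spec is not None
                else get_model(self.model_id))
        trials = validate_trials(X)
        packed = self._pack(trials)
        if len(packed["groups"]) < 1 or any(
                n < 2 for n in packed["group_counts"].values()):
            raise ValueError("need at least 2 subjects per group")

        kinds = param_kinds(spec.free_params)
        G, K, S = len(packed["groups"]), spec.n_free, len(packed["subjects"])
        dim = 2 * G * K + S * K

        args = (kinds, packed["group_idx"], packed["sub_ptr"],
                packed["chosen"], packed["left"], packed["side"],
                packed["reward"], packed["reset"], G, self.q0,
                priors.mu_scale, priors.sigma_scale)

        def logp_grad(theta):
            return hier_logp_grad(theta, *args)

        ss = np.random.SeedSequence(mcmc.seed)
        chain_seeds = ss.spawn(mcmc.chains)
        chain_draws = []
        chain_lp = []
        chain_div = []
        chain_depth = []
        chain_accept = []
        for c in range(mcmc.chains):
            rng = np.random.default_rng(chain_seeds[c])
            theta0 = np.concatenate([
                rng.normal(0.0, 0.3, G * K),          # mu
                rng.normal(-1.0, 0.2, G * K),         # log sigma
                rng.normal(0.0, 0.3, S * K),          # z
            ])
            res = _sampler.nuts_sample(
                logp_grad, theta0, mcmc.warmup, mcmc.samples, rng,
                max_depth=mcmc.max_depth, target_accept=mcmc.target_accept)
            chain_draws.append(res.draws)
            chain_lp.append(res.logp)
            chain_div.append(res.divergent)
            chain_depth.append(res.tree_depth)
            chain_accept.append(res.accept_stat)

        draws = np.stack(chain_draws)  # (chain, draw, dim)
        self._assemble(draws, np.stack(chain_lp), np.stack(chain_div),
                       np.stack(chain_depth), np.stack(chain_accept),
                       packed, spec, mcmc)
        return self

    def _pack(self, trials: pd.DataFrame) -> dict:
        subjects = list(dict.fromkeys(trials["subject_id"]))
        groups: list[str] = []
        group_of: dict[str, str] = {}
        frames = []
        ptr = [0]
        for s in subjects:
            sub = trials[trials["subject_id"] == s].sort_values(["block", "trial"])
            g = str(sub["group"].iloc[0])
            group_of[s] = g
            if g not in groups:
                groups.append(g)
            frames.append(_pack_subject_trials(sub, self.reset_between_blocks))
            ptr.append(ptr[-1] + len(sub))
        packed = {k: np.concatenate([f[k] for f in frames])
                  for k in ("chosen", "left", "side", "reward", "reset")}
        packed["sub_ptr"] = np.asarray(ptr, dtype=np.int64)
        packed["subjects"] = subjects
        packed["groups"] = groups
        packed["group_of"] = group_of
        packed["group_idx"] = np.array(
            [groups.index(group_of[s]) for s in subjects], dtype=np.int64)
        packed["group_counts"] = {
            g: sum(1 for s in subjects if group_of[s] == g) for g in groups}
        packed["data_hash"] = _data_hash(trials[
            ["subject_id", "group", "block", "trial", "choice_stim",
             "choice_side", "reinforced"]])
        return packed

    def _assemble(self, draws, lp, div, depth, accept, packed, spec, mcmc):
        groups, subjects = packed["groups"], packed["subjects"]
        names = spec.free_params
        G, K, S = len(groups), spec.n_free, len(subjects)
        C, D = draws.shape[0], draws.shape[1]

        mu = draws[:, :, : G * K].reshape(C, D, G, K)
        sigma = np.exp(draws[:, :, G * K: 2 * G * K].reshape(C, D, G, K))
        z = draws[:, :, 2 * G * K:].reshape(C, D, S, K)
        u_sub = mu[:, :, packed["group_idx"], :] + \
            sigma[:, :, packed["group_idx"], :] * z
        subject_nat = _natural(names, u_sub)
        group_nat = _natural(names, mu)

        # subject-wise pointwise log-likelihood for LOO
        nat5 = self._nat5(names, subject_nat.reshape(C * D, S, K))
        ll = np.empty((C * D, S))
        for d in range(C * D):
            ll[d] = cohort_pointwise_loglik(
                nat5[d], packed["sub_ptr"], packed["chosen"], packed["left"],
                packed["side"], packed["reward"], packed["reset"], self.q0)
        ll = ll.reshape(C, D, S)

        coords = {"group": groups, "param": list(names), "subject": subjects}
        idata = az.from_dict(
            posterior={
                "mu": mu,
                "sigma": sigma,
                "group_mean_natural": group_nat,
                "subject_param": subject_nat,
            },
            sample_stats={
                "lp": lp,
                "diverging": div,
                "tree_depth": depth,
                "acceptance_rate": accept,
            },
            log_likelihood={"choices": ll},
            coords=coords,
            dims={
                "mu": ["group", "param"],
                "sigma": ["group", "param"],
                "group_mean_natural": ["group", "param"],
                "subject_param": ["subject", "param"],
                "choices": ["subject"],
            },
        )

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat_ds = az.rhat(idata, var_names=["mu", "sigma",
                                                "group_mean_natural",
                                                "subject_param"])
            ess_ds = az.ess(idata, var_names=["mu", "sigma",
                                              "group_mean_natural"])
        rhats = {}
        for var in rhat_ds.data_vars:
            vals = rhat_ds[var]
            for idx, v in np.ndenumerate(vals.values):
                labels = ",".join(str(vals.coords[d].values[i])
                                  for d, i in zip(vals.dims, idx))
                rhats[f"{var}[{labels}]"] = float(v)
        # contrast draws + their R-hat (monitored quantities include contrasts)
        contrast_rhats = {}
        for pi, pname in enumerate(names):
            for a in range(G):
                for b in range(a + 1, G):
                    diff = group_nat[:, :, a, pi] - group_nat[:, :, b, pi]
                    label = f"contrast[{pname},{groups[a]}-{groups[b]}]"
                    contrast_rhats[label] = float(az.rhat(
                        az.convert_to_dataset(diff[:, :, None]))["x"].values[0])
        rhats.update(contrast_rhats)

        self.spec_ = spec
        self.groups_ = groups
        self.subjects_ = subjects
        self.param_names_ = names
        self.posterior_ = idata
        self.rhat_ = pd.Series(rhats, dtype=float)
        self.max_rhat_ = float(self.rhat_.max())
        self.converged_ = bool(self.max_rhat_ < mcmc.rhat_threshold)
        self.ess_ = ess_ds
        self.n_divergent_ = int(div.sum())
        self.data_hash_ = packed["data_hash"]
        self._packed = packed

        sp_mean = subject_nat.mean(axis=(0, 1))  # (S, K)
        nat5_mean = self._nat5(names, sp_mean[None])[0]
        self.subject_params_ = pd.DataFrame(
            nat5_mean, columns=list(PARAM_NAMES)).assign(
                subject_id=subjects,
                group=[packed["group_of"][s] for s in subjects],
        )[["subject_id", "group", *PARAM_NAMES]]
        self.group_means_ = pd.DataFrame(
            group_nat.mean(axis=(0, 1)), index=groups, columns=list(names))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                self.loo_ = az.loo(idata)
                self.ic_method_ = "loo"
            except Exception:
                self.loo_ = az.waic(idata)
                self.ic_method_ = "waic"
        return self

    @staticmethod
    def _nat5(names, nat):
        """Expand free natural params (..., S, K) to the full 5-column layout."""
        D, S = nat.shape[0], nat.shape[1]
        out = np.empty((D, S, 5))
        cols = {n: j for j, n in enumerate(names)}
        if "alpha" in cols:
            out[..., 0] = nat[..., cols["alpha"]]
            out[..., 1] = nat[..., cols["alpha"]]
        else:
            out[..., 0] = nat[..., cols["alpha_rew"]]
            out[..., 1] = nat[..., cols["alpha_pun"]]
        out[..., 2] = nat[..., cols["beta"]]
        out[..., 3] = nat[..., cols["kappa_stim"]] if "kappa_stim" in cols else 0.0
        out[..., 4] = nat[..., cols["kappa_side"]] if "kappa_side" in cols else 0.0
        return out

    # -- post-fit operations ----------------------------------------------

    def group_contrast(self, parameter: str, group_a: str, group_b: str,
                       masses: tuple[float, float] = (0.75, 0.95)
                       ) -> GroupContrast:
        """Posterior contrast of natural-scale group means (a minus b)."""
        self._check_fitted()
        if parameter not in self.param_names_:
            raise KeyError(f"unknown parameter {parameter!r}; "
                           f"model has {self.param_names_}")
        for g in (group_a, group_b):
            if g not in self.groups_:
                raise KeyError(f"unknown group {g!r}; fit has {self.groups_}")
        gm = self.posterior_.posterior["group_mean_natural"]
        da = gm.sel(group=group_a, param=parameter).values.ravel()
        db = gm.sel(group=group_b, param=parameter).values.ravel()
        diff = da - db
        lo75, hi75 = hdi(diff, masses[0])
        lo95, hi95 = hdi(diff, masses[1])
        return GroupContrast(
            parameter=parameter, group_a=group_a, group_b=group_b, draws=diff,
            hdi_75=(lo75, hi75), hdi_95=(lo95, hi95),
            excludes_zero_75=not lo75 <= 0.0 <= hi75,
            excludes_zero_95=not lo95 <= 0.0 <= hi95,
        )

    def log_likelihood_draws(self) -> np.ndarray:
        """Subject-wise pointwise log-likelihood draws, (chain, draw, subject)."""
        self._check_fitted()
        return self.posterior_.log_likelihood["choices"].values

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-trial log-likelihood at subject posterior-mean parameters."""
        self._check_fitted()
        from .models import sequence_log_likelihood, ParameterSet

        trials = validate_trials(X)
        total, n = 0.0, 0
        by_subj = dict(tuple(trials.groupby("subject_id", sort=False)))
        pmap = self.subject_params_.set_index("subject_id")
        for s, sub in by_subj.items():
            if s not in pmap.index:
                raise KeyError(f"subject {s!r} was not in the fitted cohort")
            p = ParameterSet(*(float(pmap.loc[s, n_]) for n_ in PARAM_NAMES))
            total += sequence_log_likelihood(
                sub.sort_values(["block", "trial"]).reset_index(drop=True),
                p, self.spec_, q0=self.q0,
                reset_between_blocks=self.reset_between_blocks)
            n += len(sub)
        return total / n

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("model is not fitted; call fit() first")


def fit_model(trials: pd.DataFrame, spec: ModelSpec | int,
              mcmc: McmcConfig | None = None,
              priors: PriorConfig | None = None,
              **kwargs) -> HierarchicalRLModel:
    """Fit one candidate model to a cohort trial table."""
    if isinstance(spec, ModelSpec):
        est = HierarchicalRLModel(model_id=spec.model_id, model_spec=spec,
                                  priors=priors, mcmc=mcmc, **kwargs)
    else:
        est = HierarchicalRLModel(model_id=int(spec), priors=priors,
                                  mcmc=mcmc, **kwargs)
    return est.fit(trials)


def compare_models(fits: dict | list) -> pd.DataFrame:
    """Rank fitted models by expected log predictive density.

    All fits must be of the same data (checked by hash).  Models are treated
    as equiprobable a priori: raw criteria are compared without prior
    weights.  The returned table is sorted best-first and includes the
    criterion, its standard error, and differences from the best model.
    """
    if isinstance(fits, list):
        fits = {f"model{f.model_id}": f for f in fits}
    hashes = {f.data_hash_ for f in fits.values()}
    if len(hashes) != 1:
        raise ValueError("model fits are not all of the same data "
                         f"(distinct data hashes: {len(hashes)})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = az.compare({k: f.posterior_ for k, f in fits.items()},
                           ic="loo", scale="log")
    table = table.rename_axis("model")
    table["winner"] = [i == 0 for i in range(len(table))]
    return table


def group_contrast(fit: HierarchicalRLModel, parameter: str, group_a: str,
                   group_b: str, masses=(0.75, 0.95)) -> GroupContrast:
    return fit.group_contrast(parameter, group_a, group_b, masses)
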