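"""Plain-text (YAML) configuration for the whole pipeline.

One file governs task design, cohort generation, priors, MCMC settings and
regressor options; CLI flags override file values.  All randomness flows
from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hb import McmcConfig, PriorConfig
from .models import MODEL_REGISTRY, ModelSpec
from .regressors import TrialTiming
from .task import CohortSpec, TaskConfig


@dataclass
class PipelineConfig:
    task: TaskConfig
    cohort: CohortSpec
    priors: PriorConfig
    mcmc: McmcConfig
    model_id: int = 6
    registry: dict[int, ModelSpec] = field(
        default_factory=lambda: dict(MODEL_REGISTRY))
    regressor_threshold: float = 0.5
    regressor_mean_center: bool = True
    timing: TrialTiming = field(default_factory=TrialTiming)
    master_seed: int = 0


def _model_from_mapping(d: dict) -> ModelSpec:
    return ModelSpec(
        model_id=int(d["model_id"]),
        split_learning_rates=bool(d["split_learning_rates"]),
        use_stim_stickiness=bool(d["use_stim_stickiness"]),
        use_side_stickiness=bool(d["use_side_stickiness"]),
    )


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline configuration, merging file values over defaults.

    ``overrides`` (e.g. from CLI flags) take precedence over the file.
    Unknown keys raise, so typos fail loudly.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for section, vals in overrides.items():
            if isinstance(vals, dict):
                raw.setdefault(section, {}).update(vals)
            else:
                raw[section] = vals

    known = {"task", "cohort", "priors", "mcmc", "model_id", "models",
             "regressors", "timing", "master_seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections/keys: {sorted(unknown)}")

    master_seed = int(raw.get("master_seed", 0))
    task = TaskConfig(**{**{"rng_seed": master_seed}, **raw.get("task", {})})

    cohort_raw = dict(raw.get("cohort", {}))
    model_id = int(raw.get("model_id", 6))
    registry = dict(MODEL_REGISTRY)
    for entry in raw.get("models", []) or []:
        spec = _model_from_mapping(entry)
        registry[spec.model_id] = spec
    gen_model = registry[int(cohort_raw.pop("generating_model", model_id))]
    for key in ("group_means", "group_sds"):
        if key in cohort_raw:
            cohort_raw[key] = {g: tuple(v) for g, v in cohort_raw[key].items()}
    cohort = CohortSpec(generating_model=gen_model,
                        **{**{"rng_seed": master_seed}, **cohort_raw})

    priors = PriorConfig(**raw.get("priors", {}))
    mcmc = McmcConfig(**{**{"seed": master_seed}, **raw.get("mcmc", {})})
    reg = raw.get("regressors", {})
    timing = TrialTiming(**raw.get("timing", {}))
    return PipelineConfig(
        task=task, cohort=cohort, priors=priors, mcmc=mcmc, model_id=model_id,
        registry=registry,
        regressor_threshold=float(reg.get("threshold", 0.5)),
        regressor_mean_center=bool(reg.get("mean_center", True)),
        timing=timing, master_seed=master_seed,
    )
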