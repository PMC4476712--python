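"""Reproducible simulate -> fit -> draw -> rank -> check pipeline.

A :class:`RunConfig` pins every choice (model, hierarchy size, seeds for
generation / fitting / drawing, draw count, suppression toggles, ranking
direction) and round-trips losslessly through YAML. :func:`run_pipeline`
executes the stages, writing each artifact (panel, truth, fit, draws,
ranks, posterior predictive checks) plus a manifest into the output
directory; identical configs reproduce identical artifacts byte for byte.
:func:`compare_models` lines up two or more runs that share a county
roster and reports rank-precision differences.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .draws import AgeSchedule, PosteriorDraws, draw_posterior, ypll75
from .fit import (
    FitResult,
    fit_cross_sectional,
    fit_joint_age,
    fit_joint_bivariate,
    fit_longitudinal,
    save_fit,
)
from .panel import GeoPanel, write_panel
from .ppc import run_ppc
from .ranking import RankSummary, precision_report, summarize_ranks
from .simulate import (
    AGE_JOINT,
    FPH_LBW_JOINT,
    HEALTH_DAYS_JOINT,
    INFANT_MORTALITY_LONGITUDINAL,
    GeneratorParams,
    inject_missingness,
    simulate_binomial_pair,
    simulate_mortality_panel,
    simulate_survey_means,
)

__all__ = ["RunConfig", "run_pipeline", "compare_models", "PipelineError"]

log = logging.getLogger("countyrank.pipeline")

#: named default generator parameter sets per model kind
_DEFAULT_PARAMS = {
    "cross": INFANT_MORTALITY_LONGITUDINAL,
    "longitudinal": INFANT_MORTALITY_LONGITUDINAL,
    "joint-age": AGE_JOINT,
    "joint-normal": HEALTH_DAYS_JOINT,
    "joint-binomial": FPH_LBW_JOINT,
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat, YAML-serializable description of one pipeline run."""

    model: str = "longitudinal"  # cross | longitudinal | joint-age | joint-normal | joint-binomial
    n_states: int = 51
    counties_per_state: int = 20
    n_draws: int = 1000
    seed_generate: int = 1
    seed_fit: int = 2
    seed_draw: int = 3
    seed_ppc: int = 4
    apply_suppression: bool = False
    direction: str = "higher_is_worse"
    out_dir: str = "run_out"
    generator_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in _DEFAULT_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")

    def generator_params(self) -> GeneratorParams:
        base = _DEFAULT_PARAMS[self.model]
        kw = {
            **{k: getattr(base, k) for k in base.__dataclass_fields__},
            "n_states": self.n_states,
            "counties_per_state": self.counties_per_state,
            **self.generator_overrides,
        }
        # YAML round-trips tuples as lists; GeneratorParams wants hashable tuples
        for k in ("beta", "tau2_state", "tau2_county", "counties_per_state", "pop_range"):
            if isinstance(kw.get(k), list):
                kw[k] = tuple(kw[k])
        return GeneratorParams(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return RunConfig(**doc)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _simulate_stage(config: RunConfig):
    params = config.generator_params()
    if config.model in ("cross", "longitudinal"):
        panel, truth = simulate_mortality_panel(
            params, times=(-3, -2, -1, 0), seed=config.seed_generate
        )
        if config.model == "cross":
            df = panel.data.loc[panel.data["t_or_age"] == 0].reset_index(drop=True)
            panel = GeoPanel(panel.hierarchy, df, "counts", panel.measure_name)
    elif config.model == "joint-age":
        panel, truth = simulate_mortality_panel(
            params, times=None, ages=tuple(range(1, 10)), seed=config.seed_generate
        )
    elif config.model == "joint-normal":
        panel, truth = simulate_survey_means(params, seed=config.seed_generate)
    else:
        panel, truth = simulate_binomial_pair(params, seed=config.seed_generate)
    if config.apply_suppression:
        rule = "vital" if panel.schema in ("counts",) else "brfss"
        panel = inject_missingness(panel, rule=rule)
    return panel, truth


def _fit_stage(config: RunConfig, panel: GeoPanel) -> FitResult:
    kw = {"seed": config.seed_fit, "direction": config.direction}
    if config.model == "cross":
        return fit_cross_sectional(panel, family="poisson", **kw)
    if config.model == "longitudinal":
        return fit_longitudinal(panel, **kw)
    if config.model == "joint-age":
        return fit_joint_age(panel, **kw)
    if config.model == "joint-normal":
        return fit_joint_bivariate(
            panel, family="normal_known_variance",
            measure_labels=("physical_days", "mental_days"), **kw,
        )
    return fit_joint_bivariate(
        panel, family="binomial", measure_labels=("fair_poor_health", "low_birth_weight"),
        **kw,
    )


def _draws_frame(all_draws: dict[str, PosteriorDraws]) -> pd.DataFrame:
    frames = []
    for key, d in all_draws.items():
        f = d.to_frame()
        f.insert(0, "measure", key)
        f.insert(1, "draw", np.arange(d.n_draws))
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns artifact paths plus in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"out_dir": str(out)}

    stage = "simulate"
    try:
        log.info("simulate: model=%s seed=%d", config.model, config.seed_generate)
        panel, truth = _simulate_stage(config)
        write_panel(panel, out / "panel.csv")
        truth.to_csv(out / "truth.csv", index=False)
        artifacts["panel"] = str(out / "panel.csv")
        artifacts["truth"] = str(out / "truth.csv")

        stage = "fit"
        log.info("fit: %d counties", panel.hierarchy.n_counties)
        fit = _fit_stage(config, panel)
        save_fit(fit, out / "fit.json")
        artifacts["fit"] = str(out / "fit.json")
        log.debug("loglik=%.4f grad_norm=%.2e", fit.loglik, fit.grad_norm)

        stage = "draw"
        all_draws = draw_posterior(fit, config.n_draws, seed=config.seed_draw)
        if config.model in ("joint-age",):
            schedule = AgeSchedule.from_panel(panel)
            all_draws["ypll75"] = ypll75(
                {k: v for k, v in all_draws.items() if k.startswith("age_")}, schedule
            )
        _draws_frame(all_draws).to_csv(out / "draws.csv", index=False)
        artifacts["draws"] = str(out / "draws.csv")

        stage = "rank"
        summaries: dict[str, RankSummary] = {}
        for key, d in all_draws.items():
            summaries[key] = summarize_ranks(d, direction=config.direction)
        ranks = pd.concat(
            [s.table.assign(measure=k) for k, s in summaries.items()],
            ignore_index=True,
        )
        ranks.to_csv(out / "ranks.csv", index=False)
        artifacts["ranks"] = str(out / "ranks.csv")

        stage = "ppc"
        ppc_rows = []
        for key, d in all_draws.items():
            if key == "ypll75":
                continue  # composite has no direct sampling model
            kw = {}
            if config.model in ("joint-normal", "joint-binomial"):
                kw["measure"] = 0 if key in ("physical_days", "fair_poor_health") else 1
            elif config.model == "joint-age":
                kw["index"] = int(key.split("_")[1])
            elif config.model == "longitudinal":
                kw["index"] = 0
            for res in run_ppc(d, panel, fit.spec.family, seed=config.seed_ppc, **kw):
                ppc_rows.append(
                    {"measure": key, "statistic": res.statistic,
                     "observed": res.observed, "p_value": res.p_value,
                     "poor_fit": res.poor_fit}
                )
        pd.DataFrame(ppc_rows).to_csv(out / "ppc.csv", index=False)
        artifacts["ppc"] = str(out / "ppc.csv")

        stage = "report"
        report = precision_report(summaries)
        report.to_csv(out / "report.csv", index=False)
        artifacts["report"] = str(out / "report.csv")

        manifest = {
            "config": asdict(config),
            "config_hash": config.content_hash(),
            "package_version": __version__,
            "loglik": float(fit.loglik),
            "converged": bool(fit.converged),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        artifacts["manifest"] = str(out / "manifest.json")
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(stage, str(e)) from e

    artifacts["summaries"] = summaries
    artifacts["fit_result"] = fit
    artifacts["panel_obj"] = panel
    return artifacts


def compare_models(summaries: dict[str, RankSummary]) -> dict:
    """Precision comparison across >= 2 runs sharing a county roster.

    Returns the high-certainty report table plus, for every pair of models,
    the mean per-county difference in assigned-quartile probability
    (first minus second, paired on counties).
    """
    if len(summaries) < 2:
        raise ValueError("need at least two rank summaries to compare")
    labels = list(summaries)
    rosters = [
        list(zip(s.table["state"], s.table["county"])) for s in summaries.values()
    ]
    for r in rosters[1:]:
        if r != rosters[0]:
            raise ValueError("rank summaries do not share a county roster")
    report = precision_report(summaries)
    paired = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            diff = (
                summaries[la].table["p_assigned"].to_numpy()
                - summaries[lb].table["p_assigned"].to_numpy()
            )
            paired[(la, lb)] = {
                "mean_diff": float(diff.mean()),
                "median_diff": float(np.median(diff)),
                "share_positive": float((diff > 0).mean()),
            }
    return {"report": report, "paired_differences": paired}
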