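"""End-to-end analysis pipeline.

``analyze`` wires the stages together per ecotype: spline fits ->
growth-series assembly -> RGR masking -> plasticity -> GRCs ->
stage classification -> stage-wise GRC tests -> ontogenetic-plasticity
permutation tests -> seed-count tolerance GLM.  Every stochastic stage is
seeded from the run configuration, so a rerun with the same inputs and
configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    GrowthSeries,
    GRCSeries,
    HarvestObservation,
    PlasticitySeries,
    RunConfig,
    SeedCount,
    StageSegmentation,
    StageTestResult,
)
from .errors import DefolError, FitError
from .grc import classify_stages, grc_series, predefoliation_grc, stage_grc_tests
from .tolerance import ToleranceFit, fit_seed_glm, pairwise_group_contrasts
from .trajectories import (
    assemble_growth_series,
    bootstrap_spread,
    defoliation_aligned_grid,
    fit_log_mass_spline,
    fit_trait_splines,
    mask_nonpositive_rgr,
    ontogenetic_plasticity_test,
    plasticity_series,
)

log = logging.getLogger("defol")

PLASTICITY_TRAITS = ("rgr", "nar", "sla", "lwr", "lar")
PERMUTATION_TRAITS = ("ln_shoot_mass", "leaf_area", "sla", "lwr")


@dataclass
class PipelineResult:
    """All result families of one pipeline run."""

    growth: dict[tuple[str, str], GrowthSeries] = field(default_factory=dict)
    plasticity: dict[tuple[str, str], PlasticitySeries] = field(default_factory=dict)
    grc: dict[str, GRCSeries] = field(default_factory=dict)
    predefoliation_grc: dict[str, dict[str, float]] = field(default_factory=dict)
    stages: dict[str, StageSegmentation] = field(default_factory=dict)
    stage_tests: dict[str, list[StageTestResult]] = field(default_factory=dict)
    permutation_tests: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    tolerance: ToleranceFit | None = None
    contrasts: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def _provenance(config: RunConfig) -> dict:
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"config": cfg, "config_sha256": digest, "seed": config.seed,
            "defol_version": __version__}


def analyze_ecotype(
    obs: list[HarvestObservation],
    config: RunConfig,
    result: PipelineResult,
) -> None:
    """Run the growth stages for the observations of a single ecotype."""
    eco = obs[0].ecotype
    t_def = config.defoliation_time_h
    by_treat = {
        tr: [o for o in obs if o.treatment == tr] for tr in ("control", "defoliated")
    }
    for tr, group in by_treat.items():
        if not group:
            raise FitError(f"{eco}: no observations for treatment {tr!r}")

    lo = max(min(o.time_h for o in g) for g in by_treat.values())
    hi = min(max(o.time_h for o in g) for g in by_treat.values())
    grid = defoliation_aligned_grid(lo, hi, t_def, config.grid_step_h)

    series = {}
    for tr, group in by_treat.items():
        split = t_def if tr == "defoliated" else None
        lnm = fit_log_mass_spline(group, config.smoothing, split_at=split)
        sla = fit_trait_splines(group, "sla", config.smoothing, split_at=None)
        lwr = fit_trait_splines(group, "lwr", config.smoothing, split_at=split)
        s = assemble_growth_series(lnm, sla, lwr, grid, ecotype=eco, treatment=tr)
        if config.with_spread:
            s.spread = {
                trait: bootstrap_spread(
                    group, trait, grid, config.smoothing,
                    split_at=split if trait != "sla" else None,
                    n_boot=config.n_bootstrap, seed=config.seed,
                )
                for trait in ("ln_shoot_mass", "sla", "lwr")
            }
        series[tr] = s
        result.growth[(eco, tr)] = s

    valid = mask_nonpositive_rgr(series["control"], series["defoliated"])
    for trait in PLASTICITY_TRAITS:
        result.plasticity[(eco, trait)] = plasticity_series(
            series["control"], series["defoliated"], trait, t_def, valid
        )
    result.grc[eco] = grc_series(
        series["control"], series["defoliated"], valid, t_def=t_def
    )
    result.predefoliation_grc[eco] = predefoliation_grc(
        series["control"], window=config.grc_window
    )
    seg = classify_stages(
        result.plasticity[(eco, "rgr")], t_def, epsilon=config.stage_epsilon
    )
    result.stages[eco] = seg
    result.stage_tests[eco] = stage_grc_tests(
        result.grc[eco], result.plasticity[(eco, "rgr")], seg, alpha=config.alpha
    )
    if config.n_permutations > 0:
        for k, trait in enumerate(PERMUTATION_TRAITS):
            stat, p = ontogenetic_plasticity_test(
                obs, trait, config, seed=config.seed + 7919 * (k + 1)
            )
            result.permutation_tests[(eco, trait)] = (stat, p)


def analyze(
    observations: list[HarvestObservation],
    seed_counts: list[SeedCount] | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on a harvest table and (optionally) seed counts.

    Without seed counts the fitness/tolerance stage is skipped with a
    warning; all growth stages still run.  Stage errors are re-raised with
    the ecotype and stage named.
    """
    config = config or RunConfig()
    result = PipelineResult(provenance=_provenance(config))
    ecotypes = sorted({o.ecotype for o in observations})
    if not ecotypes:
        raise FitError("no observations")
    for eco in ecotypes:
        eco_obs = [o for o in observations if o.ecotype == eco]
        try:
            analyze_ecotype(eco_obs, config, result)
        except DefolError as exc:
            raise type(exc)(f"[ecotype {eco}] {exc}") from exc
    if seed_counts:
        result.tolerance = fit_seed_glm(seed_counts)
        result.contrasts = pairwise_group_contrasts(result.tolerance, alpha=config.alpha)
    else:
        log.warning("no seed counts provided; tolerance stage skipped")
    return result


def summarize(result: PipelineResult) -> str:
    """Human-readable run summary."""
    lines = ["defol analysis summary", "======================", ""]
    for eco, seg in sorted(result.stages.items()):
        dur = seg.buffering_duration_h
        dur_s = f"{dur:.1f} h (t_eq = {seg.t_eq:.1f} h)" if dur is not None else "not reached"
        lines.append(f"{eco}: buffering duration {dur_s}")
        p = result.plasticity[(eco, "rgr")]
        ok = np.flatnonzero(p.valid)
        if ok.size:
            j = ok[-1]
            lines.append(
                f"{eco}: end-of-experiment RGR plasticity "
                f"{100 * p.value[j]:+.0f} % at {p.grid_t[j]:.0f} h"
            )
        tr = result.predefoliation_grc.get(eco)
        if tr:
            lines.append(
                f"{eco}: pre-defoliation GRCs  NAR {tr['nar']:+.2f}  "
                f"SLA {tr['sla']:+.2f}  LWR {tr['lwr']:+.2f}"
            )
    if result.permutation_tests:
        lines.append("")
        lines.append("ontogenetic plasticity (block permutation):")
        for (eco, trait), (stat, p) in sorted(result.permutation_tests.items()):
            lines.append(f"  {eco} {trait}: statistic {stat:.4g}, p = {p:.4f}")
    if result.tolerance is not None:
        fit = result.tolerance
        lines.append("")
        lines.append("seed-set tolerance (Poisson GLM):")
        for term, (chi2, df, p) in fit.lr_tests.items():
            lines.append(f"  {term}: LR chi2 = {chi2:.2f}, df = {df}, p = {p:.3g}")
        for eco in fit.ecotypes:
            lines.append(
                f"  {eco}: mean seeds control {fit.cell_means[(eco, 'control')]:.1f}, "
                f"defoliated {fit.cell_means[(eco, 'defoliated')]:.1f} "
                f"({fit.percent_change[eco]:+.1f} %)"
            )
        if result.contrasts is not None:
            letters = result.contrasts.attrs.get("letters", {})
            if letters:
                disp = ", ".join(f"{k}={v}" for k, v in sorted(letters.items()))
                lines.append(f"  letter display: {disp}")
    return "\n".join(lines) + "\n"
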