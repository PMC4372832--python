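"""Delimited-text I/O with row-level validation.

All tables are comma-separated UTF-8 with a mandatory header and '.' as the
decimal mark.  Real numbers are written with 17 significant digits so that a
write/read round trip is lossless to double precision; integers round-trip
bitwise.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .datatypes import HarvestObservation, RunConfig, SeedCount
from .errors import SchemaError, ValidationError

log = logging.getLogger("defol")

HARVEST_COLUMNS = (
    "plant_id",
    "ecotype",
    "treatment",
    "time_h",
    "leaf_mass_g",
    "support_mass_g",
    "repro_mass_g",
    "leaf_area_cm2",
)
SEED_COLUMNS = ("plant_id", "ecotype", "treatment", "seeds")

FLOAT_FORMAT = "%.17g"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_harvest_table(path, time_unit: str = "h") -> list[HarvestObservation]:
    """Read a harvest table into validated :class:`HarvestObservation` rows.

    ``time_unit`` may be ``"h"`` (hours since seedling emergence, the native
    convention) or ``"d"`` (days, converted as 1 day = 24 h).  Rows are
    preserved in input order.  A violated invariant raises
    :class:`ValidationError` naming the plant and the reason.
    """
    if time_unit not in ("h", "d"):
        raise ValidationError(f"time_unit must be 'h' or 'd', got {time_unit!r}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"{path}: cannot parse as CSV: {exc}") from exc
    _require_columns(df, HARVEST_COLUMNS, path)
    scale = 24.0 if time_unit == "d" else 1.0
    obs: list[HarvestObservation] = []
    seen_times: dict[str, float] = {}
    for i, row in df.iterrows():
        try:
            o = HarvestObservation(
                plant_id=str(row["plant_id"]),
                ecotype=str(row["ecotype"]),
                treatment=str(row["treatment"]),
                time_h=float(row["time_h"]) * scale,
                leaf_mass_g=float(row["leaf_mass_g"]),
                support_mass_g=float(row["support_mass_g"]),
                repro_mass_g=float(row["repro_mass_g"]),
                leaf_area_cm2=float(row["leaf_area_cm2"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path} row {i}: non-numeric field ({exc})",
                plant_id=str(row.get("plant_id", "?")),
            ) from exc
        try:
            o.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}", plant_id=exc.plant_id) from exc
        # destructive harvest: one plant is observed at exactly one time
        if o.plant_id in seen_times:
            raise ValidationError(
                f"{path} row {i}: plant {o.plant_id} appears more than once "
                "(destructive harvest implies a single observation per plant)",
                plant_id=o.plant_id,
            )
        seen_times[o.plant_id] = o.time_h
        obs.append(o)
    log.info("read %d harvest observations from %s", len(obs), path)
    return obs


def write_harvest_table(obs: Iterable[HarvestObservation], path) -> None:
    df = pd.DataFrame(
        [
            {
                "plant_id": o.plant_id,
                "ecotype": o.ecotype,
                "treatment": o.treatment,
                "time_h": o.time_h,
                "leaf_mass_g": o.leaf_mass_g,
                "support_mass_g": o.support_mass_g,
                "repro_mass_g": o.repro_mass_g,
                "leaf_area_cm2": o.leaf_area_cm2,
                "shoot_mass_g": o.shoot_mass_g,
            }
            for o in obs
        ],
        columns=list(HARVEST_COLUMNS) + ["shoot_mass_g"],
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_seed_table(path) -> list[SeedCount]:
    """Read a seed-count table; ``seeds`` must parse as a non-negative integer."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"{path}: cannot parse as CSV: {exc}") from exc
    _require_columns(df, SEED_COLUMNS, path)
    counts: list[SeedCount] = []
    for i, row in df.iterrows():
        raw = row["seeds"]
        try:
            seeds = int(raw)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path} row {i}: seeds must be an integer, got {raw!r}",
                plant_id=str(row.get("plant_id", "?")),
            ) from exc
        if float(raw) != seeds:
            raise ValidationError(
                f"{path} row {i}: seeds must be an integer, got {raw!r}",
                plant_id=str(row.get("plant_id", "?")),
            )
        c = SeedCount(
            plant_id=str(row["plant_id"]),
            ecotype=str(row["ecotype"]),
            treatment=str(row["treatment"]),
            seeds=seeds,
        )
        try:
            c.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}", plant_id=exc.plant_id) from exc
        counts.append(c)
    log.info("read %d seed counts from %s", len(counts), path)
    return counts


def write_seed_table(counts: Iterable[SeedCount], path) -> None:
    df = pd.DataFrame(
        [
            {
                "plant_id": c.plant_id,
                "ecotype": c.ecotype,
                "treatment": c.treatment,
                "seeds": c.seeds,
            }
            for c in counts
        ],
        columns=list(SEED_COLUMNS),
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result families


def write_results(result, out_dir) -> dict[str, Path]:
    """Write every result family of a :class:`~defol.pipeline.PipelineResult`
    as one CSV per family under ``out_dir``.

    Returns a mapping family name -> written path.  Empty families produce
    header-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for (eco, treat), s in sorted(result.growth.items()):
        for j, t in enumerate(s.grid_t):
            rows.append(
                {
                    "ecotype": eco,
                    "treatment": treat,
                    "time_h": t,
                    "ln_shoot_mass": s.ln_shoot_mass[j],
                    "rgr_g_g_h": s.rgr[j],
                    "rgr_mg_g_h": 1000.0 * s.rgr[j],
                    "sla_cm2_g": s.sla[j],
                    "lwr_g_g": s.lwr[j],
                    "nar_g_cm2_h": s.nar[j],
                    "lar_cm2_g": s.lar[j],
                }
            )
    traj_cols = [
        "ecotype", "treatment", "time_h", "ln_shoot_mass", "rgr_g_g_h",
        "rgr_mg_g_h", "sla_cm2_g", "lwr_g_g", "nar_g_cm2_h", "lar_cm2_g",
    ]
    paths["trajectories"] = out / "trajectories.csv"
    pd.DataFrame(rows, columns=traj_cols).to_csv(
        paths["trajectories"], index=False, float_format=FLOAT_FORMAT
    )

    rows = []
    for (eco, trait), p in sorted(result.plasticity.items()):
        for j, t in enumerate(p.grid_t):
            rows.append(
                {
                    "ecotype": eco,
                    "trait": trait,
                    "time_h": t,
                    "plasticity_fraction": p.value[j],
                    "plasticity_percent": 100.0 * p.value[j],
                    "valid": bool(p.valid[j]),
                }
            )
    plast_cols = ["ecotype", "trait", "time_h", "plasticity_fraction",
                  "plasticity_percent", "valid"]
    paths["plasticity"] = out / "plasticity.csv"
    pd.DataFrame(rows, columns=plast_cols).to_csv(
        paths["plasticity"], index=False, float_format=FLOAT_FORMAT
    )

    rows = []
    for eco, g in sorted(result.grc.items()):
        for j, t in enumerate(g.grid_t):
            rows.append(
                {
                    "ecotype": eco,
                    "time_h": t,
                    "grc_nar": g.grc_nar[j],
                    "grc_sla": g.grc_sla[j],
                    "grc_lwr": g.grc_lwr[j],
                    "delta_ln_rgr": g.delta_ln_rgr[j],
                    "valid": bool(g.valid[j]),
                }
            )
    grc_cols = ["ecotype", "time_h", "grc_nar", "grc_sla", "grc_lwr",
                "delta_ln_rgr", "valid"]
    paths["grc"] = out / "grc.csv"
    pd.DataFrame(rows, columns=grc_cols).to_csv(
        paths["grc"], index=False, float_format=FLOAT_FORMAT
    )

    rows = []
    for eco, triple in sorted(result.predefoliation_grc.items()):
        rows.append({"ecotype": eco, "grc_nar": triple["nar"],
                     "grc_sla": triple["sla"], "grc_lwr": triple["lwr"]})
    paths["predefoliation_grc"] = out / "predefoliation_grc.csv"
    pd.DataFrame(rows, columns=["ecotype", "grc_nar", "grc_sla", "grc_lwr"]).to_csv(
        paths["predefoliation_grc"], index=False, float_format=FLOAT_FORMAT
    )

    rows = []
    for eco, seg in sorted(result.stages.items()):
        for stage, idx in seg.stage_indices.items():
            if len(idx) == 0:
                continue
            rows.append(
                {
                    "ecotype": eco,
                    "stage": stage,
                    "t_start_h": seg.grid_t[idx[0]],
                    "t_end_h": seg.grid_t[idx[-1]],
                    "n_grid_points": len(idx),
                    "t_eq_h": seg.t_eq,
                    "buffering_duration_h": seg.buffering_duration_h,
                }
            )
    stage_cols = ["ecotype", "stage", "t_start_h", "t_end_h", "n_grid_points",
                  "t_eq_h", "buffering_duration_h"]
    paths["stages"] = out / "stages.csv"
    pd.DataFrame(rows, columns=stage_cols).to_csv(
        paths["stages"], index=False, float_format=FLOAT_FORMAT
    )

    rows = []
    for eco, tests in sorted(result.stage_tests.items()):
        for r in tests:
            rows.append(
                {
                    "ecotype": r.ecotype,
                    "stage": r.stage,
                    "component": r.component,
                    "n": r.n,
                    "median": r.median,
                    "q1": r.q1,
                    "q3": r.q3,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                }
            )
    st_cols = ["ecotype", "stage", "component", "n", "median", "q1", "q3",
               "test", "statistic", "p_value"]
    paths["stage_tests"] = out / "stage_tests.csv"
    pd.DataFrame(rows, columns=st_cols).to_csv(
        paths["stage_tests"], index=False, float_format=FLOAT_FORMAT
    )

    rows = []
    for (eco, trait), (stat, p) in sorted(result.permutation_tests.items()):
        rows.append({"ecotype": eco, "trait": trait, "statistic": stat, "p_value": p})
    paths["permutation_tests"] = out / "permutation_tests.csv"
    pd.DataFrame(rows, columns=["ecotype", "trait", "statistic", "p_value"]).to_csv(
        paths["permutation_tests"], index=False, float_format=FLOAT_FORMAT
    )

    if result.tolerance is not None:
        fit = result.tolerance
        rows = [
            {"term": term, "lr_chi2": chi2, "df": df_, "p_value": p}
            for term, (chi2, df_, p) in fit.lr_tests.items()
        ]
        paths["tolerance_terms"] = out / "tolerance_terms.csv"
        pd.DataFrame(rows, columns=["term", "lr_chi2", "df", "p_value"]).to_csv(
            paths["tolerance_terms"], index=False, float_format=FLOAT_FORMAT
        )
        rows = []
        for eco in sorted({e for (e, _) in fit.cell_means}):
            rows.append(
                {
                    "ecotype": eco,
                    "mean_control": fit.cell_means[(eco, "control")],
                    "mean_defoliated": fit.cell_means[(eco, "defoliated")],
                    "tolerance_slope": fit.slopes[eco],
                    "percent_change": fit.percent_change[eco],
                }
            )
        paths["tolerance_cells"] = out / "tolerance_cells.csv"
        pd.DataFrame(
            rows,
            columns=["ecotype", "mean_control", "mean_defoliated",
                     "tolerance_slope", "percent_change"],
        ).to_csv(paths["tolerance_cells"], index=False, float_format=FLOAT_FORMAT)
        if result.contrasts is not None:
            paths["tolerance_contrasts"] = out / "tolerance_contrasts.csv"
            result.contrasts.to_csv(
                paths["tolerance_contrasts"], index=False, float_format=FLOAT_FORMAT
            )

    log.info("wrote %d result files to %s", len(paths), out)
    return paths


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent keys fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    try:
        return RunConfig.from_dict(data)
    except TypeError as exc:
        raise SchemaError(f"{path}: unknown config field ({exc})") from exc


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
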