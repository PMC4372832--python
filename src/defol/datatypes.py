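"""Domain types for destructive-harvest growth experiments.

The data model follows classical whole-plant growth analysis: each plant is
destructively harvested once, separated into leaves, support tissue (stems,
petioles, pedicels) and reproductive tissue (flowers, fruits), dried and
weighed, and its total one-sided leaf area recorded.  Time is measured in
hours since seedling emergence.  Derived quantities:

    shoot mass = leaf + support + reproductive dry mass   (g)
    SLA  = leaf area / leaf mass                          (cm^2 g^-1)
    LWR  = leaf mass / shoot mass                         (g g^-1)
    RGR  = d ln(shoot mass) / dt                          (g g^-1 h^-1)
    NAR  = RGR / (SLA * LWR)                              (g cm^-2 h^-1)
    LAR  = SLA * LWR                                      (cm^2 g^-1)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError

TREATMENTS = ("control", "defoliated")

#: Default ecotype labels (Patria Nueva, fast growing; Santo Domingo, slow
#: growing).  The label set is extensible: any non-empty string is accepted.
DEFAULT_ECOTYPES = ("PN", "SD")


@dataclass(frozen=True)
class HarvestObservation:
    """One destructively harvested plant."""

    plant_id: str
    ecotype: str
    treatment: str
    time_h: float
    leaf_mass_g: float
    support_mass_g: float
    repro_mass_g: float
    leaf_area_cm2: float

    @property
    def shoot_mass_g(self) -> float:
        return self.leaf_mass_g + self.support_mass_g + self.repro_mass_g

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any type invariant is violated."""
        pid = str(self.plant_id)
        if not pid:
            raise ValidationError("empty plant_id", plant_id=pid)
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}",
                plant_id=pid,
            )
        if not str(self.ecotype):
            raise ValidationError("empty ecotype label", plant_id=pid)
        if not np.isfinite(self.time_h) or self.time_h <= 0:
            raise ValidationError(
                f"time_h must be strictly positive, got {self.time_h}", plant_id=pid
            )
        for name in ("leaf_mass_g", "support_mass_g", "repro_mass_g", "leaf_area_cm2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{name} must be finite and >= 0, got {v}", plant_id=pid
                )
        if self.shoot_mass_g <= 0:
            raise ValidationError("shoot mass must be > 0", plant_id=pid)
        # leaf area and leaf mass vanish together (an area without dry mass,
        # or dry mass with no area, is a measurement inconsistency)
        if (self.leaf_mass_g == 0) != (self.leaf_area_cm2 == 0):
            raise ValidationError(
                "leaf_area_cm2 = 0 exactly when leaf_mass_g = 0 "
                f"(got mass {self.leaf_mass_g}, area {self.leaf_area_cm2})",
                plant_id=pid,
            )


@dataclass(frozen=True)
class SeedCount:
    """Total seed number of one plant at the end of the experiment."""

    plant_id: str
    ecotype: str
    treatment: str
    seeds: int

    def validate(self) -> None:
        pid = str(self.plant_id)
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}",
                plant_id=pid,
            )
        if not isinstance(self.seeds, (int, np.integer)):
            raise ValidationError(
                f"seeds must be an integer, got {self.seeds!r}", plant_id=pid
            )
        if self.seeds < 0:
            raise ValidationError(
                f"seeds must be >= 0, got {self.seeds}", plant_id=pid
            )


@dataclass(frozen=True)
class SmoothingPolicy:
    """How trajectory smoothing splines choose their penalty.

    ``lam = None`` selects the smoothing parameter by generalized
    cross-validation (the default); a float fixes the penalty.
    """

    lam: float | None = None


@dataclass
class RunConfig:
    """Run-level configuration of the analysis pipeline."""

    defoliation_time_h: float = 1464.0
    defoliation_fraction: float = 0.35
    grid_step_h: float = 6.0
    smoothing: SmoothingPolicy = field(default_factory=SmoothingPolicy)
    stage_epsilon: float = 0.05
    n_permutations: int = 999
    seed: int = 0
    alpha: float = 0.05
    grc_window: tuple[float, float] = (1416.0, 1446.0)
    n_bootstrap: int = 199
    with_spread: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.defoliation_fraction < 1:
            raise ValidationError(
                f"defoliation_fraction must be in (0, 1), got {self.defoliation_fraction}"
            )
        if self.grid_step_h <= 0:
            raise ValidationError(f"grid_step_h must be > 0, got {self.grid_step_h}")
        if self.stage_epsilon <= 0:
            raise ValidationError(f"stage_epsilon must be > 0, got {self.stage_epsilon}")
        if self.defoliation_time_h <= 0:
            raise ValidationError("defoliation_time_h must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.grc_window[0] >= self.grc_window[1]:
            raise ValidationError("grc_window must be an increasing interval")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["grc_window"] = list(self.grc_window)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "smoothing" in d and isinstance(d["smoothing"], dict):
            d["smoothing"] = SmoothingPolicy(**d["smoothing"])
        if "grc_window" in d:
            d["grc_window"] = tuple(d["grc_window"])
        return cls(**d)


#: Trait names a GrowthSeries houses, in canonical order.
SERIES_TRAITS = ("ln_shoot_mass", "rgr", "sla", "lwr", "nar", "lar")


@dataclass
class GrowthSeries:
    """Fitted trajectories for one ecotype x treatment on a common grid.

    ``rgr = nar * sla * lwr`` and ``lar = sla * lwr`` hold exactly at every
    grid point because NAR and LAR are defined as those ratios/products.
    """

    ecotype: str
    treatment: str
    grid_t: np.ndarray
    ln_shoot_mass: np.ndarray
    rgr: np.ndarray
    sla: np.ndarray
    lwr: np.ndarray
    nar: np.ndarray
    lar: np.ndarray
    #: optional pointwise bootstrap SD for ln mass, SLA and LWR
    spread: dict[str, np.ndarray] | None = None

    def trait(self, name: str) -> np.ndarray:
        if name not in SERIES_TRAITS:
            raise KeyError(f"unknown trait {name!r}; expected one of {SERIES_TRAITS}")
        return getattr(self, name)


@dataclass
class PlasticitySeries:
    """Signed fractional difference (defoliated - control)/control of a trait
    over the post-defoliation grid.  ``value`` is NaN wherever ``valid`` is
    False (masked RGR points or non-positive control values)."""

    trait: str
    ecotype: str
    grid_t: np.ndarray
    value: np.ndarray
    valid: np.ndarray

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.value


@dataclass
class GRCSeries:
    """Growth response coefficients of NAR, SLA and LWR over the
    post-defoliation grid, with the shared denominator
    ``delta_ln_rgr = ln RGR_D - ln RGR_C``.

    Wherever ``valid`` is True, ``grc_nar + grc_sla + grc_lwr = 1`` to within
    1e-9 (the log-ratio identity).  Points with a degenerate denominator
    (|delta_ln_rgr| < 1e-6) or non-positive RGR are masked.
    """

    ecotype: str
    grid_t: np.ndarray
    grc_nar: np.ndarray
    grc_sla: np.ndarray
    grc_lwr: np.ndarray
    delta_ln_rgr: np.ndarray
    valid: np.ndarray


STAGES = ("buffering", "steady", "overcompensatory")


@dataclass
class StageSegmentation:
    """Partition of the unmasked post-defoliation grid into the buffering,
    steady and overcompensatory states of the RGR plasticity trajectory."""

    ecotype: str
    t_def: float
    t_eq: float | None
    epsilon: float
    grid_t: np.ndarray
    #: stage name -> sorted array of grid indices (into grid_t)
    stage_indices: dict[str, np.ndarray]

    @property
    def buffering_duration_h(self) -> float | None:
        if self.t_eq is None:
            return None
        return self.t_eq - self.t_def


@dataclass(frozen=True)
class StageTestResult:
    """One-sample test of a GRC component (or RGR plasticity) against zero
    within one ontogenetic stage."""

    ecotype: str
    stage: str
    component: str
    n: int
    median: float
    q1: float
    q3: float
    test: str  # "t" or "wilcoxon"
    statistic: float
    p_value: float
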