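"""Trajectory fitting and ontogenetic plasticity.

Trait trajectories are modelled with cubic smoothing splines; the smoothing
penalty is chosen by generalized cross-validation (GCV) unless the policy
fixes it.  RGR is the analytical first derivative of the ln(shoot mass)
spline, so no functional form (exponential, logistic, ...) is imposed on
growth.  Destructive harvests put several plants at the same time point;
the penalized least-squares problem is then equivalent to fitting the
per-time means with weights equal to the replicate counts, which is how the
fits are computed.

Because a defoliation event removes biomass instantaneously, trajectories of
the defoliated group can be fitted piecewise with a break at the defoliation
time: one smoother before the shock, one after, so the discontinuity is
represented instead of smeared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .datatypes import (
    GrowthSeries,
    PlasticitySeries,
    RunConfig,
    SmoothingPolicy,
)
from .errors import DomainError, FitError

log = logging.getLogger("defol")

_EDGE_TOL = 1e-9  # slack when checking that a query lies in the fitted range


def _aggregate_replicates(t: np.ndarray, y: np.ndarray):
    """Collapse replicate observations at identical times to weighted means."""
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    ut, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    sums = np.zeros_like(ut)
    np.add.at(sums, inverse, y)
    return ut, sums / counts, counts.astype(float)


@dataclass
class SmoothFit:
    """A fitted cubic smoothing spline with its analytical derivative."""

    spline: object
    deriv: object
    t_min: float
    t_max: float
    clip: tuple[float, float] | None = None

    def _check(self, t: np.ndarray) -> None:
        if np.any(t < self.t_min - _EDGE_TOL) or np.any(t > self.t_max + _EDGE_TOL):
            raise DomainError(
                f"query time outside fitted range [{self.t_min}, {self.t_max}]"
            )

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        self._check(t)
        v = self.spline(t)
        if self.clip is not None:
            v = np.clip(v, self.clip[0], self.clip[1])
        return v

    def derivative(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        self._check(t)
        return self.deriv(t)


@dataclass
class PiecewiseSmoothFit:
    """Two smoothing splines joined (discontinuously) at a break time.

    Queries at exactly the break evaluate the post-break segment: the shock
    is treated as already applied at the defoliation instant.
    """

    pre: SmoothFit | None
    post: SmoothFit
    t_break: float

    @property
    def t_min(self) -> float:
        return self.pre.t_min if self.pre is not None else self.post.t_min

    @property
    def t_max(self) -> float:
        return self.post.t_max

    def _split(self, t: np.ndarray):
        before = t < self.t_break
        if np.any(before) and self.pre is None:
            raise DomainError("no pre-break segment fitted")
        return before

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        before = self._split(t)
        out = np.empty_like(t)
        if np.any(before):
            out[before] = self.pre(t[before])
        if np.any(~before):
            out[~before] = self.post(t[~before])
        return out

    def derivative(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        before = self._split(t)
        out = np.empty_like(t)
        if np.any(before):
            out[before] = self.pre.derivative(t[before])
        if np.any(~before):
            out[~before] = self.post.derivative(t[~before])
        return out


def _fit_scatter(
    t: np.ndarray,
    y: np.ndarray,
    policy: SmoothingPolicy,
    clip: tuple[float, float] | None = None,
) -> SmoothFit:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ut, ym, w = _aggregate_replicates(t, y)
    if ut.size < 5:
        raise FitError(
            f"need >= 5 distinct observation times for a smoothing spline, got {ut.size}"
        )
    lam = policy.lam if policy.lam is not None else _gcv_lambda(t, y)
    spline = make_smoothing_spline(ut, ym, w=w, lam=lam)
    # The penalized solution satisfies natural boundary conditions (second
    # derivative zero at the ends), which biases the endpoint derivative
    # whenever the true trajectory is curved there.  Re-interpolating the
    # smoothed knot values with a not-a-knot cubic keeps the fitted curve
    # and removes that boundary bias from the derivative.
    final = CubicSpline(ut, spline(ut), bc_type="not-a-knot")
    return SmoothFit(
        spline=final,
        deriv=final.derivative(),
        t_min=float(ut[0]),
        t_max=float(ut[-1]),
        clip=clip,
    )


def _obs_arrays(obs, trait: str):
    """Per-plant (time, value) pairs for a trait, with exclusion logging."""
    t, y, excluded = [], [], 0
    for o in obs:
        if trait == "ln_shoot_mass":
            m = o.shoot_mass_g
            if m <= 0:
                raise DomainError(f"plant {o.plant_id}: non-positive shoot mass")
            v = np.log(m)
        elif trait == "sla":
            if o.leaf_mass_g <= 0:
                excluded += 1
                continue
            v = o.leaf_area_cm2 / o.leaf_mass_g
        elif trait == "lwr":
            v = o.leaf_mass_g / o.shoot_mass_g
        elif trait == "leaf_area":
            v = o.leaf_area_cm2
        else:
            raise KeyError(f"unknown trait {trait!r}")
        t.append(o.time_h)
        y.append(v)
    if excluded:
        log.info("trait %s: excluded %d plants with zero leaf mass", trait, excluded)
    if not t:
        raise FitError(f"trait {trait}: all plants excluded")
    return np.asarray(t), np.asarray(y)


def fit_log_mass_spline(
    obs,
    policy: SmoothingPolicy = SmoothingPolicy(),
    split_at: float | None = None,
) -> SmoothFit | PiecewiseSmoothFit:
    """Fit a cubic smoothing spline to (time, ln shoot mass).

    Requires at least 8 observations spanning at least 5 distinct times and
    strictly positive shoot masses.  With ``split_at`` set (the defoliation
    time for a defoliated group), pre- and post-shock segments are fitted
    separately so the instantaneous biomass loss is not smoothed over.  The
    returned object exposes the fit and its first derivative (RGR) at any
    time within the data range.
    """
    if len(obs) < 8:
        raise FitError(f"need >= 8 observations, got {len(obs)}")
    t, y = _obs_arrays(obs, "ln_shoot_mass")
    if split_at is None:
        return _fit_scatter(t, y, policy)
    return _fit_piecewise(t, y, policy, split_at, clip=None)


def _fit_piecewise(t, y, policy, split_at, clip):
    post_sel = t >= split_at
    if not np.any(post_sel):
        raise FitError("no observations at or after the split time")
    pre = None
    if np.any(~post_sel):
        pre = _fit_scatter(t[~post_sel], y[~post_sel], policy, clip=clip)
        # the pre-shock segment is valid (by cubic extrapolation of the
        # smoother) right up to the break instant
        pre.t_max = max(pre.t_max, float(split_at))
    post = _fit_scatter(t[post_sel], y[post_sel], policy, clip=clip)
    return PiecewiseSmoothFit(pre=pre, post=post, t_break=float(split_at))


def fit_trait_splines(
    obs,
    trait: str,
    policy: SmoothingPolicy = SmoothingPolicy(),
    split_at: float | None = None,
) -> SmoothFit | PiecewiseSmoothFit:
    """Fit a cubic smoothing spline through per-plant trait values.

    ``trait`` is one of ``sla`` (leaf area / leaf mass), ``lwr``
    (leaf mass / shoot mass) or ``leaf_area``.  SLA is undefined for plants
    without leaves; such plants are excluded with a logged count.  LWR
    predictions are clipped to (0, 1] (a dry-mass fraction cannot exceed 1;
    observation noise can push the unconstrained smoother above it).
    """
    if trait not in ("sla", "lwr", "leaf_area"):
        raise KeyError(f"unknown trait {trait!r}")
    t, y = _obs_arrays(obs, trait)
    clip = (np.finfo(float).tiny, 1.0) if trait == "lwr" else None
    if split_at is None:
        return _fit_scatter(t, y, policy, clip=clip)
    return _fit_piecewise(t, y, policy, split_at, clip=clip)


def assemble_growth_series(
    ln_mass_fit,
    sla_fit,
    lwr_fit,
    grid: np.ndarray,
    ecotype: str = "",
    treatment: str = "",
) -> GrowthSeries:
    """Evaluate all fitted trajectories on a common grid and derive
    NAR = RGR / (SLA * LWR) and LAR = SLA * LWR.

    The decomposition RGR = NAR * SLA * LWR holds exactly at every grid
    point by construction.  A grid outside the common fitted range raises
    :class:`DomainError`.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise DomainError("grid must be a non-empty strictly increasing 1-D array")
    ln_mass = ln_mass_fit(grid)
    rgr = ln_mass_fit.derivative(grid)
    sla = sla_fit(grid)
    lwr = lwr_fit(grid)
    lar = sla * lwr
    nar = rgr / lar
    return GrowthSeries(
        ecotype=ecotype,
        treatment=treatment,
        grid_t=grid,
        ln_shoot_mass=ln_mass,
        rgr=rgr,
        sla=sla,
        lwr=lwr,
        nar=nar,
        lar=lar,
    )


def mask_nonpositive_rgr(series_c: GrowthSeries, series_d: GrowthSeries) -> np.ndarray:
    """Boolean validity mask over the shared grid: False wherever either
    series has a non-positive predicted RGR.

    Negative predicted RGR can occur at the tail of a declining trajectory
    (smoother overshoot); such points are excluded from plasticity and GRC
    estimation.  The number of masked points is logged.
    """
    if not np.array_equal(series_c.grid_t, series_d.grid_t):
        raise DomainError("control and defoliated series must share a grid")
    valid = (series_c.rgr > 0) & (series_d.rgr > 0)
    n_masked = int(np.sum(~valid))
    if n_masked:
        log.info(
            "%s: masked %d grid point(s) with non-positive predicted RGR",
            series_c.ecotype,
            n_masked,
        )
    return valid


def plasticity_series(
    series_c: GrowthSeries,
    series_d: GrowthSeries,
    trait: str,
    t_def: float,
    valid: np.ndarray | None = None,
) -> PlasticitySeries:
    """Signed plasticity (X_D - X_C)/X_C of a trait over the post-defoliation
    grid.  Points where the validity mask is False, or where the control
    value is not positive, are NaN-masked (the latter with a warning)."""
    if not np.array_equal(series_c.grid_t, series_d.grid_t):
        raise DomainError("control and defoliated series must share a grid")
    grid = series_c.grid_t
    if valid is None:
        valid = np.ones(grid.shape, dtype=bool)
    post = grid >= t_def
    g = grid[post]
    xc = series_c.trait(trait)[post]
    xd = series_d.trait(trait)[post]
    ok = valid[post].copy()
    bad_control = ok & (xc <= 0)
    if np.any(bad_control):
        log.warning(
            "%s %s: control value <= 0 at %d unmasked point(s); masked",
            series_c.ecotype,
            trait,
            int(np.sum(bad_control)),
        )
        ok &= ~bad_control
    value = np.full(g.shape, np.nan)
    value[ok] = (xd[ok] - xc[ok]) / xc[ok]
    return PlasticitySeries(
        trait=trait, ecotype=series_c.ecotype, grid_t=g, value=value, valid=ok
    )


def signed_plasticity(defoliated: float, control: float) -> float:
    """Scalar signed plasticity (X_D - X_C)/X_C; the conventional
    "signed percentage" is 100x this value."""
    if control == 0:
        raise DomainError("control value must be non-zero")
    return (defoliated - control) / control


# ---------------------------------------------------------------------------
# ontogenetic plasticity permutation test


def _gcv_lambda(t: np.ndarray, y: np.ndarray) -> float:
    """Generalized cross-validation choice of the smoothing penalty for a
    scatter with replicate observations at shared times.

    The penalized least-squares fit only sees the per-time weighted means,
    but the cross-validated residual sum of squares must include the
    within-time replicate scatter, otherwise replicate noise is invisible
    and GCV near-interpolates.  For each candidate penalty on a log-spaced
    grid, the hat matrix of the aggregated problem is obtained in a single
    matrix-valued spline fit (columns = responses to unit vectors) and

        GCV(lam) = N * [RSS_means(lam) + SS_within] / (N - tr H(lam))^2

    with N the total number of observations.
    """
    ut, ym, w = _aggregate_replicates(t, y)
    n = ut.size
    n_total = t.size
    # within-time scatter, constant in lam
    means_back = ym[np.searchsorted(ut, t)]
    ss_within = float(np.sum((y - means_back) ** 2))
    eye = np.eye(n)
    best_lam, best_gcv = None, np.inf
    for lam in np.logspace(-6.0, 12.0, 46):
        s = make_smoothing_spline(ut, eye, w=w, lam=float(lam), axis=0)
        hat = s(ut)
        rss_means = float(np.sum(w * (ym - hat @ ym) ** 2))
        edf = float(np.trace(hat))
        denom = n_total - edf
        if denom <= 1e-9:
            continue
        gcv = n_total * (rss_means + ss_within) / (denom * denom)
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, float(lam)
    if best_lam is None:
        raise FitError("GCV search failed: no admissible smoothing penalty")
    return best_lam


def ontogenetic_plasticity_test(
    obs,
    trait: str,
    config: RunConfig,
    n_perm: int | None = None,
    seed: int | None = None,
    grid: np.ndarray | None = None,
):
    """Block-permutation test for ontogenetic plasticity of one trait.

    The null hypothesis is that the control and defoliated trajectories of
    the trait coincide over the post-defoliation window.  The statistic is
    the integral over the shared post-defoliation grid of the squared
    difference between the treatment-specific smoothing-spline fits.  The
    null distribution is built by permuting treatment labels within
    harvest-time blocks, which preserves the harvest design; harvest times
    containing only one treatment cannot inform the contrast and are dropped
    with a warning.  Returns ``(statistic, p_value)`` with
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.

    When the policy selects GCV, the smoothing penalty is chosen once on the
    pooled, treatment-blind scatter and then held fixed for every
    treatment-specific fit.  The pooled penalty is invariant under label
    permutation, so the test remains exact, and both groups are smoothed
    identically.
    """
    n_perm = config.n_permutations if n_perm is None else n_perm
    if n_perm < 99:
        raise DomainError(f"n_perm must be >= 99, got {n_perm}")
    seed = config.seed if seed is None else seed
    t_def = config.defoliation_time_h

    sel = [o for o in obs if o.time_h >= t_def]
    trait_key = "ln_shoot_mass" if trait == "ln_shoot_mass" else trait
    t_all, y_all = [], []
    labels = []
    for o in sel:
        if trait_key == "sla" and o.leaf_mass_g <= 0:
            continue
        tt, yy = _obs_arrays([o], trait_key)
        t_all.append(tt[0])
        y_all.append(yy[0])
        labels.append(o.treatment)
    t_all = np.asarray(t_all)
    y_all = np.asarray(y_all)
    labels = np.asarray(labels)

    # harvest-time blocks with both treatments present
    kept = np.zeros(t_all.shape, dtype=bool)
    dropped_blocks = 0
    blocks: list[np.ndarray] = []
    for ut in np.unique(t_all):
        idx = np.flatnonzero(t_all == ut)
        if len(set(labels[idx])) < 2:
            dropped_blocks += 1
            continue
        kept[idx] = True
        blocks.append(idx)
    if dropped_blocks:
        log.warning(
            "plasticity test (%s): dropped %d single-treatment harvest block(s)",
            trait,
            dropped_blocks,
        )
    if not blocks:
        raise FitError("plasticity test: no harvest block contains both treatments")
    # re-index onto the kept subset
    keep_idx = np.flatnonzero(kept)
    remap = {old: new for new, old in enumerate(keep_idx)}
    blocks = [np.asarray([remap[i] for i in b]) for b in blocks]
    t_all, y_all, labels = t_all[kept], y_all[kept], labels[kept]

    if grid is None:
        lo, hi = t_all.min(), t_all.max()
        grid = defoliation_aligned_grid(lo, hi, t_def, config.grid_step_h)
    grid = np.asarray(grid, dtype=float)

    policy = config.smoothing
    if policy.lam is None:
        if np.unique(t_all).size < 5:
            raise FitError("plasticity test: fewer than 5 distinct harvest times")
        policy = SmoothingPolicy(lam=_gcv_lambda(t_all, y_all))

    def statistic(lab: np.ndarray) -> float:
        is_d = lab == "defoliated"
        fc = _fit_scatter(t_all[~is_d], y_all[~is_d], policy)
        fd = _fit_scatter(t_all[is_d], y_all[is_d], policy)
        diff = fd(grid) - fc(grid)
        return float(np.trapezoid(diff * diff, grid))

    obs_stat = statistic(labels)
    rng = np.random.default_rng(seed)
    count = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        for b in blocks:
            perm_labels[b] = labels[b][rng.permutation(len(b))]
        if statistic(perm_labels) >= obs_stat:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return obs_stat, p


def defoliation_aligned_grid(lo: float, hi: float, t_def: float, step: float) -> np.ndarray:
    """Strictly increasing grid with step ``step`` containing ``t_def`` as a
    grid point (when it lies in [lo, hi]) and covering [lo, hi]."""
    if hi <= lo:
        raise DomainError("empty time range")
    below = np.arange(t_def, lo - 1e-9, -step)[::-1]
    above = np.arange(t_def + step, hi + 1e-9, step)
    grid = np.concatenate([below, above])
    grid = grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]
    if grid.size == 0:
        raise DomainError("grid does not intersect the fitted range")
    return grid


def bootstrap_spread(
    obs,
    trait: str,
    grid: np.ndarray,
    policy: SmoothingPolicy = SmoothingPolicy(),
    split_at: float | None = None,
    n_boot: int = 199,
    seed: int = 0,
) -> np.ndarray:
    """Pointwise SD of the fitted trait curve under resampling of plants
    with replacement.  A display-oriented spread estimate; resamples whose
    fit becomes infeasible (too few distinct times) are redrawn."""
    rng = np.random.default_rng(seed)
    obs = list(obs)
    n = len(obs)
    fits = []
    attempts = 0
    while len(fits) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        sample = [obs[i] for i in rng.integers(0, n, size=n)]
        try:
            if trait == "ln_shoot_mass":
                f = fit_log_mass_spline(sample, policy, split_at=split_at)
            else:
                f = fit_trait_splines(sample, trait, policy, split_at=split_at)
            fits.append(f(grid))
        except (FitError, DomainError):
            continue
    if len(fits) < n_boot:
        log.warning("bootstrap: only %d/%d feasible resamples", len(fits), n_boot)
    if not fits:
        raise FitError("bootstrap: no feasible resample")
    return np.std(np.vstack(fits), axis=0, ddof=1)
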