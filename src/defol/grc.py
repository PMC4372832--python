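"""Growth response coefficients and ontogenetic stage analysis.

The growth response coefficient of a growth determinant X (NAR, SLA or LWR)
measures the share of a defoliation-induced change in RGR attributable to X:

    GRC_X = (ln X_D - ln X_C) / (ln RGR_D - ln RGR_C)

Because RGR = NAR * SLA * LWR, the three coefficients sum to exactly 1
wherever the denominator is non-degenerate: the decomposition is an exact
log-ratio partition, not an approximation.  GRC_NAR's numerator is computed
through that identity (Δln RGR - Δln SLA - Δln LWR), which keeps the
sum-to-1 property at full floating-point accuracy even near the denominator
mask threshold.

The post-defoliation RGR plasticity trajectory is segmented into three
ontogenetic states: buffering (from the shock until defoliated plants first
equal controls), steady (parity within a tolerance band ±ε) and
overcompensatory (defoliated above controls by more than ε).  Within each
state, each GRC component is tested against zero with a one-sample t-test
when a Shapiro-Wilk gate supports normality, otherwise with a Wilcoxon
signed-rank test whose null distribution is enumerated exactly (tie-aware)
up to n = 25.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .datatypes import (
    GrowthSeries,
    GRCSeries,
    PlasticitySeries,
    StageSegmentation,
    StageTestResult,
    STAGES,
)
from .errors import DomainError, FitError, StageError

log = logging.getLogger("defol")

#: points with |ln RGR_D - ln RGR_C| below this are degenerate and masked
DENOMINATOR_TOL = 1e-6


def grc_series(
    series_c: GrowthSeries,
    series_d: GrowthSeries,
    valid: np.ndarray | None = None,
    t_def: float | None = None,
) -> GRCSeries:
    """Compute GRC_NAR, GRC_SLA and GRC_LWR over the (post-defoliation) grid.

    Points already masked (non-positive RGR) or with a degenerate
    denominator are flagged invalid; the count of degenerate points is
    logged.  ``t_def`` restricts the output grid to t >= t_def (before the
    shock the two series coincide and the denominator vanishes identically).
    """
    if not np.array_equal(series_c.grid_t, series_d.grid_t):
        raise DomainError("control and defoliated series must share a grid")
    grid = series_c.grid_t
    if valid is None:
        valid = np.ones(grid.shape, dtype=bool)
    post = grid >= t_def if t_def is not None else np.ones(grid.shape, dtype=bool)
    g = grid[post]
    ok = valid[post].copy()
    ok &= (series_c.rgr[post] > 0) & (series_d.rgr[post] > 0)

    dln_rgr = np.full(g.shape, np.nan)
    num_sla = np.full(g.shape, np.nan)
    num_lwr = np.full(g.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        dln_rgr[ok] = np.log(series_d.rgr[post][ok]) - np.log(series_c.rgr[post][ok])
        num_sla[ok] = np.log(series_d.sla[post][ok]) - np.log(series_c.sla[post][ok])
        num_lwr[ok] = np.log(series_d.lwr[post][ok]) - np.log(series_c.lwr[post][ok])
    degenerate = ok & (np.abs(dln_rgr) < DENOMINATOR_TOL)
    if np.any(degenerate):
        log.info(
            "%s: masked %d GRC point(s) with degenerate denominator",
            series_c.ecotype,
            int(np.sum(degenerate)),
        )
        ok &= ~degenerate

    grc_sla = np.full(g.shape, np.nan)
    grc_lwr = np.full(g.shape, np.nan)
    grc_nar = np.full(g.shape, np.nan)
    grc_sla[ok] = num_sla[ok] / dln_rgr[ok]
    grc_lwr[ok] = num_lwr[ok] / dln_rgr[ok]
    # NAR numerator via the identity ln NAR = ln RGR - ln SLA - ln LWR
    grc_nar[ok] = (dln_rgr[ok] - num_sla[ok] - num_lwr[ok]) / dln_rgr[ok]
    return GRCSeries(
        ecotype=series_c.ecotype,
        grid_t=g,
        grc_nar=grc_nar,
        grc_sla=grc_sla,
        grc_lwr=grc_lwr,
        delta_ln_rgr=dln_rgr,
        valid=ok,
    )


def predefoliation_grc(
    series: GrowthSeries, window: tuple[float, float] = (1416.0, 1446.0)
) -> dict[str, float]:
    """Pre-defoliation GRC triple for one condition, as allometric slopes.

    Before the shock there is no treatment contrast, so each component's GRC
    is estimated as the OLS slope of ln X(t) on ln RGR(t) across the grid
    points inside the window.  The three slopes sum to 1 whenever the
    components multiply exactly to RGR.
    """
    sel = (series.grid_t >= window[0]) & (series.grid_t <= window[1])
    if np.sum(sel) < 4:
        raise FitError(
            f"need >= 4 grid points inside the window {window}, got {int(np.sum(sel))}"
        )
    rgr = series.rgr[sel]
    if np.any(rgr <= 0):
        raise DomainError("RGR must be positive throughout the regression window")
    x = np.log(rgr)
    if np.ptp(x) < 1e-12:
        raise FitError("ln RGR is constant in the window (zero-variance regressor)")
    ln_sla = np.log(series.sla[sel])
    ln_lwr = np.log(series.lwr[sel])
    ln_nar = x - ln_sla - ln_lwr  # identity: ln NAR = ln RGR - ln SLA - ln LWR

    def slope(y: np.ndarray) -> float:
        xc = x - x.mean()
        return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))

    return {"nar": slope(ln_nar), "sla": slope(ln_sla), "lwr": slope(ln_lwr)}


# ---------------------------------------------------------------------------
# stage classification


def classify_stages(
    rgr_plasticity: PlasticitySeries,
    t_def: float,
    epsilon: float = 0.05,
) -> StageSegmentation:
    """Segment the post-defoliation RGR plasticity trajectory.

    Buffering runs from the shock until t_eq, the linearly interpolated time
    at which defoliated plants first equal controls (plasticity crosses 0
    from below); if the trajectory enters the parity band [-ε, +ε] without
    ever reaching 0, the band-entry time is used.  After t_eq, grid points
    with |plasticity| <= ε are steady and points with plasticity > +ε are
    overcompensatory.  A trajectory that starts above -ε raises
    :class:`StageError` ("no detectable shock"); one that never re-enters
    the band leaves buffering extending to the end with a warning.
    """
    if epsilon <= 0:
        raise DomainError("epsilon must be > 0")
    grid = rgr_plasticity.grid_t
    p = rgr_plasticity.value
    valid = rgr_plasticity.valid & np.isfinite(p)
    v_idx = np.flatnonzero(valid)
    if v_idx.size == 0:
        raise StageError("no valid plasticity points after defoliation")
    first = v_idx[0]
    if not p[first] < -epsilon:
        raise StageError(
            "no detectable shock: plasticity at the defoliation time is "
            f"{p[first]:.4f}, not below -{epsilon}"
        )

    t_eq: float | None = None
    eq_pos = None  # position in v_idx after which stages are assigned
    for k in range(1, v_idx.size):
        i0, i1 = v_idx[k - 1], v_idx[k]
        if p[i1] >= 0:
            # linear interpolation of the zero crossing
            if p[i1] == 0 or p[i0] == p[i1]:
                t_eq = float(grid[i1])
            else:
                frac = -p[i0] / (p[i1] - p[i0])
                t_eq = float(grid[i0] + frac * (grid[i1] - grid[i0]))
            eq_pos = k
            break
    if t_eq is None:
        # never reached equality; maybe the band was entered
        for k in range(1, v_idx.size):
            i0, i1 = v_idx[k - 1], v_idx[k]
            if p[i1] >= -epsilon:
                frac = (-epsilon - p[i0]) / (p[i1] - p[i0])
                t_eq = float(grid[i0] + frac * (grid[i1] - grid[i0]))
                eq_pos = k
                log.warning(
                    "%s: plasticity enters the parity band but never reaches 0; "
                    "buffering ends at band entry",
                    rgr_plasticity.ecotype,
                )
                break
    if t_eq is None:
        log.warning(
            "%s: plasticity never re-enters the parity band; buffering extends "
            "to the end of the experiment",
            rgr_plasticity.ecotype,
        )
        stage_indices = {
            "buffering": v_idx.copy(),
            "steady": np.array([], dtype=int),
            "overcompensatory": np.array([], dtype=int),
        }
        return StageSegmentation(
            ecotype=rgr_plasticity.ecotype,
            t_def=t_def,
            t_eq=None,
            epsilon=epsilon,
            grid_t=grid,
            stage_indices=stage_indices,
        )

    buf, steady, over = [], [], []
    relapse = 0
    for k, i in enumerate(v_idx):
        if k < eq_pos:
            buf.append(i)
        elif p[i] > epsilon:
            over.append(i)
        elif p[i] >= -epsilon:
            steady.append(i)
        else:  # dipped back below the band after equality
            relapse += 1
            buf.append(i)
    if relapse:
        log.warning(
            "%s: %d post-equality point(s) fell back below the parity band; "
            "counted as buffering",
            rgr_plasticity.ecotype,
            relapse,
        )
    stage_indices = {
        "buffering": np.asarray(buf, dtype=int),
        "steady": np.asarray(steady, dtype=int),
        "overcompensatory": np.asarray(over, dtype=int),
    }
    return StageSegmentation(
        ecotype=rgr_plasticity.ecotype,
        t_def=t_def,
        t_eq=t_eq,
        epsilon=epsilon,
        grid_t=grid,
        stage_indices=stage_indices,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with an exact tie-aware null


def wilcoxon_signed_rank(x, exact_max_n: int = 25) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of median 0, two-sided.

    Zeros are dropped (Wilcoxon's convention) and ties share mid-ranks.  For
    n <= ``exact_max_n`` the null distribution of W+ (sum of positive ranks)
    is enumerated exactly by dynamic programming over doubled mid-ranks, so
    tied samples are handled without approximation; above that, the normal
    approximation with tie correction and a 0.5 continuity correction is
    used.  Returns ``(W+, p)``.
    """
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    n = x.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(x))
    w_plus = float(np.sum(ranks[x > 0]))
    if n <= exact_max_n:
        # doubled mid-ranks are integers; DP over the subset-sum distribution
        d = np.rint(2 * ranks).astype(int)
        total = int(d.sum())
        poly = np.zeros(total + 1)
        poly[0] = 1.0
        for di in d:
            nxt = poly.copy()
            nxt[di:] += poly[: total + 1 - di]
            poly = nxt
        poly /= poly.sum()
        w2 = int(round(2 * w_plus))
        cdf = np.cumsum(poly)
        p_le = cdf[w2]
        p_ge = 1.0 - (cdf[w2 - 1] if w2 > 0 else 0.0)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, float(p)
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w_plus, 1.0
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def stage_grc_tests(
    grc: GRCSeries,
    rgr_plasticity: PlasticitySeries,
    seg: StageSegmentation,
    alpha: float = 0.05,
) -> list[StageTestResult]:
    """Test GRC_NAR, GRC_SLA, GRC_LWR and the RGR plasticity against zero
    within each ontogenetic stage.

    Each unmasked grid point in a stage contributes one observation.  A
    Shapiro-Wilk gate at ``alpha`` selects the one-sample t-test when met,
    otherwise the Wilcoxon signed-rank test.  Stages with fewer than 3
    usable points are skipped with a warning; a stage whose values are all
    exactly zero returns statistic 0 and p = 1.
    """
    if not np.array_equal(grc.grid_t, rgr_plasticity.grid_t):
        raise DomainError("GRC and plasticity series must share a grid")
    components = {
        "NAR": (grc.grc_nar, grc.valid),
        "SLA": (grc.grc_sla, grc.valid),
        "LWR": (grc.grc_lwr, grc.valid),
        "RGR-plasticity": (rgr_plasticity.value, rgr_plasticity.valid),
    }
    results: list[StageTestResult] = []
    for stage in STAGES:
        idx = seg.stage_indices.get(stage, np.array([], dtype=int))
        for comp, (values, valid) in components.items():
            use = idx[valid[idx]] if idx.size else idx
            vals = values[use]
            n = vals.size
            if n < 3:
                if idx.size:
                    log.warning(
                        "%s %s/%s: only %d usable point(s); stage skipped",
                        grc.ecotype, stage, comp, n,
                    )
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            if np.all(vals == 0):
                results.append(
                    StageTestResult(
                        ecotype=grc.ecotype, stage=stage, component=comp, n=n,
                        median=float(med), q1=float(q1), q3=float(q3),
                        test="wilcoxon", statistic=0.0, p_value=1.0,
                    )
                )
                continue
            use_t = False
            if np.ptp(vals) > 1e-12 * max(1.0, np.max(np.abs(vals))):
                sw_p = stats.shapiro(vals).pvalue
                use_t = sw_p > alpha
            if use_t:
                res = stats.ttest_1samp(vals, 0.0)
                statistic, p = float(res.statistic), float(res.pvalue)
                test = "t"
            else:
                statistic, p = wilcoxon_signed_rank(vals)
                test = "wilcoxon"
            results.append(
                StageTestResult(
                    ecotype=grc.ecotype, stage=stage, component=comp, n=n,
                    median=float(med), q1=float(q1), q3=float(q3),
                    test=test, statistic=statistic, p_value=p,
                )
            )
    return results
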