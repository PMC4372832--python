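"""Fitness tolerance analysis: Poisson GLM of seed counts.

Total seed number per plant is modelled with a log-link Poisson GLM on the
2 x 2 factorial ecotype x treatment design.  Term importance is assessed
with likelihood-ratio tests under a hierarchical drop scheme: the
interaction is tested against the additive model, and each main effect is
tested by removing it together with the interaction (so its chi-square
carries the number of dropped parameters as degrees of freedom).  The
tolerance of an ecotype is the slope of fitness across environments,
mean(defoliated) - mean(control); positive slope = overtolerance, zero =
complete tolerance, negative = undertolerance.

Pairwise comparisons of the four cell means use Wald contrasts on the log
scale with Holm adjustment, from which a compact letter display is derived.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SeedCount, TREATMENTS
from .errors import DomainError, FitError

log = logging.getLogger("defol")


@dataclass
class ToleranceFit:
    """Fitted Poisson seed-count model for a 2 x 2 ecotype x treatment design."""

    ecotypes: tuple[str, str]
    params: np.ndarray  # (intercept, ecotype, treatment, interaction) on log scale
    cov: np.ndarray
    loglik: float
    #: term -> (LR chi2, df, p)
    lr_tests: dict[str, tuple[float, int, float]]
    #: (ecotype, treatment) -> fitted mean seeds per plant
    cell_means: dict[tuple[str, str], float]
    #: ecotype -> mean_defoliated - mean_control (seeds per plant)
    slopes: dict[str, float]
    #: ecotype -> 100 * (mean_D - mean_C) / mean_C
    percent_change: dict[str, float]
    overdispersion: float  # Pearson chi2 / df of the full model
    quasi: bool


def _design(ecos: np.ndarray, treats: np.ndarray, levels: tuple[str, str]) -> np.ndarray:
    e = (ecos == levels[1]).astype(float)
    t = (treats == "defoliated").astype(float)
    return np.column_stack([np.ones_like(e), e, t, e * t])


def fit_seed_glm(counts: list[SeedCount], quasi: bool = False) -> ToleranceFit:
    """Fit the Poisson seed-count GLM and its per-term likelihood-ratio tests.

    Requires all four ecotype x treatment cells non-empty and a positive
    grand total; non-integer or negative counts are a domain error.  With
    ``quasi=True`` the LR chi-squares are rescaled by the Pearson
    overdispersion of the full model (a quasi-likelihood correction, off by
    default).
    """
    if not counts:
        raise FitError("empty seed-count collection")
    for c in counts:
        if not isinstance(c.seeds, (int, np.integer)) or c.seeds < 0:
            raise DomainError(
                f"plant {c.plant_id}: seeds must be a non-negative integer"
            )
    ecos = np.asarray([c.ecotype for c in counts])
    treats = np.asarray([c.treatment for c in counts])
    y = np.asarray([c.seeds for c in counts], dtype=float)
    levels = tuple(sorted(set(ecos)))
    if len(levels) != 2:
        raise FitError(f"need exactly 2 ecotypes, got {levels}")
    for eco in levels:
        for treat in TREATMENTS:
            if not np.any((ecos == eco) & (treats == treat)):
                raise FitError(f"empty design cell: ecotype {eco}, treatment {treat}")
    if y.sum() <= 0:
        raise FitError("total seed count must be > 0")

    X_full = _design(ecos, treats, levels)

    def loglik(cols: list[int]) -> tuple[float, np.ndarray, np.ndarray]:
        model = sm.GLM(y, X_full[:, cols], family=sm.families.Poisson())
        res = model.fit()
        return float(res.llf), np.asarray(res.params), np.asarray(res.cov_params())

    llf_full, params, cov = loglik([0, 1, 2, 3])
    ll_no_int, _, _ = loglik([0, 1, 2])
    ll_no_treat, _, _ = loglik([0, 1])  # treatment and interaction dropped
    ll_no_eco, _, _ = loglik([0, 2])  # ecotype and interaction dropped

    full_model = sm.GLM(y, X_full, family=sm.families.Poisson()).fit()
    dof = y.size - 4
    overdisp = float(full_model.pearson_chi2 / dof) if dof > 0 else np.nan
    scale = overdisp if quasi and np.isfinite(overdisp) and overdisp > 0 else 1.0

    def lrt(ll_red: float, df: int) -> tuple[float, int, float]:
        chi2 = max(0.0, 2.0 * (llf_full - ll_red)) / scale
        return chi2, df, float(stats.chi2.sf(chi2, df))

    lr_tests = {
        "ecotype": lrt(ll_no_eco, 2),
        "treatment": lrt(ll_no_treat, 2),
        "ecotype:treatment": lrt(ll_no_int, 1),
    }

    cell_means: dict[tuple[str, str], float] = {}
    for eco in levels:
        for treat in TREATMENTS:
            row = _design(np.asarray([eco]), np.asarray([treat]), levels)[0]
            cell_means[(eco, treat)] = float(np.exp(row @ params))
    slopes = {
        eco: cell_means[(eco, "defoliated")] - cell_means[(eco, "control")]
        for eco in levels
    }
    percent_change = {
        eco: 100.0 * slopes[eco] / cell_means[(eco, "control")] for eco in levels
    }
    return ToleranceFit(
        ecotypes=levels,
        params=params,
        cov=cov * scale,
        loglik=llf_full,
        lr_tests=lr_tests,
        cell_means=cell_means,
        slopes=slopes,
        percent_change=percent_change,
        overdispersion=overdisp,
        quasi=quasi,
    )


def pairwise_group_contrasts(fit: ToleranceFit, alpha: float = 0.05) -> pd.DataFrame:
    """All six pairwise Wald contrasts of the four cell means, Holm-adjusted.

    Contrasts are formed on the log scale from the saturated-model
    coefficients and covariance.  The returned frame carries the log
    rate-ratio estimate, its SE, z, raw and Holm-adjusted p-values and a
    significance flag at ``alpha``; a compact letter display over the cells
    is attached as ``frame.attrs["letters"]`` (cells sharing a letter do not
    differ significantly).
    """
    cells = [(eco, treat) for eco in fit.ecotypes for treat in TREATMENTS]
    rows = {
        cell: _design(np.asarray([cell[0]]), np.asarray([cell[1]]), fit.ecotypes)[0]
        for cell in cells
    }
    recs = []
    for (a, b) in itertools.combinations(cells, 2):
        d = rows[a] - rows[b]
        est = float(d @ fit.params)
        se = float(np.sqrt(d @ fit.cov @ d))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = est / se
            p = float(2.0 * stats.norm.sf(abs(z)))
        recs.append(
            {
                "cell_a": f"{a[0]}:{a[1]}",
                "cell_b": f"{b[0]}:{b[1]}",
                "log_ratio": est,
                "se": se,
                "z": z,
                "p_value": p,
            }
        )
    frame = pd.DataFrame(recs)
    reject, p_adj, _, _ = multipletests(frame["p_value"], alpha=alpha, method="holm")
    frame["p_holm"] = p_adj
    frame["significant"] = reject
    frame.attrs["letters"] = _compact_letters(cells, frame)
    return frame


def _compact_letters(cells, frame: pd.DataFrame) -> dict[str, str]:
    """Compact letter display from the non-significance graph (maximal
    cliques of mutually non-different cells each get one letter)."""
    names = [f"{e}:{t}" for e, t in cells]
    nonsig = {frozenset((r.cell_a, r.cell_b)) for r in frame.itertuples() if not r.significant}

    def is_clique(subset: tuple[str, ...]) -> bool:
        return all(
            frozenset((a, b)) in nonsig for a, b in itertools.combinations(subset, 2)
        )

    cliques: list[tuple[str, ...]] = []
    for r in range(len(names), 0, -1):
        for subset in itertools.combinations(names, r):
            if is_clique(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    letters = {n: "" for n in names}
    for letter, clique in zip("abcdefghij", cliques):
        for n in clique:
            letters[n] += letter
    return letters
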