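"""Funnel-plot data and small-study asymmetry tests.

The funnel plot scatters each study's effect against its standard error;
asymmetry around the pooled effect suggests (but never proves) selective
publication.  Two formal tests are provided:

Begg-Mazumdar adjusted rank correlation
    Kendall tau-b between variance-standardised deviates from the
    fixed-effect pool and the study variances, with a tie-corrected,
    continuity-corrected normal approximation (or exact permutation for
    small k).

Egger regression
    OLS of the standardised effect (effect/se) on precision (1/se); a
    nonzero intercept indicates that small studies report systematically
    different effects.  Two-sided t test on the intercept with k-2 df.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .meta import EffectStudy, pool

__all__ = [
    "FunnelData",
    "BiasTestResult",
    "funnel_data",
    "begg_test",
    "egger_test",
    "kendall_statistics",
]

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class FunnelData:
    """Plot-ready funnel rows plus pseudo-confidence funnel bounds."""

    effects: np.ndarray
    ses: np.ndarray
    study_ids: tuple[str, ...]
    pooled: float
    se_grid: np.ndarray
    lower_bound: np.ndarray   # pooled - z * se over the grid
    upper_bound: np.ndarray
    z: float


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of one asymmetry test.

    ``statistic`` is Kendall tau-b for Begg and the regression intercept for
    Egger; ``p`` is two-sided.
    """

    method: Literal["begg", "egger"]
    statistic: float
    p: float
    detail: dict


def funnel_data(studies: Sequence[EffectStudy], pooled: float | None = None, z: float = 1.96) -> FunnelData:
    """Rows for a funnel plot with pseudo-95% bounds over the se range."""
    if not studies:
        raise ValueError("no studies")
    effects = np.array([s.effect for s in studies])
    ses = np.array([s.se for s in studies])
    if pooled is None:
        pooled = (
            pool(studies, "fixed").effect_fixed if len(studies) >= 2 else float(effects[0])
        )
    grid = np.linspace(0.0, float(ses.max()), 50)
    return FunnelData(
        effects=effects,
        ses=ses,
        study_ids=tuple(s.study_id for s in studies),
        pooled=float(pooled),
        se_grid=grid,
        lower_bound=pooled - z * grid,
        upper_bound=pooled + z * grid,
        z=z,
    )


def kendall_statistics(x: np.ndarray, y: np.ndarray) -> tuple[int, float, float]:
    """Kendall S, tau-b, and tie-corrected Var(S) for paired sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, 1)
    s = int(np.sum(sx[iu] * sy[iu]))

    def tie_sizes(v):
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1]

    tx, ty = tie_sizes(x), tie_sizes(y)
    n0 = n * (n - 1) / 2
    n1 = float(np.sum(tx * (tx - 1) / 2))
    n2 = float(np.sum(ty * (ty - 1) / 2))
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    tau_b = s / denom if denom > 0 else 0.0

    def v_terms(t):
        return (
            float(np.sum(t * (t - 1) * (2 * t + 5))),
            float(np.sum(t * (t - 1) * (t - 2))),
            float(np.sum(t * (t - 1))),
        )

    vx1, vx2, vx3 = v_terms(tx)
    vy1, vy2, vy3 = v_terms(ty)
    var_s = (
        (n * (n - 1) * (2 * n + 5) - vx1 - vy1) / 18.0
        + vx2 * vy2 / (9.0 * n * (n - 1) * (n - 2))
        + vx3 * vy3 / (2.0 * n * (n - 1))
    )
    return s, tau_b, var_s


def _count_extreme(perms: np.ndarray, st: np.ndarray, sv: np.ndarray, s_abs: float) -> int:
    """Count permutations whose |S| is at least ``s_abs``.

    ``perms`` maps permuted positions to original deviate indices; S for a
    permutation sums sign-products over upper-triangle pairs.
    """
    k = perms.shape[1]
    iu, ju = np.triu_indices(k, 1)
    prods = st[perms[:, iu], perms[:, ju]] * sv[iu, ju]
    s_perm = prods.sum(axis=1)
    return int(np.sum(np.abs(s_perm) >= s_abs - 1e-9))


def _begg_deviates(studies: Sequence[EffectStudy]) -> tuple[np.ndarray, np.ndarray]:
    effects = np.array([s.effect for s in studies])
    variances = np.array([s.variance for s in studies])
    w = 1.0 / variances
    theta_f = float(np.sum(w * effects) / np.sum(w))
    v_bar = 1.0 / float(np.sum(w))  # variance of the pooled estimate
    adj = variances - v_bar
    if np.any(adj <= _VAR_FLOOR):
        # v_i > var(pooled) holds in exact arithmetic; a dominant study can
        # cancel it away in floats, so floor rather than divide by ~0
        warnings.warn(
            "variance correction v_i - var(pooled) numerically non-positive "
            "for some studies; flooring at 1e-12",
            stacklevel=2,
        )
        adj = np.maximum(adj, _VAR_FLOOR)
    t = (effects - theta_f) / np.sqrt(adj)
    return t, variances


def begg_test(studies: Sequence[EffectStudy], exact: bool = False) -> BiasTestResult:
    """Begg-Mazumdar adjusted rank correlation test for funnel asymmetry.

    Standardised deviates ``t_i = (effect_i - pooled_fixed) / sqrt(v_i - v_bar)``
    are rank-correlated with the variances ``v_i``.  The default p-value uses
    the tie-corrected normal approximation for Kendall S with a continuity
    correction; ``exact=True`` enumerates all permutations (k <= 10 only).
    """
    if len(studies) < 3:
        raise ValueError("Begg test requires at least 3 studies")
    t, v = _begg_deviates(studies)
    s, tau_b, var_s = kendall_statistics(t, v)
    if exact:
        k = len(studies)
        if k > 10:
            raise ValueError("exact permutation p limited to k <= 10")
        st = np.sign(t[:, None] - t[None, :])
        sv = np.sign(v[:, None] - v[None, :])
        count = 0
        total = 0
        chunk: list[tuple[int, ...]] = []
        for perm in permutations(range(k)):
            chunk.append(perm)
            if len(chunk) == 100_000:
                count += _count_extreme(np.array(chunk), st, sv, abs(s))
                total += len(chunk)
                chunk = []
        if chunk:
            count += _count_extreme(np.array(chunk), st, sv, abs(s))
            total += len(chunk)
        p = count / total
        detail = {"S": s, "exact": True, "n_perm": total}
    else:
        if var_s <= 0:
            p = 1.0
        else:
            z = (abs(s) - 1) / math.sqrt(var_s) if abs(s) >= 1 else 0.0
            p = float(2 * norm.sf(z))
        detail = {"S": s, "var_S": var_s, "exact": False}
    return BiasTestResult(method="begg", statistic=float(tau_b), p=min(p, 1.0), detail=detail)


def egger_test(studies: Sequence[EffectStudy], weighted: bool = False) -> BiasTestResult:
    """Egger regression asymmetry test.

    Regresses the standardised effect on precision with an intercept; under
    no small-study asymmetry the line passes through the origin.  The classic
    form is unweighted on the standardised scale; ``weighted=True`` weights
    by precision squared.
    """
    if len(studies) < 3:
        raise ValueError("Egger test requires at least 3 studies")
    ses = np.array([s.se for s in studies])
    effects = np.array([s.effect for s in studies])
    precision = 1.0 / ses
    if np.ptp(precision) < 1e-12:
        raise ValueError(
            "precision constant, intercept not estimable (regressor collinear with constant)"
        )
    y = effects / ses
    X = sm.add_constant(precision)
    if weighted:
        fit = sm.WLS(y, X, weights=precision**2).fit()
    else:
        fit = sm.OLS(y, X).fit()
    intercept = float(fit.params[0])
    se_int = float(fit.bse[0])
    if se_int < 1e-12:
        # exact fit through (or off) the origin: the t statistic degenerates
        p = 1.0 if abs(intercept) < 1e-9 else 0.0
        tval = math.nan
    else:
        tval = intercept / se_int
        p = float(fit.pvalues[0])
    return BiasTestResult(
        method="egger",
        statistic=intercept,
        p=p,
        detail={"se": se_int, "t": tval, "df": len(studies) - 2, "slope": float(fit.params[1])},
    )
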