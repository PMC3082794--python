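"""Three-source capture-recapture via Poisson log-linear models.

The observed data are the 7 cells of the 2x2x2 source-incidence table (the
all-absent cell is unobservable).  Each of the 8 hierarchical log-linear
models contains the three source main effects plus a subset of the pairwise
interactions {AB, AC, BC}; the triple interaction is never included because
with 7 cells and 8 parameters it would leave the missing cell unidentified.
Fitting a model by Poisson maximum likelihood and extrapolating to the
all-absent pattern gives the estimated number of missing studies
``x_hat = exp(intercept)`` and the estimated total ``N = n_obs + x_hat``.

Model comparison uses the deviance G^2 with df = 3 - (#interactions),
AIC = G^2 - 2*df, and BIC = G^2 - ln(n_obs / 2*pi) * df.  Interval estimation
for the missing cell uses the profile likelihood by default (a log-normal
delta-method interval is also available).

Usage::

    model = CaptureRecapture(table)
    fits = model.fit_all()           # 8 CrcFit results, canonical order
    best = fits.select("aic")
    fits.completeness()              # per-source and overall retrieval rates
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, norm

from .capture import CELL_PATTERNS, CaptureTable, round_half_away

__all__ = [
    "LoglinearModelSpec",
    "CrcFit",
    "CrcFitCollection",
    "CompletenessRow",
    "CompletenessResult",
    "CaptureRecapture",
    "enumerate_models",
    "chi2_pvalue",
    "aic",
    "bic",
]

_INTERACTION_ORDER = ("AB", "AC", "BC")
#: All-absent capture pattern whose fitted count is the missing-study estimate.
_MISSING_PATTERN = (0, 0, 0)


@dataclass(frozen=True)
class LoglinearModelSpec:
    """One hierarchical log-linear model: main effects A, B, C always present,
    plus a subset of the pairwise interaction terms."""

    interactions: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.interactions - set(_INTERACTION_ORDER)
        if bad:
            raise ValueError(f"unknown interaction terms {sorted(bad)}")

    @property
    def label(self) -> str:
        terms = ["A", "B", "C"] + [t for t in _INTERACTION_ORDER if t in self.interactions]
        return " ".join(terms)

    @property
    def df(self) -> int:
        """Residual degrees of freedom when fitted to the 7 observed cells."""
        return 3 - len(self.interactions)

    def design(self, patterns: Sequence[tuple[int, int, int]] = CELL_PATTERNS) -> np.ndarray:
        """Design matrix: intercept, main-effect indicators, interaction products."""
        rows = []
        for a, b, c in patterns:
            prod = {"AB": a * b, "AC": a * c, "BC": b * c}
            rows.append(
                [1, a, b, c] + [prod[t] for t in _INTERACTION_ORDER if t in self.interactions]
            )
        return np.asarray(rows, dtype=float)


def enumerate_models() -> list[LoglinearModelSpec]:
    """The 8 models, ordered by number of interaction terms then term order."""
    specs = []
    for k in range(4):
        for combo in combinations(_INTERACTION_ORDER, k):
            specs.append(LoglinearModelSpec(frozenset(combo)))
    return specs


def chi2_pvalue(g2: float, df: int) -> float:
    """Upper-tail chi-square probability for a deviance statistic.

    At df = 0 the deviance is identically 0 for a perfectly saturated fit and
    the conventional report is p = 1.
    """
    if g2 < 0 or df < 0:
        raise ValueError("g2 and df must be nonnegative")
    if df == 0:
        return 1.0 if g2 <= 1e-8 else 0.0
    return float(chi2.sf(g2, df))


def aic(g2: float, df: int) -> float:
    """Akaike criterion on the deviance scale: G^2 - 2*df (smaller is better)."""
    return g2 - 2.0 * df


def bic(g2: float, df: int, n_obs: int) -> float:
    """Bayesian criterion on the deviance scale: G^2 - ln(n_obs / 2*pi) * df.

    ``n_obs`` is the number of observed studies (the sample size the penalty
    is scaled by).
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return g2 - math.log(n_obs / (2.0 * math.pi)) * df


@dataclass(frozen=True)
class CrcFit:
    """Results of one log-linear model fitted to a 7-cell capture table."""

    model: LoglinearModelSpec
    table: CaptureTable
    df: int
    g2: float
    p: float
    x_hat: float          # estimated missing-study count (inf if divergent)
    n_est: float          # n_obs + x_hat
    ci_x: tuple[float, float] | None
    ci_level: float
    aic: float
    bic: float
    identifiable: bool
    converged: bool
    params: np.ndarray | None = None
    cov_params: np.ndarray | None = None
    fitted: np.ndarray | None = None

    @property
    def n_obs(self) -> int:
        return self.table.n_obs

    @property
    def ci_n(self) -> tuple[float, float] | None:
        """Interval for the estimated total, n_obs + CI(X)."""
        if self.ci_x is None:
            return None
        return (self.n_obs + self.ci_x[0], self.n_obs + self.ci_x[1])

    def summary_row(self) -> dict:
        """One display row: estimates rounded the way count data are reported."""
        inf = not self.identifiable
        return {
            "model": self.model.label,
            "df": self.df,
            "G2": round(self.g2, 2),
            "p": round(self.p, 4),
            "N_est": math.inf if inf else round_half_away(self.n_est),
            "X": math.inf if inf else round_half_away(self.x_hat),
            "X_lower": math.nan if self.ci_x is None else round(self.ci_x[0], 1),
            "X_upper": math.nan if self.ci_x is None else round(self.ci_x[1], 1),
            "AIC": round(self.aic, 2),
            "BIC": round(self.bic, 2),
        }


@dataclass(frozen=True)
class CompletenessRow:
    source: str
    observed: int
    n_est: float
    pct: float
    ci_pct: tuple[float, float] | None


@dataclass(frozen=True)
class CompletenessResult:
    """Retrieval completeness of each source, and overall, against N_est."""

    rows: tuple[CompletenessRow, ...]

    @property
    def overall(self) -> CompletenessRow:
        return self.rows[-1]

    def summary(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "source": r.source,
                    "n_observed": r.observed,
                    "n_estimated": round_half_away(r.n_est),
                    "completeness_pct": round(r.pct, 1),
                    "ci_lower_pct": math.nan if r.ci_pct is None else round(r.ci_pct[0], 1),
                    "ci_upper_pct": math.nan if r.ci_pct is None else round(r.ci_pct[1], 1),
                }
            )
        return pd.DataFrame.from_records(recs)


class _IrlsFit:
    """Raw IRLS output for a Poisson log-linear fit on given cells."""

    __slots__ = ("beta", "cov", "deviance", "fitted", "converged")

    def __init__(self, beta, cov, deviance, fitted, converged):
        self.beta = beta
        self.cov = cov
        self.deviance = deviance
        self.fitted = fitted
        self.converged = converged


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _irls(y: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> _IrlsFit:
    """Iteratively reweighted least squares for the Poisson log link.

    Count cells may be zero; the likelihood handles them without correction.
    Divergent fits (an unidentified missing cell) drive the intercept toward
    +inf: iteration is capped and the caller applies the divergence rule.
    """
    beta = np.zeros(X.shape[1])
    beta[0] = math.log(max(float(y.mean()), 0.5))
    dev_old = math.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -300, 300)
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        xtw = X.T * w
        try:
            beta = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta)):
            break
        mu = np.exp(np.clip(X @ beta, -300, 300))
        dev = _poisson_deviance(y, mu)
        if abs(dev - dev_old) < tol:
            converged = True
            break
        dev_old = dev
    mu = np.exp(np.clip(X @ beta, -300, 300))
    dev = _poisson_deviance(y, mu)
    try:
        cov = np.linalg.inv((X.T * mu) @ X)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return _IrlsFit(beta, cov, dev, mu, converged)


class CaptureRecapture:
    """Capture-recapture model over a three-source capture table.

    Parameters
    ----------
    table : CaptureTable
        The 7 observed cells.
    divergence_ratio : float
        A fit is declared non-identifiable when the estimated missing cell
        exceeds ``divergence_ratio * n_obs`` (or its log-scale standard error
        is non-finite).  Such fits are reported with infinite ``x_hat`` and
        ``n_est``, mirroring how unstable log-linear estimates present in
        sparse incidence tables.
    max_iter, tol : int, float
        IRLS iteration cap and deviance-change convergence tolerance.
    """

    def __init__(
        self,
        table: CaptureTable,
        divergence_ratio: float = 1000.0,
        max_iter: int = 100,
        tol: float = 1e-10,
    ) -> None:
        if table.n_obs <= 0:
            raise ValueError("capture table has no observed studies")
        self.table = table
        self.divergence_ratio = divergence_ratio
        self.max_iter = max_iter
        self.tol = tol
        self._y = np.asarray(table.cells, dtype=float)

    @classmethod
    def from_records(cls, records, **kwargs) -> "CaptureRecapture":
        from .capture import build_capture_table

        return cls(build_capture_table(records), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CaptureRecapture":
        """Build from a per-study frame with columns study_id, source_a/b/c."""
        from .capture import SourceRecord, build_capture_table

        records = [
            SourceRecord(str(r.study_id), bool(r.source_a), bool(r.source_b), bool(r.source_c))
            for r in df.itertuples(index=False)
        ]
        return cls(build_capture_table(records), **kwargs)

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        model: LoglinearModelSpec,
        ci_level: float | None = 0.95,
        ci_method: Literal["profile", "lognormal"] = "profile",
    ) -> CrcFit:
        """Fit one log-linear model and estimate the missing cell.

        ``ci_level=None`` skips interval computation.
        """
        X = model.design()
        raw = _irls(self._y, X, self.max_iter, self.tol)
        x_hat = float(np.exp(raw.beta[0])) if np.all(np.isfinite(raw.beta)) else math.inf
        se_log_x = float(np.sqrt(raw.cov[0, 0])) if np.all(np.isfinite(raw.cov)) else math.inf
        n_obs = self.table.n_obs
        identifiable = (
            math.isfinite(x_hat)
            and math.isfinite(se_log_x)
            and x_hat <= self.divergence_ratio * n_obs
        )
        g2 = max(raw.deviance, 0.0)
        df = model.df
        fit = CrcFit(
            model=model,
            table=self.table,
            df=df,
            g2=g2,
            p=chi2_pvalue(g2, df),
            x_hat=x_hat if identifiable else math.inf,
            n_est=n_obs + x_hat if identifiable else math.inf,
            ci_x=None,
            ci_level=ci_level if ci_level is not None else math.nan,
            aic=aic(g2, df),
            bic=bic(g2, df, n_obs),
            identifiable=identifiable,
            converged=raw.converged,
            params=raw.beta,
            cov_params=raw.cov,
            fitted=raw.fitted,
        )
        if ci_level is not None and identifiable:
            ci = self.confidence_interval_x(model, ci_level, method=ci_method, _fit=fit)
            fit = dataclasses.replace(fit, ci_x=ci)
        return fit

    def fit_all(
        self,
        ci_level: float | None = 0.95,
        ci_method: Literal["profile", "lognormal"] = "profile",
    ) -> "CrcFitCollection":
        """Fit all 8 models in canonical order; per-fit failures never abort."""
        return CrcFitCollection(
            tuple(self.fit(m, ci_level, ci_method) for m in enumerate_models())
        )

    # -- intervals -----------------------------------------------------------

    def _profile_deviance(self, model: LoglinearModelSpec, x: float) -> float:
        """Deviance of the 8-cell fit with the missing cell pinned at ``x``."""
        patterns = CELL_PATTERNS + (_MISSING_PATTERN,)
        X8 = model.design(patterns)
        y8 = np.concatenate([self._y, [x]])
        return _irls(y8, X8, self.max_iter, self.tol).deviance

    def confidence_interval_x(
        self,
        model: LoglinearModelSpec,
        level: float = 0.95,
        method: Literal["profile", "lognormal"] = "profile",
        _fit: CrcFit | None = None,
    ) -> tuple[float, float]:
        """Confidence interval for the missing-study count X.

        ``profile`` inverts the likelihood-ratio statistic obtained by pinning
        the missing cell and refitting (preferred: respects the likelihood's
        asymmetry and the X >= 0 boundary).  ``lognormal`` is the delta-method
        interval on the log scale, ``x_hat * exp(+-z * se(log x_hat))``.
        """
        fit = _fit if _fit is not None else self.fit(model, ci_level=None)
        if not fit.identifiable:
            raise ValueError("CI undefined: the missing-cell estimate diverges")
        x_hat = fit.x_hat
        if method == "lognormal":
            se = float(np.sqrt(fit.cov_params[0, 0]))
            z = norm.ppf(0.5 + level / 2)
            return (x_hat * math.exp(-z * se), x_hat * math.exp(z * se))
        crit = float(chi2.ppf(level, 1))
        dev0 = fit.g2

        def shifted(x: float) -> float:
            return self._profile_deviance(model, x) - dev0 - crit

        if x_hat <= 1e-9:
            lower = 0.0
        elif shifted(0.0) <= 0:
            lower = 0.0
        else:
            lower = brentq(shifted, 1e-12, x_hat, xtol=1e-8)
        hi = max(x_hat * 2, x_hat + 5.0)
        cap = self.divergence_ratio * self.table.n_obs
        while shifted(hi) <= 0 and hi < cap:
            hi *= 2
        upper = math.inf if hi >= cap else brentq(shifted, max(x_hat, 1e-12), hi, xtol=1e-8)
        return (lower, upper)


@dataclass(frozen=True)
class CrcFitCollection:
    """The 8 fits in canonical order, with selection and reporting helpers."""

    fits: tuple[CrcFit, ...]

    def __iter__(self):
        return iter(self.fits)

    def __len__(self) -> int:
        return len(self.fits)

    def __getitem__(self, i) -> CrcFit:
        return self.fits[i]

    def by_label(self, label: str) -> CrcFit:
        for f in self.fits:
            if f.model.label == label:
                return f
        raise KeyError(label)

    def select(self, criterion: Literal["aic", "bic"] = "aic") -> CrcFit:
        """Identifiable fit minimising the criterion.

        Ties break toward fewer interaction terms, then canonical order.
        """
        if criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        candidates = [
            (getattr(f, criterion), len(f.model.interactions), i, f)
            for i, f in enumerate(self.fits)
            if f.identifiable
        ]
        if not candidates:
            raise ValueError("no identifiable fits to select from")
        return min(candidates)[-1]

    def completeness(
        self, selected: CrcFit | None = None, use_rounded_n: bool = True
    ) -> CompletenessResult:
        """Per-source and overall retrieval completeness against N_est.

        Completeness is 100 * observed / N_est.  By default the denominator
        is N_est rounded to the integer actually reported in a completeness
        table, so the percent column is consistent with the displayed total
        (``use_rounded_n=False`` divides by the full-precision estimate).
        Percent CI bounds come from the monotone transform of the X interval:
        a larger plausible missing count means a lower plausible
        completeness.
        """
        fit = selected if selected is not None else self.select("aic")
        if not fit.identifiable:
            raise ValueError("completeness undefined for a non-identifiable fit")
        table = fit.table
        n_obs = table.n_obs
        from .capture import round_half_away

        denom = float(round_half_away(fit.n_est)) if use_rounded_n else fit.n_est

        def row(source: str, count: int) -> CompletenessRow:
            pct = 100.0 * count / denom
            ci = None
            if fit.ci_x is not None:
                x_lo, x_up = fit.ci_x
                ci = (100.0 * count / (n_obs + x_up), 100.0 * count / (n_obs + x_lo))
            return CompletenessRow(source, count, fit.n_est, pct, ci)

        labels = table.labels
        rows = (
            row(labels[0], table.m_a),
            row(labels[1], table.m_b),
            row(labels[2], table.m_c),
            row("all sources", n_obs),
        )
        return CompletenessResult(rows)

    def summary(self) -> pd.DataFrame:
        """Model-comparison table: df, G^2, p, N_est, X with CI, AIC, BIC."""
        return pd.DataFrame.from_records([f.summary_row() for f in self.fits])
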