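"""Effect-size handling and inverse-variance pooling.

Supports the diagnostics in :mod:`crcbias.bias` and :mod:`crcbias.trimfill`:
proportion transforms (raw, logit, Freeman-Tukey double arcsine), fixed-effect
and DerSimonian-Laird random-effects pooling, and the Q / I^2 / tau^2
heterogeneity summaries.  Pooling delegates to
:func:`statsmodels.stats.meta_analysis.combine_effects`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.meta_analysis import combine_effects

__all__ = [
    "EffectStudy",
    "MetaResult",
    "MetaAnalysis",
    "transform_proportion",
    "pool",
    "HETEROGENEITY_ALPHA",
]

#: Conventional significance level for the heterogeneity chi-square test.
HETEROGENEITY_ALPHA = 0.10

ProportionScale = Literal["raw", "logit", "ft"]


@dataclass(frozen=True)
class EffectStudy:
    """One study's effect estimate on the analysis scale.

    ``events``/``total`` are carried along when the effect came from a
    proportion, so reports can show the original counts.
    """

    study_id: str
    effect: float
    se: float
    events: int | None = None
    total: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"study {self.study_id!r}: standard error must be > 0")
        if (self.events is None) != (self.total is None):
            raise ValueError("events and total must be given together")
        if self.events is not None and not 0 <= self.events <= self.total:
            raise ValueError(f"study {self.study_id!r}: events must lie in [0, total]")

    @property
    def variance(self) -> float:
        return self.se**2


def transform_proportion(
    events: int, total: int, scale: ProportionScale = "logit"
) -> tuple[float, float]:
    """Proportion -> (effect, se) on the requested analysis scale.

    raw
        p with se sqrt(p(1-p)/n); rejected at p in {0, 1} where the
        binomial variance degenerates to zero.
    logit
        log(p/(1-p)); a 0.5 continuity correction on both counts is applied
        at the boundaries so the transform stays finite.
    ft
        Freeman-Tukey double arcsine, variance 1/(n + 0.5); defined and
        variance-stabilised over the whole [0, 1] range.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= events <= total:
        raise ValueError("events must lie in [0, total]")
    if scale == "raw":
        p = events / total
        if p in (0.0, 1.0):
            raise ValueError(
                "raw-scale se is 0 at a boundary proportion; use scale='logit' or 'ft'"
            )
        return p, math.sqrt(p * (1 - p) / total)
    if scale == "logit":
        e, f = float(events), float(total - events)
        if events == 0 or events == total:
            e += 0.5
            f += 0.5
        return math.log(e / f), math.sqrt(1.0 / e + 1.0 / f)
    if scale == "ft":
        n = total
        effect = math.asin(math.sqrt(events / (n + 1))) + math.asin(
            math.sqrt((events + 1) / (n + 1))
        )
        return effect, math.sqrt(1.0 / (n + 0.5))
    raise ValueError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect with heterogeneity summaries.

    ``i2`` is a percent; ``tau2`` is the DerSimonian-Laird between-study
    variance, truncated at zero.  ``q_significant`` applies the conventional
    10% level for the heterogeneity test.
    """

    effect_fixed: float
    se_fixed: float
    effect_random: float
    se_random: float
    q: float
    df: int
    p_q: float
    i2: float
    tau2: float
    k: int

    @property
    def q_significant(self) -> bool:
        return self.p_q < HETEROGENEITY_ALPHA

    def effect(self, model: Literal["fixed", "random"]) -> float:
        return self.effect_fixed if model == "fixed" else self.effect_random

    def se(self, model: Literal["fixed", "random"]) -> float:
        return self.se_fixed if model == "fixed" else self.se_random

    def summary(self) -> str:
        return (
            f"k={self.k}  fixed {self.effect_fixed:.4f} (se {self.se_fixed:.4f})  "
            f"random {self.effect_random:.4f} (se {self.se_random:.4f})  "
            f"Q={self.q:.3f} (df={self.df}, p={self.p_q:.4f})  "
            f"I2={self.i2:.1f}%  tau2={self.tau2:.4f}"
        )


def pool(studies: Sequence[EffectStudy], model: Literal["fixed", "random"] = "random") -> MetaResult:
    """Inverse-variance pooling with DerSimonian-Laird tau^2.

    Both fixed- and random-effects summaries are always computed; ``model``
    only records the caller's primary choice (the result carries both).
    """
    if len(studies) < 2:
        raise ValueError("pooling requires at least 2 studies")
    effects = np.array([s.effect for s in studies])
    variances = np.array([s.variance for s in studies])
    with np.errstate(invalid="ignore"):  # statsmodels sqrt's an untruncated tau2
        res = combine_effects(effects, variances, method_re="chi2")
    q = max(float(res.q), 0.0)
    df = len(studies) - 1
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    # statsmodels reports the raw moment estimate, which can be negative;
    # DL truncates at zero, and the random pool must use the truncated value
    tau2 = max(float(res.tau2), 0.0)
    w_re = 1.0 / (variances + tau2)
    return MetaResult(
        effect_fixed=float(res.mean_effect_fe),
        se_fixed=float(res.sd_eff_w_fe),
        effect_random=float(np.sum(w_re * effects) / np.sum(w_re)),
        se_random=float(1.0 / math.sqrt(np.sum(w_re))),
        q=q,
        df=df,
        p_q=float(chi2.sf(q, df)),
        i2=i2,
        tau2=tau2,
        k=len(studies),
    )


class MetaAnalysis:
    """Meta-analysis model over a set of effect studies.

    ``fit`` pools; the publication-bias diagnostics (funnel export, Begg,
    Egger, trim-and-fill) are methods so a single object carries one dataset
    through the whole comparison.
    """

    def __init__(self, studies: Sequence[EffectStudy]) -> None:
        studies = list(studies)
        if not studies:
            raise ValueError("no studies")
        ids = [s.study_id for s in studies]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate study ids")
        self.studies = studies

    @classmethod
    def from_proportions(
        cls,
        counts: Sequence[tuple[str, int, int]],
        scale: ProportionScale = "logit",
    ) -> "MetaAnalysis":
        """Build from (study_id, events, total) triples on a chosen scale."""
        studies = []
        for sid, ev, tot in counts:
            eff, se = transform_proportion(ev, tot, scale)
            studies.append(EffectStudy(sid, eff, se, events=ev, total=tot))
        return cls(studies)

    @property
    def k(self) -> int:
        return len(self.studies)

    def fit(self, model: Literal["fixed", "random"] = "random") -> MetaResult:
        return pool(self.studies, model)

    # -- diagnostics (implemented in sibling modules) ------------------------

    def funnel_data(self, pooled: float | None = None):
        from .bias import funnel_data

        return funnel_data(self.studies, pooled)

    def begg_test(self, exact: bool = False):
        from .bias import begg_test

        return begg_test(self.studies, exact=exact)

    def egger_test(self, weighted: bool = False):
        from .bias import egger_test

        return egger_test(self.studies, weighted=weighted)

    def trim_and_fill(self, side: str = "auto", estimator: str = "L0", pool_model: str = "random"):
        from .trimfill import trim_and_fill

        return trim_and_fill(self.studies, side=side, estimator=estimator, pool_model=pool_model)
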