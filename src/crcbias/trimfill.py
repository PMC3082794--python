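"""Duval-Tweedie nonparametric trim-and-fill.

Estimates the number of studies suppressed from one side of a funnel plot
from the ranks of absolute deviations about the pooled centre, trims the
surplus extreme studies, re-centres, and finally "fills" by reflecting the
trimmed studies about the centre so an asymmetry-adjusted pooled effect can
be computed.

Estimators (k observed studies, deviations centred at the current pool,
ranks of absolute deviations, T = sum of ranks on the surplus side):

    L0 = (4*T - k*(k+1)) / (2*k - 1)
    R0 = (length of the rightmost run of surplus-side signs) - 1

L0 is the default for its small-sample stability; both round to the nearest
nonnegative integer.  Trimming centres with the fixed-effect pool (the
random-effects pool would be dragged by the very studies under suspicion);
the final adjusted pool is random-effects by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .meta import EffectStudy, MetaResult, pool

__all__ = ["TrimFillResult", "estimate_k0", "trim_and_fill"]

Side = Literal["auto", "left", "right"]
Estimator = Literal["L0", "R0"]


@dataclass(frozen=True)
class TrimFillResult:
    side: Literal["left", "right"]
    estimator: Estimator
    k0: int
    filled: tuple[EffectStudy, ...]
    pooled_original: MetaResult
    pooled_adjusted: MetaResult
    iterations: int
    converged: bool

    @property
    def changed(self) -> bool:
        return self.k0 > 0


def estimate_k0(deviations: Sequence[float], estimator: Estimator = "L0") -> int:
    """Estimated suppressed-study count from centred deviations.

    ``deviations`` are effects minus the pooled centre, oriented so the
    surplus (over-represented) side is positive.  Ties in absolute value get
    average ranks; zero deviations count to neither side.
    """
    d = np.asarray(deviations, dtype=float)
    k = len(d)
    if k < 3:
        raise ValueError("need at least 3 studies")
    ranks = rankdata(np.abs(d))
    if estimator == "L0":
        t = float(np.sum(ranks[d > 0]))
        est = (4.0 * t - k * (k + 1)) / (2.0 * k - 1.0)
    elif estimator == "R0":
        order = np.argsort(ranks)  # ascending |d|
        signs_desc = (d[order] > 0)[::-1]
        run = 0
        for pos in signs_desc:
            if pos:
                run += 1
            else:
                break
        est = run - 1.0
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return max(0, int(round(est)))


def _auto_side(studies: Sequence[EffectStudy]) -> Literal["left", "right"]:
    """Suppression side opposite the Egger intercept's sign; ties go left."""
    from .bias import egger_test

    try:
        intercept = egger_test(studies).statistic
    except ValueError:
        return "left"
    return "left" if intercept >= 0 else "right"


def trim_and_fill(
    studies: Sequence[EffectStudy],
    side: Side = "auto",
    estimator: Estimator = "L0",
    pool_model: Literal["fixed", "random"] = "random",
    max_iter: int = 50,
) -> TrimFillResult:
    """Run the full trim-and-fill adjustment.

    Iterates centre -> k0 estimate -> trim until the trimmed count
    stabilises (or ``max_iter``), then fills mirror-image studies and
    re-pools observed + filled with ``pool_model``.
    """
    studies = list(studies)
    k = len(studies)
    if k < 3:
        raise ValueError("trim-and-fill requires at least 3 studies")
    resolved: Literal["left", "right"] = _auto_side(studies) if side == "auto" else side  # type: ignore[assignment]
    flip = -1.0 if resolved == "right" else 1.0

    effects = flip * np.array([s.effect for s in studies])
    order = np.argsort(effects)  # surplus side (largest) last
    sorted_studies = [studies[i] for i in order]
    eff_sorted = effects[order]

    k0 = 0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        kept = sorted_studies[: k - k0] if k0 else sorted_studies
        if len(kept) < 2:
            break
        kept_flipped = [dataclasses.replace(s, effect=flip * s.effect) for s in kept]
        center = pool(kept_flipped, "fixed").effect_fixed
        k0_new = min(estimate_k0(eff_sorted - center, estimator), k - 1)
        if k0_new == k0:
            converged = True
            break
        k0 = k0_new

    filled = tuple(
        dataclasses.replace(
            s,
            study_id=f"{s.study_id}_fill",
            effect=flip * (2.0 * center - flip * s.effect),
            events=None,
            total=None,
        )
        for s in sorted_studies[k - k0 :]
    )
    original = pool(studies, pool_model)
    adjusted = pool(studies + list(filled), pool_model) if filled else original
    return TrimFillResult(
        side=resolved,
        estimator=estimator,
        k0=k0,
        filled=filled,
        pooled_original=original,
        pooled_adjusted=adjusted,
        iterations=iterations,
        converged=converged,
    )
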