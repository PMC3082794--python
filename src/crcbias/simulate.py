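"""Synthetic data generators: multi-source capture processes and
meta-analyses with selective publication.

``simulate_capture`` draws each study's capture pattern from a log-linear
probability model whose main effects are the logits of the per-source
capture probabilities and whose pairwise terms are log odds-ratios, so the
generator and the fitted models share one family: independence data should
be recovered by the independence model, and positively dependent sources
should bias the independence-model total downward (dependent lists overlap
more than independence predicts, making the population look smaller).

``simulate_meta`` draws study effects around a true mean with between-study
variance tau^2 and within-study noise, then applies a selection function
mapping (effect, se) to a publication probability; both the published and
the suppressed studies are returned so recovery can be checked against
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .capture import CELL_PATTERNS, CaptureTable
from .meta import EffectStudy

__all__ = [
    "CaptureSimConfig",
    "MetaSimConfig",
    "CaptureSimResult",
    "MetaSimResult",
    "simulate_capture",
    "simulate_meta",
]

_ALL_PATTERNS = ((0, 0, 0),) + CELL_PATTERNS


@dataclass(frozen=True)
class CaptureSimConfig:
    """Three-source capture process.

    ``p_a, p_b, p_c`` are the marginal capture probabilities under
    independence; ``dependence`` maps pairwise terms ("AB", "AC", "BC") to
    log odds-ratios (0 = independent sources).
    """

    n_true: int
    p_a: float
    p_b: float
    p_c: float
    dependence: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_true < 1:
            raise ValueError("n_true must be >= 1")
        for p in (self.p_a, self.p_b, self.p_c):
            if not 0 < p < 1:
                raise ValueError("capture probabilities must lie in (0, 1)")
        bad = set(self.dependence) - {"AB", "AC", "BC"}
        if bad:
            raise ValueError(f"unknown dependence terms {sorted(bad)}")

    def pattern_probs(self) -> np.ndarray:
        """Probabilities of the 8 capture patterns, all-absent first."""
        logits = [math.log(p / (1 - p)) for p in (self.p_a, self.p_b, self.p_c)]
        g = self.dependence
        w = []
        for a, b, c in _ALL_PATTERNS:
            lw = a * logits[0] + b * logits[1] + c * logits[2]
            lw += g.get("AB", 0.0) * a * b + g.get("AC", 0.0) * a * c + g.get("BC", 0.0) * b * c
            w.append(math.exp(lw))
        w = np.array(w)
        total = w.sum()
        if not total > 0:
            raise ValueError("capture pattern probabilities have zero mass")
        return w / total


@dataclass(frozen=True)
class CaptureSimResult:
    table: CaptureTable
    n_missed: int
    n_true: int


def simulate_capture(config: CaptureSimConfig) -> CaptureSimResult:
    """Draw a capture table; studies missed by every source are counted
    separately (they would be invisible to a real review)."""
    rng = np.random.default_rng(config.seed)
    counts = rng.multinomial(config.n_true, config.pattern_probs())
    n_missed = int(counts[0])
    table = CaptureTable(*(int(c) for c in counts[1:]))
    return CaptureSimResult(table=table, n_missed=n_missed, n_true=config.n_true)


SelectionFn = Callable[[float, float], float]


@dataclass(frozen=True)
class MetaSimConfig:
    """Meta-analysis generator with optional selective publication.

    Per-study standard errors are drawn uniformly on ``(se_min, se_max)``.
    ``selection(effect, se)`` returns a publication probability; ``None``
    publishes everything.
    """

    k: int
    true_effect: float = 0.0
    tau2: float = 0.0
    se_min: float = 0.1
    se_max: float = 0.5
    selection: SelectionFn | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not 0 < self.se_min <= self.se_max:
            raise ValueError("need 0 < se_min <= se_max")


@dataclass(frozen=True)
class MetaSimResult:
    published: tuple[EffectStudy, ...]
    suppressed: tuple[EffectStudy, ...]

    @property
    def k_published(self) -> int:
        return len(self.published)


def simulate_meta(config: MetaSimConfig) -> MetaSimResult:
    """Generate studies and apply the selection mechanism.

    Raises if fewer than 2 studies survive selection (increase ``k`` or relax
    the selection function).
    """
    rng = np.random.default_rng(config.seed)
    ses = rng.uniform(config.se_min, config.se_max, size=config.k)
    effects = (
        config.true_effect
        + rng.normal(0.0, math.sqrt(config.tau2), size=config.k)
        + rng.normal(0.0, 1.0, size=config.k) * ses
    )
    published, suppressed = [], []
    for i, (eff, se) in enumerate(zip(effects, ses)):
        study = EffectStudy(f"s{i + 1}", float(eff), float(se))
        prob = 1.0 if config.selection is None else float(config.selection(eff, se))
        if rng.random() < prob:
            published.append(study)
        else:
            suppressed.append(study)
    if len(published) < 2:
        raise ValueError(
            f"only {len(published)} studies published after selection; increase k"
        )
    return MetaSimResult(published=tuple(published), suppressed=tuple(suppressed))
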