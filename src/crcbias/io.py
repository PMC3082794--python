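"""CSV input/output and report serialization.

Input dialects
--------------
Retrieval records: ``study_id, source_a, source_b, source_c`` with 0/1 or
true/false cells (case-insensitive).

Effect data: either ``study_id, effect, se`` or ``study_id, events, total``
(the latter transformed onto an analysis scale on read).  Files carrying
both column sets are rejected as ambiguous rather than guessed at.

Reports serialize to JSON (full precision, stable key order) or markdown
(display precision), covering the model-comparison table, the completeness
table, bias tests and trim-and-fill.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from . import __version__
from .capture import CELL_PATTERNS, CaptureTable, SourceRecord
from .loglinear import CompletenessResult, CrcFitCollection
from .meta import EffectStudy, transform_proportion

__all__ = [
    "read_records_csv",
    "read_effects_csv",
    "write_capture_table_csv",
    "read_capture_table_csv",
    "write_effects_csv",
    "Report",
    "write_report",
]

_TRUTHY = {"1": True, "true": True, "0": False, "false": False}


def _parse_flag(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s not in _TRUTHY:
        raise ValueError(f"row {row}: column {column!r} has non-boolean value {value!r}")
    return _TRUTHY[s]


def read_records_csv(path: str | Path) -> list[SourceRecord]:
    """Read per-study retrieval flags; errors name the offending row (1-based
    data rows, excluding the header)."""
    df = pd.read_csv(path, dtype=str)
    required = ["study_id", "source_a", "source_b", "source_c"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    records: list[SourceRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.study_id)
        if sid in seen:
            raise ValueError(f"row {i}: duplicate study_id {sid!r}")
        seen.add(sid)
        flags = [_parse_flag(getattr(row, c), c, i) for c in required[1:]]
        if not any(flags):
            raise ValueError(f"row {i}: study {sid!r} has no retrieval source")
        records.append(SourceRecord(sid, *flags))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def read_effects_csv(path: str | Path, scale: str = "logit") -> list[EffectStudy]:
    """Read effect data, auto-detecting the effect/se vs events/total schema."""
    df = pd.read_csv(path)
    if "study_id" not in df.columns:
        raise ValueError(f"missing column 'study_id' in {path}")
    has_effect = {"effect", "se"} <= set(df.columns)
    has_counts = {"events", "total"} <= set(df.columns)
    if has_effect and has_counts:
        raise ValueError("ambiguous schema: both effect/se and events/total columns present")
    if not has_effect and not has_counts:
        raise ValueError("expected columns effect,se or events,total")
    studies: list[EffectStudy] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.study_id)
        try:
            if has_effect:
                studies.append(EffectStudy(sid, float(row.effect), float(row.se)))
            else:
                ev, tot = int(row.events), int(row.total)
                eff, se = transform_proportion(ev, tot, scale)  # type: ignore[arg-type]
                studies.append(EffectStudy(sid, eff, se, events=ev, total=tot))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    if not studies:
        raise ValueError(f"no studies in {path}")
    return studies


def write_effects_csv(studies: Sequence[EffectStudy], path: str | Path) -> None:
    pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "effect": [repr(s.effect) for s in studies],  # repr: round-trip exact
            "se": [repr(s.se) for s in studies],
        }
    ).to_csv(path, index=False)


_PATTERN_STRINGS = tuple("".join(str(f) for f in pat) for pat in CELL_PATTERNS)


def write_capture_table_csv(table: CaptureTable, path: str | Path) -> None:
    """One row per cell with its capture pattern (`110` = A and B, not C)."""
    pd.DataFrame({"pattern": _PATTERN_STRINGS, "count": table.cells}).to_csv(path, index=False)


def read_capture_table_csv(path: str | Path) -> CaptureTable:
    df = pd.read_csv(path, dtype={"pattern": str, "count": int})
    counts = dict(zip(df["pattern"], df["count"]))
    missing = [p for p in _PATTERN_STRINGS if p not in counts]
    if missing:
        raise ValueError(f"missing pattern rows {missing} in {path}")
    return CaptureTable(*(int(counts[p]) for p in _PATTERN_STRINGS))


def _jsonable(obj):
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return _jsonable(obj.tolist())
    return obj


@dataclasses.dataclass
class Report:
    """Assembled analysis report; sections left as ``None`` are omitted."""

    input_summary: dict
    model_table: list[dict] | None = None
    completeness: list[dict] | None = None
    bias_tests: list[dict] | None = None
    trim_fill: dict | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_results(
        cls,
        *,
        input_summary: dict,
        fits: CrcFitCollection | None = None,
        completeness: CompletenessResult | None = None,
        bias_tests: Sequence = (),
        trim_fill=None,
        config: dict | None = None,
        seed: int | None = None,
    ) -> "Report":
        model_table = None
        if fits is not None:
            model_table = [
                {
                    **f.summary_row(),
                    "g2_full": f.g2,
                    "p_full": f.p,
                    "x_hat_full": f.x_hat,
                    "n_est_full": f.n_est,
                    "identifiable": f.identifiable,
                    "converged": f.converged,
                }
                for f in fits
            ]
        comp = None
        if completeness is not None:
            comp = completeness.summary().to_dict(orient="records")
        bias = [
            {"method": b.method, "statistic": b.statistic, "p": b.p, "detail": b.detail}
            for b in bias_tests
        ] or None
        tf = None
        if trim_fill is not None:
            tf = {
                "side": trim_fill.side,
                "estimator": trim_fill.estimator,
                "k0": trim_fill.k0,
                "filled": [
                    {"study_id": s.study_id, "effect": s.effect, "se": s.se}
                    for s in trim_fill.filled
                ],
                "pooled_original": dataclasses.asdict(trim_fill.pooled_original),
                "pooled_adjusted": dataclasses.asdict(trim_fill.pooled_adjusted),
                "iterations": trim_fill.iterations,
                "converged": trim_fill.converged,
            }
        return cls(
            input_summary=input_summary,
            model_table=model_table,
            completeness=comp,
            bias_tests=bias,
            trim_fill=tf,
            provenance={"package": "crcbias", "version": __version__, "seed": seed,
                        "config": config or {}},
        )

    def to_json(self) -> str:
        payload = {k: _jsonable(v) for k, v in dataclasses.asdict(self).items() if v is not None}
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        parts = ["# crcbias report", ""]
        if self.model_table:
            parts += ["## Log-linear models", ""]
            cols = ["model", "df", "G2", "p", "N_est", "X", "AIC", "BIC"]
            parts.append("| " + " | ".join(cols) + " |")
            parts.append("|" + "---|" * len(cols))
            for r in self.model_table:
                cells = []
                for c in cols:
                    v = r[c]
                    cells.append("inf" if isinstance(v, float) and math.isinf(v) else str(v))
                parts.append("| " + " | ".join(cells) + " |")
            parts.append("")
        if self.completeness:
            parts += ["## Source completeness", ""]
            cols = ["source", "n_observed", "n_estimated", "completeness_pct",
                    "ci_lower_pct", "ci_upper_pct"]
            parts.append("| " + " | ".join(cols) + " |")
            parts.append("|" + "---|" * len(cols))
            for r in self.completeness:
                parts.append("| " + " | ".join(str(r[c]) for c in cols) + " |")
            parts.append("")
        if self.bias_tests:
            parts += ["## Bias tests", ""]
            for b in self.bias_tests:
                parts.append(f"- {b['method']}: statistic {b['statistic']:.4f}, p {b['p']:.4f}")
            parts.append("")
        if self.trim_fill:
            tf = self.trim_fill
            parts += [
                "## Trim-and-fill",
                "",
                f"- imputed studies (k0): {tf['k0']} on the {tf['side']} side "
                f"({tf['estimator']})",
                f"- adjusted pooled effect (random): "
                f"{tf['pooled_adjusted']['effect_random']:.4f}",
                "",
            ]
        return "\n".join(parts)


def write_report(report: Report, path: str | Path, format: Literal["json", "markdown"] = "json") -> None:
    text = report.to_json() if format == "json" else report.to_markdown()
    Path(path).write_text(text + "\n")
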