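"""Score ranked predictions against a native contact map.

PPV = |TP| / (|TP| + |FP|) over the top-N predictions, cumulative
true-positive curves, and breakdowns of the true positives by sequence
range (short / medium / long) and by secondary-structure category
(base pair, stem-loop, loop-loop, intra/inter stem-stem).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .contact_maps import (
    CATEGORIES,
    RANGE_LONG,
    RANGE_MEDIUM,
    RANGE_SHORT,
    ContactMap,
    classify_category,
    classify_range,
)
from .io_formats import SecondaryStructure
from .scoring import ScoredContacts


@dataclass
class EvaluationReport:
    ppv_at_n: dict  # N -> PPV
    tp_curve: list  # cumulative TP at rank 1..n_max
    range_breakdown: dict  # short/medium/long -> TP count at n_max
    category_breakdown: dict | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "ppv_at_n": {str(k): v for k, v in self.ppv_at_n.items()},
                "tp_curve": self.tp_curve,
                "range_breakdown": self.range_breakdown,
                "category_breakdown": self.category_breakdown,
            },
            indent=2,
        )


def _is_native(i: int, j: int, native: ContactMap) -> bool:
    return bool(native.values[i - 1, j - 1])


def ppv(predicted: ScoredContacts, native: ContactMap, n: int | None = None) -> float:
    """Positive predictive value of the top-n predictions."""
    entries = predicted.entries if n is None else predicted.entries[:n]
    if not entries:
        raise ValueError("no predictions")
    tp = sum(_is_native(i, j, native) for i, j, _ in entries)
    return tp / len(entries)


def tp_curve(predicted: ScoredContacts, native: ContactMap, n_max: int = 100) -> list[int]:
    """Cumulative count of native contacts at each rank 1..n_max."""
    curve, tp = [], 0
    for i, j, _ in predicted.entries[:n_max]:
        tp += int(_is_native(i, j, native))
        curve.append(tp)
    return curve


def breakdown(
    predicted: ScoredContacts,
    native: ContactMap,
    ss: SecondaryStructure | None = None,
    n: int = 100,
    categories: bool = False,
) -> EvaluationReport:
    """Evaluation report at rank n: PPV, TP curve, and TP breakdowns."""
    if categories and ss is None:
        raise ValueError("secondary structure required")
    curve = tp_curve(predicted, native, n_max=n)
    n_eff = min(n, len(predicted.entries))
    ppv_at = {k: curve[k - 1] / k for k in (10, 30, 50, 100) if k <= n_eff}
    if n_eff:
        ppv_at[n_eff] = curve[n_eff - 1] / n_eff

    ranges = {RANGE_SHORT: 0, RANGE_MEDIUM: 0, RANGE_LONG: 0}
    cats = {c: 0 for c in CATEGORIES} if categories else None
    for i, j, _ in predicted.entries[:n]:
        if not _is_native(i, j, native):
            continue
        r = classify_range(i, j)
        if r in ranges:
            ranges[r] += 1
        if categories:
            cats[classify_category(i, j, ss)] += 1
    return EvaluationReport(ppv_at, curve, ranges, cats)
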