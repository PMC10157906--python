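"""Set-based confusion counts and micro-averaged precision/recall/F1.

Identification is multi-label: for each prescription the truth is a set of
manually marked formula names ``A`` and the algorithm produces a set ``B``.
The three counts are summed over samples:

    f11 = Σ |A ∩ B|    correctly identified names
    f12 = Σ |B − A|    spurious names (identified, not marked)
    f21 = Σ |A − B|    missed names (marked, not identified)

and precision = f11/(f11+f12), recall = f11/(f11+f21), F1 = 2PR/(P+R).
Counts are micro-aggregated across samples before computing the ratios,
never macro-averaged per sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .formulary import Formulary, Prescription
from .matcher import identify, identified_names

if TYPE_CHECKING:  # pragma: no cover
    from .training import WeightModel

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion_counts",
    "metrics",
    "f1_score",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    f11: int
    f12: int
    f21: int

    def __post_init__(self) -> None:
        if min(self.f11, self.f12, self.f21) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.f11 + other.f11, self.f12 + other.f12, self.f21 + other.f21)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


def confusion_counts(
    predicted: Mapping[str, Iterable[str]],
    truth: Mapping[str, Iterable[str]],
) -> ConfusionCounts:
    """Micro-aggregated counts over samples aligned by id.

    Raises ``ValueError`` if the two collections do not cover the same ids.
    """
    if set(predicted) != set(truth):
        extra = sorted(set(predicted) ^ set(truth))[:5]
        raise ValueError(f"predicted/truth id mismatch, e.g. {extra}")
    f11 = f12 = f21 = 0
    for pid in truth:
        A = frozenset(truth[pid])
        B = frozenset(predicted[pid])
        inter = len(A & B)
        f11 += inter
        f12 += len(B) - inter
        f21 += len(A) - inter
    return ConfusionCounts(f11, f12, f21)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is zero; defining {name} = 0", stacklevel=3)
        return 0.0
    return num / den


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall and F1 from micro-aggregated counts.

    A zero denominator yields the value 0 with a warning; real evaluation
    sets never hit this, but thresholded predictions can be globally empty.
    """
    p = _ratio(c.f11, c.f11 + c.f12, "precision")
    r = _ratio(c.f11, c.f11 + c.f21, "recall")
    return Metrics(precision=p, recall=r, f1=f1_score(p, r))


def evaluate(
    model: "WeightModel",
    prescriptions: Sequence[Prescription],
    formulary: Formulary,
    report_path: str | Path | None = None,
) -> tuple[Metrics, list[dict]]:
    """Identify every labelled prescription and score against its labels.

    Returns the micro-averaged metrics and a per-sample report (truth,
    predicted, missed, spurious); the report is also written as JSONL when
    ``report_path`` is given.
    """
    predicted: dict[str, frozenset[str]] = {}
    truth: dict[str, frozenset[str]] = {}
    report = []
    for p in prescriptions:
        if p.labels is None:
            raise ValueError(f"prescription {p.id!r} has no labels; cannot evaluate")
        B = identified_names(identify(p, formulary, model))
        predicted[p.id] = B
        truth[p.id] = p.labels
        report.append(
            {
                "id": p.id,
                "truth": sorted(p.labels),
                "predicted": sorted(B),
                "missed": sorted(p.labels - B),
                "spurious": sorted(B - p.labels),
            }
        )
    m = metrics(confusion_counts(predicted, truth))
    if report_path is not None:
        with open(report_path, "w") as fh:
            for row in report:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    return m, report
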