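"""Core scoring: candidate pooling, per-level distances, weighted similarity.

Matching a prescription ``A`` (a drug-name set) against a standard formula
proceeds in three steps:

1. *Candidate pooling* — every formula whose full composition intersects
   ``A`` in at least one drug is a candidate.
2. *Distance coefficients* — for each importance level ``B`` of a
   candidate, ``d = |A ∩ B| / |B|``: the fraction of that level's drugs
   present in the prescription.  ``d1..d4`` score the chief/deputy/
   assistant/envoy levels, ``d5`` the full composition.
3. *Similarity* — ``sim = Σ d_i · w_i`` with normalized weights, compared
   against a trained threshold.

Three scoring variants exist: ``ISR`` (the intersection-set-rate baseline,
``sim = d5``), ``SIAP-All`` (weighted sum over d1..d4) and ``SIAP+All``
(weighted sum over d1..d5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from .formulary import LEVELS, Formulary, Prescription, StandardFormula

if TYPE_CHECKING:  # pragma: no cover
    from .training import WeightModel

__all__ = [
    "DistanceVector",
    "MatchResult",
    "candidate_set",
    "level_distance",
    "distance_vector",
    "similarity",
    "identify",
]

VARIANTS = ("ISR", "SIAP-All", "SIAP+All")

#: indices of the active distance components per variant (0-based into d1..d5)
ACTIVE_COMPONENTS = {
    "ISR": (4,),
    "SIAP-All": (0, 1, 2, 3),
    "SIAP+All": (0, 1, 2, 3, 4),
}


@dataclass(frozen=True)
class DistanceVector:
    """The five per-level distance coefficients for one (A, formula) pair."""

    d1: float
    d2: float
    d3: float
    d4: float
    d5: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.d1, self.d2, self.d3, self.d4, self.d5)

    def __getitem__(self, i: int) -> float:
        return self.as_tuple()[i]


@dataclass(frozen=True)
class MatchResult:
    """One identified candidate with its distances and similarity."""

    formula_name: str
    distances: DistanceVector
    sim: float


def candidate_set(A: Iterable[str], formulary: Formulary) -> list[StandardFormula]:
    """Formulas whose full composition shares at least one drug with ``A``.

    Order follows the formulary; an empty formulary yields an empty list.
    """
    drugs = frozenset(A)
    return [f for f in formulary if drugs & f.full_set]


def level_distance(A: Iterable[str], B_level: Iterable[str]) -> float:
    """Overlap fraction ``|A ∩ B| / |B|`` of a level set covered by ``A``.

    An empty level is vacuously satisfied and scores 1 (a requirement with
    no members is met; envoy sets are empty for about half of formulas, so
    this 0/0 case is routine, not exceptional).
    """
    B = frozenset(B_level)
    if not B:
        return 1.0
    return len(frozenset(A) & B) / len(B)


def distance_vector(A: Iterable[str], formula: StandardFormula) -> DistanceVector:
    """All five distance coefficients of ``A`` against one formula."""
    drugs = frozenset(A)
    ds = [level_distance(drugs, formula.level(k)) for k in LEVELS]
    ds.append(level_distance(drugs, formula.full_set))
    return DistanceVector(*ds)


def similarity(d: DistanceVector, model: "WeightModel") -> float:
    """Weighted similarity ``sim = Σ d_i w_i`` over the variant's active components.

    For the ISR baseline this is just ``d5``.  Raises ``ValueError`` if the
    model's active weights do not sum to 1.
    """
    active = ACTIVE_COMPONENTS[model.variant]
    total = sum(model.weights[i] for i in active)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"weights of variant {model.variant} sum to {total!r}, expected 1"
        )
    ds = d.as_tuple()
    if all(ds[i] == 1.0 for i in active):
        return 1.0  # exact cover must score exactly 1, immune to float round-off
    s = sum(ds[i] * model.weights[i] for i in active)
    return min(1.0, max(0.0, s))


def identify(
    p: Prescription | Iterable[str],
    formulary: Formulary,
    model: "WeightModel",
    threshold: float | None = None,
) -> list[MatchResult]:
    """All candidates whose similarity reaches the model's threshold.

    Results are sorted by similarity descending, ties broken by formula
    name ascending, so output is reproducible byte-for-byte.  The list may
    be empty; there is no forced top-1 fallback.
    """
    thr = model.threshold if threshold is None else threshold
    if not 0.0 <= thr <= 1.0:
        raise ValueError(f"threshold {thr} outside [0, 1]")
    drugs = p.drugs if isinstance(p, Prescription) else frozenset(p)
    out = []
    for f in candidate_set(drugs, formulary):
        d = distance_vector(drugs, f)
        sim = similarity(d, model)
        if sim >= thr:
            out.append(MatchResult(formula_name=f.name, distances=d, sim=sim))
    out.sort(key=lambda m: (-m.sim, m.formula_name))
    return out


def identified_names(matches: Sequence[MatchResult]) -> frozenset[str]:
    """The predicted formula-name set of an identification result."""
    return frozenset(m.formula_name for m in matches)
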