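"""Data model and I/O for standard formularies and clinical prescriptions.

A *standard formula* is a named drug combination whose constituents are
graded into four importance levels (chief, deputy, assistant, envoy —
C1..C4 in decreasing importance), plus the full composition set (the C5
role) which may also contain drugs assigned to no level.  A clinical
*prescription* is simply a set of drug names, optionally carrying the
formula names assigned by manual review (the multi-label ground truth).

Drug identity is exact string equality after case-folding, whitespace
trimming and synonym mapping; there is no fuzzy matching.  The formulary
file is the single source of level assignments — prescriptions never carry
level information.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "FormularyValidationError",
    "InvalidPrescriptionError",
    "SynonymMap",
    "StandardFormula",
    "Formulary",
    "Prescription",
    "canonical_name",
    "normalize",
    "load_formulary",
    "save_formulary",
    "load_prescriptions",
    "save_prescriptions",
    "load_synonyms",
]

LEVELS = ("C1", "C2", "C3", "C4")


class FormularyValidationError(ValueError):
    """A formulary file or formula object violates a structural invariant."""


class InvalidPrescriptionError(ValueError):
    """A prescription row is unusable (missing id, empty drug set, ...)."""


def canonical_name(raw: str) -> str:
    """Case-fold and whitespace-trim a raw drug name."""
    return raw.strip().casefold()


@dataclass(frozen=True)
class SynonymMap:
    """Mapping from raw drug names to canonical ones.

    Keys and values are canonicalised (case-folded, trimmed) on
    construction and chains ``a -> b -> c`` are collapsed so that applying
    the map is idempotent: a canonical name maps to itself.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {canonical_name(k): canonical_name(v) for k, v in self.entries.items()}
        resolved: dict[str, str] = {}
        for key, value in cleaned.items():
            seen = {key}
            while value in cleaned and cleaned[value] != value:
                if cleaned[value] in seen:
                    raise ValueError(f"synonym cycle involving {value!r}")
                seen.add(value)
                value = cleaned[value]
            if value != key:
                resolved[key] = value
        object.__setattr__(self, "entries", resolved)

    def apply(self, raw: str) -> str:
        name = canonical_name(raw)
        return self.entries.get(name, name)


def normalize(raw_names: Iterable[str], synonyms: SynonymMap | None = None) -> frozenset[str]:
    """Normalize a list of raw drug names to a canonical drug-name set.

    Case-folds, trims, applies the synonym map, drops empty tokens and
    collapses duplicates.  Raises :class:`InvalidPrescriptionError` if the
    result is empty.
    """
    synonyms = synonyms or SynonymMap()
    out = {synonyms.apply(r) for r in raw_names}
    out.discard("")
    if not out:
        raise InvalidPrescriptionError("no drug names remain after normalization")
    return frozenset(out)


@dataclass(frozen=True)
class StandardFormula:
    """A named standard prescription with graded drug levels.

    ``levels`` maps C1..C4 to pairwise-disjoint drug-name sets; ``full_set``
    is the complete composition (it must contain every levelled drug and
    may contain unlevelled ones, which contribute only to the C5 distance).
    """

    name: str
    levels: Mapping[str, frozenset[str]]
    full_set: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        lv = {k: frozenset(self.levels.get(k, frozenset())) for k in LEVELS}
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "full_set", frozenset(self.full_set))
        if not self.name:
            raise FormularyValidationError("formula name must be non-empty")
        if not self.full_set:
            raise FormularyValidationError(f"formula {self.name!r}: full composition set is empty")
        for i, a in enumerate(LEVELS):
            for b in LEVELS[i + 1:]:
                overlap = lv[a] & lv[b]
                if overlap:
                    raise FormularyValidationError(
                        f"formula {self.name!r}: levels {a} and {b} share drugs {sorted(overlap)}"
                    )
        levelled = frozenset().union(*lv.values())
        if not levelled <= self.full_set:
            missing = sorted(levelled - self.full_set)
            raise FormularyValidationError(
                f"formula {self.name!r}: levelled drugs {missing} missing from full set"
            )

    def level(self, key: str) -> frozenset[str]:
        return self.levels[key]


@dataclass(frozen=True)
class Formulary:
    """A collection of standard formulas keyed by unique name."""

    formulas: Mapping[str, StandardFormula]

    def __post_init__(self) -> None:
        object.__setattr__(self, "formulas", dict(self.formulas))

    @classmethod
    def from_iterable(cls, formulas: Iterable[StandardFormula]) -> "Formulary":
        out: dict[str, StandardFormula] = {}
        for f in formulas:
            if f.name in out:
                raise FormularyValidationError(f"duplicate formula name {f.name!r}")
            out[f.name] = f
        return cls(out)

    def __len__(self) -> int:
        return len(self.formulas)

    def __iter__(self) -> Iterator[StandardFormula]:
        return iter(self.formulas.values())

    def __getitem__(self, name: str) -> StandardFormula:
        return self.formulas[name]

    def __contains__(self, name: str) -> bool:
        return name in self.formulas

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formulary):
            return NotImplemented
        return dict(self.formulas) == dict(other.formulas)


@dataclass(frozen=True)
class Prescription:
    """An identified clinical drug-name set, optionally manually labelled."""

    id: str
    drugs: frozenset[str]
    labels: frozenset[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        if self.labels is not None:
            object.__setattr__(self, "labels", frozenset(self.labels))
        if not self.id:
            raise InvalidPrescriptionError("prescription id must be non-empty")
        if not self.drugs:
            raise InvalidPrescriptionError(f"prescription {self.id!r}: empty drug set")


# ---------------------------------------------------------------------------
# serialization


def _formula_to_dict(f: StandardFormula) -> dict:
    return {
        "name": f.name,
        "source": f.source,
        "levels": {k: sorted(f.levels[k]) for k in LEVELS},
        "full": sorted(f.full_set),
    }


def save_formulary(formulary: Formulary, path: str | Path) -> None:
    doc = {"formulas": [_formula_to_dict(f) for f in formulary]}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False))


def load_formulary(path: str | Path) -> Formulary:
    """Load and validate a formulary JSON file.

    Raises :class:`FormularyValidationError` naming the offending formula
    on any schema violation, duplicate name or level overlap.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormularyValidationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or not isinstance(doc.get("formulas"), list):
        raise FormularyValidationError(f"{path}: expected object with a 'formulas' list")
    formulas = []
    for i, entry in enumerate(doc["formulas"]):
        if not isinstance(entry, dict) or "name" not in entry or "full" not in entry:
            raise FormularyValidationError(f"{path}: formulas[{i}] missing 'name' or 'full'")
        levels_raw = entry.get("levels", {})
        formulas.append(
            StandardFormula(
                name=str(entry["name"]),
                source=str(entry.get("source", "")),
                levels={k: frozenset(map(str, levels_raw.get(k, []))) for k in LEVELS},
                full_set=frozenset(map(str, entry["full"])),
            )
        )
    return Formulary.from_iterable(formulas)


def save_prescriptions(prescriptions: Sequence[Prescription], path: str | Path) -> None:
    """Write prescriptions as CSV with pipe-delimited drugs and ;-delimited labels."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "drugs", "labels"])
        for p in prescriptions:
            labels = ";".join(sorted(p.labels)) if p.labels is not None else ""
            writer.writerow([p.id, "|".join(sorted(p.drugs)), labels])


def _parse_row(row: Mapping[str, str], index: int, synonyms: SynonymMap) -> Prescription:
    pid = (row.get("id") or "").strip()
    if not pid:
        raise InvalidPrescriptionError(f"row {index}: missing id")
    raw_drugs = [d for d in (row.get("drugs") or "").split("|") if d.strip()]
    if not raw_drugs:
        raise InvalidPrescriptionError(f"row {index} (id={pid!r}): empty drug list")
    labels_field = row.get("labels")
    labels = None
    if labels_field is not None and labels_field.strip():
        labels = frozenset(s.strip() for s in labels_field.split(";") if s.strip())
    return Prescription(id=pid, drugs=normalize(raw_drugs, synonyms), labels=labels)


def load_prescriptions(path: str | Path, synonyms: SynonymMap | None = None) -> list[Prescription]:
    """Load prescriptions from CSV (or JSONL when the suffix is .jsonl).

    Drug names are normalized through ``synonyms``; per-row failures raise
    :class:`InvalidPrescriptionError` with the offending row index.
    """
    synonyms = synonyms or SynonymMap()
    path = Path(path)
    out: list[Prescription] = []
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            rec = json.loads(line)
            row = {
                "id": str(rec.get("id", "")),
                "drugs": "|".join(rec.get("drugs", [])),
                "labels": ";".join(rec["labels"]) if rec.get("labels") is not None else None,
            }
            out.append(_parse_row(row, i, synonyms))
        return out
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            out.append(_parse_row(row, i, synonyms))
    return out


def load_synonyms(path: str | Path) -> SynonymMap:
    """Load a two-column (raw, canonical) CSV synonym dictionary."""
    entries: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() == "raw":
                continue
            if len(row) < 2:
                raise ValueError(f"synonym row {row!r} needs two columns")
            entries[row[0]] = row[1]
    return SynonymMap(entries)
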