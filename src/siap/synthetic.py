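"""Seeded generator for formularies and labelled clinical prescriptions.

The generator emulates the shape of a real standard-formulary / clinical
corpus so every other module is testable without any data download:

* a formulary of named formulas whose level sizes follow the reference
  quartiles (chief median 1, deputy 2, assistant 2, envoy 0; ~7 drugs per
  formula) over a shared drug vocabulary.  The vocabulary is stratified
  into a small *common* pool (harmonizing herbs that recur across many
  formulas, typically in assistant/envoy roles) and a larger *distinctive*
  remainder from which chief drugs are drawn, so formulas overlap mostly
  on their low-importance drugs.  A configurable fraction of formulas are
  generated as *variants* of an earlier formula — a level-preserving
  random share of the parent's drugs, topped up with fresh ones —
  mirroring the derivative ("modified") formulas real formularies are
  full of; these relatives are the hard near-miss candidates that pass
  the overlap gate without being correct answers;
* clinical prescriptions built by sampling one or two source formulas,
  keeping each constituent drug with a level-graded probability (chief
  drugs are retained most reliably, envoy drugs least — the generative
  encoding of drug importance), forcing at least one chief drug per source
  so labels stay recoverable, and padding with noise drugs drawn from the
  same vocabulary so that other formulas produce realistic false
  candidates.  Labels are the source formula names.

Everything is driven by one integer seed; identical seeds give identical
data, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formulary import LEVELS, Formulary, Prescription, StandardFormula

__all__ = ["GeneratorConfig", "generate_formulary", "generate_prescriptions", "generate"]

# Per-level size distributions: (sizes, probabilities).  Chosen to hit the
# reference medians/quartiles C1: 1 (1,2), C2: 2 (1,3), C3: 2 (1,4),
# C4: 0 (0,1), totalling ~7 drugs per formula.
DEFAULT_LEVEL_SIZES: Mapping[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "C1": ((1, 2, 3), (0.6, 0.3, 0.1)),
    "C2": ((1, 2, 3, 4), (0.3, 0.3, 0.25, 0.15)),
    "C3": ((0, 1, 2, 3, 4, 5), (0.05, 0.2, 0.3, 0.2, 0.15, 0.1)),
    "C4": ((0, 1, 2), (0.6, 0.3, 0.1)),
}

# Probability that a drug at each level is drawn from the common pool
# rather than the distinctive stratum: chief drugs define a formula and are
# never common; envoy/assistant roles are mostly filled by ubiquitous herbs.
DEFAULT_COMMON_AFFINITY = {"C1": 0.0, "C2": 0.2, "C3": 0.5, "C4": 0.8}


@dataclass(frozen=True)
class GeneratorConfig:
    """Generation parameters; defaults mirror the reference corpus shape.

    376 formulas over a 419-drug vocabulary; 1438 prescriptions of 1-2
    source formulas each, level-graded keep probabilities, and enough
    noise drugs (Poisson mean 6) to land prescription sizes around a
    median of 13 drugs (IQR roughly 11-15).
    """

    n_formulas: int = 376
    vocabulary_size: int = 419
    variant_fraction: float = 0.5
    variant_share: float = 0.75
    common_fraction: float = 0.12
    common_affinity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMMON_AFFINITY)
    )
    level_sizes: Mapping[str, tuple[tuple[int, ...], tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_SIZES)
    )
    n_prescriptions: int = 1438
    formulas_per_prescription: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.4}
    )
    keep_probabilities: tuple[float, float, float, float] = (0.95, 0.85, 0.6, 0.4)
    noise_mean: float = 6.0
    noise_common_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_formulas < 1 or self.vocabulary_size < 1 or self.n_prescriptions < 0:
            raise ValueError("sizes must be positive (prescription count may be 0)")
        for k in LEVELS:
            sizes, probs = self.level_sizes[k]
            if len(sizes) != len(probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"level {k}: sizes and probabilities malformed")
            if any(s < 0 for s in sizes):
                raise ValueError(f"level {k}: negative size")
        if min(self.level_sizes["C1"][0]) < 1:
            raise ValueError("chief level (C1) must have at least one drug")
        if max(sum(max(self.level_sizes[k][0]) for k in LEVELS), 1) > self.vocabulary_size:
            raise ValueError("vocabulary too small for the requested formula sizes")
        for p in self.keep_probabilities:
            if not 0.0 < p <= 1.0:
                raise ValueError("keep probabilities must be in (0, 1]")
        if not 0.0 <= self.common_fraction < 1.0:
            raise ValueError("common_fraction must be in [0, 1)")
        if not 0.0 <= self.variant_fraction <= 1.0:
            raise ValueError("variant_fraction must be in [0, 1]")
        if not 0.0 <= self.variant_share <= 1.0:
            raise ValueError("variant_share must be in [0, 1]")
        if not 0.0 <= self.noise_common_fraction <= 1.0:
            raise ValueError("noise_common_fraction must be in [0, 1]")
        for k in LEVELS:
            if not 0.0 <= self.common_affinity[k] <= 1.0:
                raise ValueError(f"common affinity for {k} must be in [0, 1]")
        if not all(isinstance(k, int) and k >= 1 for k in self.formulas_per_prescription):
            raise ValueError("formulas-per-prescription counts must be positive integers")
        if abs(sum(self.formulas_per_prescription.values()) - 1.0) > 1e-9:
            raise ValueError("formulas-per-prescription probabilities must sum to 1")
        if self.noise_mean < 0:
            raise ValueError("noise mean must be non-negative")


def _vocabulary(config: GeneratorConfig) -> tuple[list[str], int]:
    """Drug names plus the size of the leading common-herb stratum."""
    width = len(str(config.vocabulary_size - 1))
    names = [f"herb-{i:0{width}d}" for i in range(config.vocabulary_size)]
    return names, int(round(config.common_fraction * config.vocabulary_size))


def _draw_drug(
    rng: np.random.Generator,
    level: str,
    used: set[str],
    excluded: set[str],
    common: list[str],
    distinctive: list[str],
    vocab: list[str],
    config: GeneratorConfig,
) -> str:
    """One fresh drug for ``level``, preferring its stratum, avoiding ``used|excluded``."""
    affinity = config.common_affinity[level]
    pool = common if (common and rng.random() < affinity) else distinctive
    avail = [d for d in pool if d not in used and d not in excluded]
    if not avail:
        avail = [d for d in vocab if d not in used and d not in excluded]
    if not avail:
        raise ValueError("vocabulary exhausted while building a formula")
    drug = str(rng.choice(avail))
    used.add(drug)
    return drug


def generate_formulary(config: GeneratorConfig) -> Formulary:
    """Generate ``n_formulas`` standard formulas over the drug vocabulary.

    Within one formula drugs are drawn without replacement (levels are
    disjoint); distinct formulas draw independently and may share drugs,
    and with probability ``variant_fraction`` a formula is instead derived
    from a previously generated one, retaining each parent drug in its
    original role with probability ``variant_share`` (at least one parent
    drug is always replaced, so no two formulas are identical) and filling
    the remaining slots with fresh drugs from outside the parent.
    The full set is the union of the four levels.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    vocab, n_common = _vocabulary(config)
    common = vocab[:n_common]
    distinctive = vocab[n_common:]
    formulas: list[StandardFormula] = []
    seen_full: set[frozenset[str]] = set()
    width = len(str(max(config.n_formulas - 1, 1)))
    for i in range(config.n_formulas):
        for _attempt in range(100):
            used: set[str] = set()
            levels: dict[str, frozenset[str]] = {}
            parent = None
            if formulas and rng.random() < config.variant_fraction:
                parent = formulas[int(rng.integers(0, len(formulas)))]
            if parent is None:
                for k in LEVELS:
                    sizes, probs = config.level_sizes[k]
                    count = int(rng.choice(sizes, p=probs))
                    chosen = {
                        _draw_drug(rng, k, used, set(), common, distinctive, vocab, config)
                        for _ in range(count)
                    }
                    levels[k] = frozenset(chosen)
            else:
                kept: dict[str, set[str]] = {
                    k: {d for d in sorted(parent.level(k)) if rng.random() < config.variant_share}
                    for k in LEVELS
                }
                if sum(len(v) for v in kept.values()) == len(parent.full_set):
                    # force at least one replacement so the variant is a new formula
                    lvl = str(
                        rng.choice(sorted(k for k in LEVELS if kept[k]))
                    )
                    kept[lvl].discard(str(rng.choice(sorted(kept[lvl]))))
                for k in LEVELS:
                    chosen = set(kept[k])
                    used.update(chosen)
                    while len(chosen) < len(parent.level(k)):
                        chosen.add(
                            _draw_drug(
                                rng, k, used, set(parent.full_set), common, distinctive, vocab, config
                            )
                        )
                    levels[k] = frozenset(chosen)
            full = frozenset().union(*levels.values())
            if full and full not in seen_full:
                break
        else:
            raise ValueError("could not generate a distinct formula; vocabulary too small")
        seen_full.add(full)
        formulas.append(
            StandardFormula(
                name=f"formula-{i:0{width}d}",
                levels=levels,
                full_set=full,
                source="synthetic-variant" if parent is not None else "synthetic",
            )
        )
    return Formulary.from_iterable(formulas)


def generate_prescriptions(
    formulary: Formulary, config: GeneratorConfig
) -> list[Prescription]:
    """Generate labelled prescriptions by composing formulas with dropout.

    Each prescription samples 1-2 distinct source formulas, keeps every
    source drug independently with its level's keep probability (at least
    one chief drug is always retained per source), then adds Poisson noise
    drugs from the vocabulary.  Labels are the source formula names.
    """
    if len(formulary) == 0:
        raise ValueError("formulary is empty")
    rng = np.random.default_rng([int(config.seed), 1])
    vocab, n_common = _vocabulary(config)
    common = np.array(vocab[:n_common])
    full_vocab = np.array(vocab)
    names = sorted(f.name for f in formulary)
    k_values = sorted(config.formulas_per_prescription)
    k_probs = [config.formulas_per_prescription[k] for k in k_values]
    keep = dict(zip(LEVELS, config.keep_probabilities))

    out = []
    width = len(str(max(config.n_prescriptions - 1, 1)))
    for i in range(config.n_prescriptions):
        k = int(rng.choice(k_values, p=k_probs))
        k = min(k, len(names))
        sources = rng.choice(names, size=k, replace=False)
        drugs: set[str] = set()
        for name in sources:
            f = formulary[str(name)]
            kept_c1 = 0
            for lvl in LEVELS:
                for drug in sorted(f.level(lvl)):
                    if rng.random() < keep[lvl]:
                        drugs.add(drug)
                        if lvl == "C1":
                            kept_c1 += 1
            if kept_c1 == 0 and f.level("C1"):
                drugs.add(str(rng.choice(sorted(f.level("C1")))))
        n_noise = int(rng.poisson(config.noise_mean))
        for _ in range(n_noise):
            pool = common if (common.size and rng.random() < config.noise_common_fraction) else full_vocab
            drugs.add(str(rng.choice(pool)))
        out.append(
            Prescription(
                id=f"rx-{i:0{width}d}",
                drugs=frozenset(drugs),
                labels=frozenset(str(s) for s in sources),
            )
        )
    return out


def generate(config: GeneratorConfig) -> tuple[Formulary, list[Prescription]]:
    """Generate a matched (formulary, labelled prescriptions) pair."""
    formulary = generate_formulary(config)
    return formulary, generate_prescriptions(formulary, config)
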