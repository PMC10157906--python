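"""Weight-model training: labelled records, logistic weighting, threshold search.

Training proceeds in three stages:

1. *Record building.*  The overlap-coefficient baseline (ISR) at a 0.5
   gate is run over the labelled training prescriptions: every
   (prescription, candidate) pair whose full-set distance ``d5`` reaches
   the gate becomes a training record, positive when the candidate's name
   is among the prescription's manual labels and negative otherwise.  The
   negatives mined this way share drugs with real matches, which is what
   makes them informative.

2. *Logistic weighting.*  An unregularized maximum-likelihood logistic
   model ``logit(Y) = β0 + Σ β_i d_i`` is fit on the variant's active
   distance coefficients (d1..d4 without the full-set term, d1..d5 with
   it).  Because the raw coefficients live on the scale of their
   predictors, each is standardized as ``β'_i = |β_i| · √3 · S_i / π``
   (S_i the sample standard deviation of d_i) and the standardized
   coefficients are normalized to weights ``w_i = β'_i / Σ β'_i``.

3. *Threshold search.*  The decision threshold is chosen on a grid over
   [0, 1] by bootstrap: at each grid point, resamples of the training
   prescriptions are scored (micro precision/recall/F1) and the threshold
   maximizing the mean F1 is kept (ties go to the smallest threshold).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .evaluation import f1_score
from .formulary import Formulary, Prescription
from .matcher import (
    ACTIVE_COMPONENTS,
    VARIANTS,
    DistanceVector,
    candidate_set,
    distance_vector,
    similarity,
)

__all__ = [
    "TrainingDataError",
    "TrainingRecord",
    "WeightModel",
    "ThresholdCurve",
    "LogisticFit",
    "build_training_records",
    "fit_logistic",
    "standardize",
    "normalize_weights",
    "train_threshold",
    "train_full",
    "save_model",
    "load_model",
]

SQRT3_OVER_PI = math.sqrt(3.0) / math.pi


class TrainingDataError(ValueError):
    """The labelled data cannot support training (no records, one class, ...)."""


@dataclass(frozen=True)
class TrainingRecord:
    prescription_id: str
    formula_name: str
    distances: DistanceVector
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class WeightModel:
    """A trained scoring model: variant, coefficients, weights, threshold.

    ``betas``, ``sds`` and ``beta_primes`` are five-vectors aligned with
    d1..d5; the ISR baseline carries no fitted coefficients.  ``weights``
    is a five-vector whose inactive components are zero and whose active
    components sum to one.
    """

    variant: str
    weights: tuple[float, ...]
    threshold: float
    beta0: float | None = None
    betas: tuple[float, ...] | None = None
    sds: tuple[float, ...] | None = None
    beta_primes: tuple[float, ...] | None = None
    p_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        w = tuple(float(x) for x in self.weights)
        if len(w) != 5:
            raise ValueError("weights must have five components (inactive ones zero)")
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        active = ACTIVE_COMPONENTS[self.variant]
        if abs(sum(w[i] for i in active) - 1.0) > 1e-9:
            raise ValueError("active weights must sum to 1")
        if any(abs(w[i]) > 0 for i in range(5) if i not in active):
            raise ValueError("inactive weight components must be zero")
        object.__setattr__(self, "weights", w)
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold {self.threshold} outside [0, 1]")
        if self.betas is not None and self.sds is not None and self.beta_primes is not None:
            for i in range(5):
                expected = standardize(self.betas[i], self.sds[i])
                if not math.isclose(self.beta_primes[i], expected, rel_tol=1e-9, abs_tol=1e-12):
                    raise ValueError(
                        f"beta_prime[{i}] = {self.beta_primes[i]} inconsistent with "
                        f"|beta|*sqrt(3)*S/pi = {expected}"
                    )


@dataclass(frozen=True)
class ThresholdCurve:
    """Bootstrap-mean precision/recall/F1 over a threshold grid."""

    grid: tuple[float, ...]
    mean_precision: tuple[float, ...]
    mean_recall: tuple[float, ...]
    mean_f1: tuple[float, ...]

    def __post_init__(self) -> None:
        g = self.grid
        if any(b <= a for a, b in zip(g, g[1:])) or g[0] < 0 or g[-1] > 1:
            raise ValueError("grid must be strictly increasing within [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold,precision,recall,f1\n")
            for t, p, r, f1 in zip(self.grid, self.mean_precision, self.mean_recall, self.mean_f1):
                fh.write(f"{t:.6g},{p:.6f},{r:.6f},{f1:.6f}\n")

    @property
    def best_threshold(self) -> float:
        best = int(np.argmax(self.mean_f1))  # first max -> smallest threshold
        return self.grid[best]


def build_training_records(
    prescriptions: Sequence[Prescription],
    formulary: Formulary,
    isr_threshold: float = 0.5,
) -> list[TrainingRecord]:
    """Mine labelled (prescription, candidate) records through the ISR gate.

    A record is emitted for every candidate whose full-set overlap fraction
    ``d5`` reaches ``isr_threshold`` (>= comparison); its label is 1 when
    the candidate name is among the prescription's manual labels.
    """
    records: list[TrainingRecord] = []
    for p in prescriptions:
        if p.labels is None:
            raise TrainingDataError(f"prescription {p.id!r} has no labels")
        for f in candidate_set(p.drugs, formulary):
            d = distance_vector(p.drugs, f)
            if d.d5 >= isr_threshold:
                records.append(
                    TrainingRecord(
                        prescription_id=p.id,
                        formula_name=f.name,
                        distances=d,
                        label=int(f.name in p.labels),
                    )
                )
    if not records:
        raise TrainingDataError(
            f"no (prescription, candidate) pairs pass the ISR gate at {isr_threshold}"
        )
    return records


@dataclass(frozen=True)
class LogisticFit:
    """Unregularized logistic fit over the five distance predictors.

    Dropped predictors (constant or perfectly separating) carry β = 0 and
    p-value NaN; ``dropped`` lists their indices.
    """

    beta0: float
    betas: tuple[float, ...]
    sds: tuple[float, ...]
    p_values: tuple[float, ...]
    dropped: tuple[int, ...] = field(default_factory=tuple)


def _separating_columns(X: np.ndarray, y: np.ndarray) -> list[int]:
    """Columns that perfectly separate the two classes on their own."""
    out = []
    for j in range(X.shape[1]):
        pos, neg = X[y == 1, j], X[y == 0, j]
        if pos.min() > neg.max() or neg.min() > pos.max():
            out.append(j)
    return out


def fit_logistic(
    records: Sequence[TrainingRecord],
    predictors: Sequence[int] = (0, 1, 2, 3, 4),
) -> LogisticFit:
    """Maximum-likelihood logistic regression of label on distance coefficients.

    ``predictors`` are 0-based indices into (d1..d5); the default uses all
    five.  Standard deviations use the unbiased (n-1) denominator.
    Constant and perfectly separating predictors are dropped with a warning
    (their β and β' become 0), keeping the downstream weight normalization
    well defined.
    """
    if not records:
        raise TrainingDataError("no training records")
    y = np.array([r.label for r in records], dtype=float)
    if y.min() == y.max():
        raise TrainingDataError("training records contain a single class")
    D = np.array([r.distances.as_tuple() for r in records], dtype=float)
    X = D[:, list(predictors)]
    sds_full = np.zeros(5)
    sds_full[list(predictors)] = D[:, list(predictors)].std(ddof=1, axis=0)

    keep = list(range(X.shape[1]))
    dropped_local: list[int] = []
    for j in range(X.shape[1]):
        if X[:, j].std() == 0.0:
            dropped_local.append(j)
    for j in _separating_columns(X, y):
        if j not in dropped_local:
            dropped_local.append(j)
    if dropped_local:
        names = [f"d{predictors[j] + 1}" for j in sorted(dropped_local)]
        warnings.warn(
            f"dropping predictor(s) {names} (constant or perfectly separating); "
            "their weight contribution is set to 0",
            stacklevel=2,
        )
        keep = [j for j in keep if j not in dropped_local]
    if not keep:
        raise TrainingDataError("every predictor is degenerate")

    design = sm.add_constant(X[:, keep], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels convergence chatter
        logit = sm.Logit(y, design)
        try:
            result = logit.fit(disp=0, maxiter=200)
            ok = np.all(np.isfinite(result.params))
        except Exception:
            ok = False
        if not ok:
            result = logit.fit(disp=0, maxiter=500, method="lbfgs")

    betas = np.zeros(5)
    pvals = np.full(5, np.nan)
    for pos, j in enumerate(keep):
        betas[predictors[j]] = result.params[pos + 1]
        pvals[predictors[j]] = result.pvalues[pos + 1]
    dropped = tuple(predictors[j] for j in sorted(dropped_local))
    return LogisticFit(
        beta0=float(result.params[0]),
        betas=tuple(betas),
        sds=tuple(sds_full),
        p_values=tuple(pvals),
        dropped=dropped,
    )


def standardize(beta_i: float, S_i: float) -> float:
    """Standardized logistic coefficient ``β' = |β| · √3 · S / π``.

    The √3/π factor converts the logistic latent scale (variance π²/3) so
    that coefficients of predictors with different spreads become
    comparable; a constant predictor (S = 0) standardizes to 0.
    """
    if S_i < 0:
        raise ValueError("standard deviation must be non-negative")
    return abs(beta_i) * SQRT3_OVER_PI * S_i


def normalize_weights(beta_primes: Sequence[float]) -> list[float]:
    """Normalize standardized coefficients to weights summing to 1."""
    total = float(sum(beta_primes))
    if any(b < 0 for b in beta_primes):
        raise ValueError("standardized coefficients must be non-negative")
    if total <= 0:
        raise TrainingDataError("all standardized coefficients are zero; model is degenerate")
    return [float(b) / total for b in beta_primes]


# ---------------------------------------------------------------------------
# threshold search


def _threshold_grid(grid_step: float) -> tuple[float, ...]:
    n = round(1.0 / grid_step)
    if not math.isclose(n * grid_step, 1.0, rel_tol=1e-9) or n < 1:
        raise ValueError(f"grid step {grid_step} must divide 1 evenly")
    return tuple(i / n for i in range(n + 1))


def train_threshold(
    model: WeightModel,
    prescriptions: Sequence[Prescription],
    formulary: Formulary,
    grid_step: float = 0.05,
    boot_n: int = 200,
    boot_reps: int = 100,
    seed: int = 0,
) -> tuple[float, ThresholdCurve]:
    """Pick the similarity threshold maximizing bootstrap-mean F1.

    For each grid threshold, ``boot_reps`` resamples of ``boot_n``
    prescriptions are drawn uniformly with replacement and scored with the
    micro-averaged metrics; the grid point with the highest mean F1 wins,
    ties going to the smallest threshold.  Randomness: one
    ``numpy.random.default_rng(seed)`` stream, consumed as a single
    ``integers(0, n, size=(boot_reps, boot_n))`` draw per grid point in
    grid order, so runs are bit-reproducible.
    """
    grid = _threshold_grid(grid_step)
    n = len(prescriptions)
    if n == 0:
        raise TrainingDataError("no prescriptions for threshold training")

    # Per-prescription candidate sims and truth flags, computed once.
    sims: list[np.ndarray] = []
    is_true: list[np.ndarray] = []
    n_truth = np.zeros(n, dtype=np.int64)
    for i, p in enumerate(prescriptions):
        if p.labels is None:
            raise TrainingDataError(f"prescription {p.id!r} has no labels")
        cand = candidate_set(p.drugs, formulary)
        s = np.array([similarity(distance_vector(p.drugs, f), model) for f in cand])
        t = np.array([f.name in p.labels for f in cand], dtype=bool)
        sims.append(s)
        is_true.append(t)
        n_truth[i] = len(p.labels)

    # Per-threshold, per-prescription confusion contributions.
    f11 = np.zeros((len(grid), n), dtype=np.int64)
    f12 = np.zeros((len(grid), n), dtype=np.int64)
    for i in range(n):
        if sims[i].size == 0:
            continue
        hit = sims[i][None, :] >= np.asarray(grid)[:, None]
        f11[:, i] = (hit & is_true[i][None, :]).sum(axis=1)
        f12[:, i] = (hit & ~is_true[i][None, :]).sum(axis=1)
    f21 = n_truth[None, :] - f11

    rng = np.random.default_rng(seed)
    mean_p, mean_r, mean_f = [], [], []
    for ti in range(len(grid)):
        idx = rng.integers(0, n, size=(boot_reps, boot_n))
        a = f11[ti][idx].sum(axis=1).astype(float)
        b = f12[ti][idx].sum(axis=1).astype(float)
        c = f21[ti][idx].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(a + b > 0, a / (a + b), 0.0)
            rec = np.where(a + c > 0, a / (a + c), 0.0)
            f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
        mean_p.append(float(prec.mean()))
        mean_r.append(float(rec.mean()))
        mean_f.append(float(f1.mean()))

    curve = ThresholdCurve(
        grid=grid,
        mean_precision=tuple(mean_p),
        mean_recall=tuple(mean_r),
        mean_f1=tuple(mean_f),
    )
    return curve.best_threshold, curve


def train_full(
    prescriptions: Sequence[Prescription],
    formulary: Formulary,
    variant: str = "SIAP+All",
    isr_threshold: float = 0.5,
    grid_step: float = 0.05,
    boot_n: int = 200,
    boot_reps: int = 100,
    seed: int = 0,
) -> tuple[WeightModel, ThresholdCurve]:
    """End-to-end training: records → logistic weights → threshold.

    The ISR baseline skips the fitting stage entirely (its similarity is
    the full-set overlap fraction, weight 1 on d5) and only trains the
    threshold.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "ISR":
        weights = (0.0, 0.0, 0.0, 0.0, 1.0)
        provisional = WeightModel(variant=variant, weights=weights, threshold=0.0)
        thr, curve = train_threshold(
            provisional, prescriptions, formulary, grid_step, boot_n, boot_reps, seed
        )
        return WeightModel(variant=variant, weights=weights, threshold=thr), curve

    records = build_training_records(prescriptions, formulary, isr_threshold)
    fit = fit_logistic(records, predictors=ACTIVE_COMPONENTS[variant])
    beta_primes = tuple(standardize(b, s) for b, s in zip(fit.betas, fit.sds))
    active = ACTIVE_COMPONENTS[variant]
    normalized = normalize_weights([beta_primes[i] for i in active])
    weights = [0.0] * 5
    for i, w in zip(active, normalized):
        weights[i] = w
    provisional = WeightModel(
        variant=variant,
        weights=tuple(weights),
        threshold=0.0,
        beta0=fit.beta0,
        betas=fit.betas,
        sds=fit.sds,
        beta_primes=beta_primes,
        p_values=fit.p_values,
    )
    thr, curve = train_threshold(
        provisional, prescriptions, formulary, grid_step, boot_n, boot_reps, seed
    )
    model = WeightModel(
        variant=variant,
        weights=tuple(weights),
        threshold=thr,
        beta0=fit.beta0,
        betas=fit.betas,
        sds=fit.sds,
        beta_primes=beta_primes,
        p_values=fit.p_values,
    )
    return model, curve


# ---------------------------------------------------------------------------
# model serialization


def save_model(model: WeightModel, path: str | Path, config: Mapping | None = None) -> None:
    doc = {
        "variant": model.variant,
        "beta0": model.beta0,
        "betas": list(model.betas) if model.betas is not None else None,
        "sds": list(model.sds) if model.sds is not None else None,
        "beta_primes": list(model.beta_primes) if model.beta_primes is not None else None,
        "p_values": list(model.p_values) if model.p_values is not None else None,
        "weights": list(model.weights),
        "threshold": model.threshold,
        "config": dict(config) if config else {},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True, allow_nan=True))


def load_model(path: str | Path) -> WeightModel:
    doc = json.loads(Path(path).read_text())
    opt = lambda k: tuple(doc[k]) if doc.get(k) is not None else None
    return WeightModel(
        variant=doc["variant"],
        weights=tuple(doc["weights"]),
        threshold=float(doc["threshold"]),
        beta0=doc.get("beta0"),
        betas=opt("betas"),
        sds=opt("sds"),
        beta_primes=opt("beta_primes"),
        p_values=opt("p_values"),
    )
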