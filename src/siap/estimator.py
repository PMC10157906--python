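"""Scikit-learn style estimator wrapping the full train/identify pipeline.

``PrescriptionMatcher`` is a multi-label classifier over drug-name sets:
``fit`` mines training records through the overlap-coefficient gate, fits
the logistic weighting and trains the similarity threshold by bootstrap;
``predict`` returns, for each prescription, the set of standard-formula
names whose weighted similarity reaches the trained threshold.  It follows
the scikit-learn estimator contract (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``check_is_fitted``-style
errors) so it composes with sklearn model selection where applicable.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import evaluation, matcher, training
from .formulary import Formulary, Prescription
from .matcher import VARIANTS, MatchResult
from .training import ThresholdCurve, WeightModel

__all__ = ["PrescriptionMatcher"]


def _as_prescriptions(X: Sequence, y: Sequence | None) -> list[Prescription]:
    out = []
    for i, x in enumerate(X):
        labels = frozenset(y[i]) if y is not None else None
        if isinstance(x, Prescription):
            out.append(x if y is None else Prescription(x.id, x.drugs, labels))
        else:
            out.append(Prescription(id=f"x{i}", drugs=frozenset(x), labels=labels))
    return out


class PrescriptionMatcher(BaseEstimator):
    """Multi-label matcher of prescriptions to standard formulas.

    Parameters
    ----------
    formulary : Formulary
        The standard formulas to match against (levels C1..C4 + full set).
    variant : {"SIAP+All", "SIAP-All", "ISR"}
        Scoring variant: weighted similarity over d1..d5, over d1..d4, or
        the plain full-set overlap fraction baseline.
    isr_threshold : float, default 0.5
        Overlap gate used to mine training records.
    grid_step : float, default 0.05
        Threshold-grid resolution over [0, 1].
    boot_n, boot_reps : int
        Bootstrap resample size and repetition count for threshold search.
    random_state : int, default 0
        Seed for the bootstrap resampling.

    Attributes
    ----------
    model_ : WeightModel
        Trained variant weights and similarity threshold.
    weights_ : tuple of 5 floats
        Normalized weights for d1..d5 (inactive components zero).
    threshold_ : float
        Trained similarity threshold.
    curve_ : ThresholdCurve
        Bootstrap-mean precision/recall/F1 over the threshold grid.
    """

    def __init__(
        self,
        formulary: Formulary | None = None,
        variant: str = "SIAP+All",
        isr_threshold: float = 0.5,
        grid_step: float = 0.05,
        boot_n: int = 200,
        boot_reps: int = 100,
        random_state: int = 0,
    ):
        self.formulary = formulary
        self.variant = variant
        self.isr_threshold = isr_threshold
        self.grid_step = grid_step
        self.boot_n = boot_n
        self.boot_reps = boot_reps
        self.random_state = random_state

    def _validate(self) -> None:
        if self.formulary is None or len(self.formulary) == 0:
            raise ValueError("a non-empty formulary is required")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if not 0.0 <= self.isr_threshold <= 1.0:
            raise ValueError("isr_threshold must be in [0, 1]")
        if self.boot_n < 1 or self.boot_reps < 1:
            raise ValueError("boot_n and boot_reps must be positive")

    def fit(self, X: Sequence, y: Sequence | None = None) -> "PrescriptionMatcher":
        """Train weights and threshold on labelled prescriptions.

        ``X`` is a sequence of :class:`Prescription` or of drug-name
        iterables; ``y`` the per-sample sets of true formula names
        (optional when X are already-labelled prescriptions).
        """
        self._validate()
        prescriptions = _as_prescriptions(X, y)
        model, curve = training.train_full(
            prescriptions,
            self.formulary,
            variant=self.variant,
            isr_threshold=self.isr_threshold,
            grid_step=self.grid_step,
            boot_n=self.boot_n,
            boot_reps=self.boot_reps,
            seed=self.random_state,
        )
        self.model_ = model
        self.curve_ = curve
        self.weights_ = model.weights
        self.threshold_ = model.threshold
        return self

    def _check_fitted(self) -> WeightModel:
        if not hasattr(self, "model_"):
            raise NotFittedError("PrescriptionMatcher is not fitted; call fit first")
        return self.model_

    def predict(self, X: Sequence) -> list[frozenset[str]]:
        """Predicted formula-name set for each prescription."""
        model = self._check_fitted()
        return [
            matcher.identified_names(matcher.identify(p, self.formulary, model))
            for p in _as_prescriptions(X, None)
        ]

    def match(self, drugs: Iterable[str] | Prescription) -> list[MatchResult]:
        """Full ranked match detail (name, distances, similarity) for one query."""
        model = self._check_fitted()
        return matcher.identify(drugs, self.formulary, model)

    def score(self, X: Sequence, y: Sequence) -> float:
        """Micro-averaged F1 of predictions against true label sets."""
        model = self._check_fitted()
        m, _ = evaluation.evaluate(model, _as_prescriptions(X, y), self.formulary)
        return m.f1
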