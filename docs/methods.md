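# Methods

This note documents the model, the estimation choices, the synthetic data
generator and its limits, and the design decisions taken where the design
was genuinely open.

## Model and assumptions

Drug identity is exact string equality after case-folding, whitespace
trimming and synonym mapping.  There is no fuzzy matching: name
standardization is assumed to have happened upstream (a synonym dictionary
can be supplied).  Doses, frequencies and preparation methods are ignored
throughout — a prescription is a set.

A standard formula carries four disjoint importance levels C1..C4 and a
full composition set (the C5 role) that may also contain unlevelled drugs;
unlevelled drugs contribute only to the full-set distance.  For a
prescription *A* and level set *B*, the distance coefficient is the
coverage fraction d = |A∩B|/|B|.  Note the asymmetry: d measures how much
of the *formula's* requirement is met, not how much of the prescription is
explained, so a large compound prescription can fully match several small
formulas at once — which is the point of the method.

**Empty levels score d = 1.**  A requirement with no members is vacuously
met.  The envoy level is empty for roughly half of formulas (its median
size is 0), so 0/0 is routine; scoring it 1 avoids penalizing formulas for
lacking a level.  The alternative (d = 0) would make any formula without
an envoy drug unmatchable at high thresholds.

**Threshold comparison is attainment (sim ≥ t).**  This makes t = 1
attainable by exact matches.  An exact cover returns sim exactly 1.0
(special-cased so floating-point round-off in the weight sum can never
exclude an exact match at threshold 1).  When no candidate reaches the
threshold the output is empty — there is no forced top-1 fallback.
Output order is similarity descending, name ascending: byte-reproducible.

## Weight estimation

Training records are (prescription, candidate) pairs passing the overlap
gate d₅ ≥ 0.5, labelled by whether the candidate is among the manual
labels.  The gate is attainment (≥), consistent with the thresholding
convention above.

The logistic fit is plain maximum likelihood (Newton, with an L-BFGS
fallback if the Hessian is singular), no regularization — the
standardized-coefficient formula β′ = |β|·√3·S/π presumes unshrunk ML
coefficients.  S is the sample standard deviation of the predictor over
the records with the unbiased (n−1) denominator.  Wald p-values are
carried on the model for transparency.  Constant and perfectly separating
predictors are dropped with a warning and enter the weight normalization
with β′ = 0, keeping w = β′/Σβ′ well defined.

**Each variant fits its own predictor set** — d₁..d₄ for the weighted
variant without the full-set term (SIAP-All), d₁..d₅ with it (SIAP+All).
Including d₅ alongside the level distances changes what the level
coefficients mean: conditional on overall coverage, a true match's
coverage concentrates on the high-importance levels, which pushes the
partial coefficients of the low-importance levels toward zero or below,
and the absolute value in the standardization then scrambles the weight
ordering.  Fitting the per-level variant without d₅ preserves the graded
marginal contrasts that the weights are meant to encode.  The two
variants' weight normalizations still agree when the full-set
coefficient is forced to zero.

The ISR baseline has no fitting stage: its similarity is d₅ itself
(weight vector (0,0,0,0,1)); only its threshold is trained.

## Threshold training

The grid is 0, 0.05, …, 1.0 by default (step configurable down to 0.01;
the step must divide 1 evenly).  At each grid point, 100 bootstrap
resamples of 200 prescriptions are drawn uniformly with replacement at
the prescription level, each scored with the micro-averaged F1, and the
means form the threshold curve; the smallest threshold attaining the
maximal mean F1 wins.  All randomness flows from one integer seed through
a single `numpy.random.default_rng` stream, consumed as one
`integers(0, n, size=(reps, boot_n))` draw per grid point in grid order —
documented so an independent reimplementation can reproduce runs bit for
bit.  Per-resample metrics with empty predictions define the affected
ratio as 0 (in ordinary evaluation this case warns; inside the bootstrap
the convention is applied silently since high grid points routinely empty
the predictions).

## Evaluation conventions

Counts are micro-aggregated across samples before the ratios are formed
(never macro-averaged per sample).  Zero denominators define the metric
as 0 with a warning.  Per-sample reports list truth, predictions, missed
and spurious names.

## The synthetic data generator

No suitable formulary/clinical corpus is freely redistributable, so the
generator emulates the documented shape of such corpora and every claim
the test suite makes about real-data behaviour should be read through it.

* **Formulary** — 376 formulas over a 419-drug vocabulary; per-level size
  distributions with medians (C1, C2, C3, C4) = (1, 2, 2, 0) and roughly
  7 drugs per formula.  The vocabulary is stratified: 12% of it is a
  *common-herb* pool (harmonizing drugs that recur across formulas), and
  the probability of filling a slot from that pool grows with level
  (0 / 0.2 / 0.5 / 0.8 for C1..C4) — chief drugs define a formula and are
  distinctive, envoy drugs are ubiquitous.  Half of the formulas are
  generated as *variants* of an earlier formula, retaining each parent
  drug in its original role with probability 0.75 (at least one drug is
  always replaced) and refilling the rest — the derivative "modified"
  formulas that real formularies contain in abundance.  These two
  mechanisms are what make overlap-gated negative training examples
  realistic: near-miss relatives and common-herb coincidences, not
  uniform random noise.
* **Prescriptions** — 1438 prescriptions; each samples 1–2 source
  formulas (60/40), keeps each source drug with its level's probability
  (defaults 0.95 / 0.85 / 0.6 / 0.4, always retaining at least one chief
  drug per source so labels stay recoverable), and adds Poisson(6) noise
  drugs drawn half from the common pool.  Resulting sizes have median
  ~13 drugs, interquartile range roughly 11–15.
* **Determinism** — one integer seed drives everything; formulary and
  prescriptions consume independent substreams of it.

What the generator does **not** model: herb co-occurrence pharmacology,
dose, syndrome or indication structure, the long-tailed popularity of
real herbs beyond the two-stratum approximation, and annotator
disagreement in the manual labels (labels are exact by construction).
Passing tests therefore demonstrate correctness of the algorithms and
recoverability of graded importance under the stated generative
assumptions, not clinical performance.

## Problem sizes used in tests and the acceptance script

The acceptance script trains all three variants on 1000 synthetic
prescriptions and evaluates on the remaining 438 (mirroring a 70/30 split
of 1438), runs the noiseless-limit exact-recovery check at 50 formulas /
100 prescriptions, and measures weight-ordering recovery over 20 seeded
replicates of the full corpus.  Unit and property tests use smaller
corpora (tens of formulas, ~150 prescriptions) chosen to keep the suite
fast while still exercising multi-formula prescriptions, false candidates
and threshold training end to end.

## Known limitations

* The empty-level convention means a formula consisting mostly of empty
  levels is easy to match at the level distances; the full-set distance
  (and the candidate gate) is what keeps such matches in check.
* Bootstrap threshold selection optimizes mean F1 only; no uncertainty
  band is attached to the chosen threshold (the curve is exported so
  users can inspect flatness).
* Weight recovery assumes the labelled corpus contains hard negatives
  (near-miss candidates).  On a corpus whose false candidates are all
  trivial, the logistic fit may separate perfectly and degrade to
  dropped predictors.
* The standardization uses |β|: a genuinely *negative* association
  (a level whose coverage argues against a match) would be folded into a
  positive weight.  This is inherent to the weighting scheme, one reason
  the per-variant predictor sets matter.
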