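# Methods

This note documents the models and procedures implemented in `raacfam`,
the defaults they use, and the design choices made where the design was
genuinely open.

## Reduced alphabets

A reduction scheme is an ordered partition of the 20 canonical amino acids
into `s` disjoint, non-empty groups (2 ≤ s ≤ 19).  The representative of a
group — the symbol sequences are rewritten to — is its **first listed
letter**; no convention is standard in scheme catalogs, and first-letter is
deterministic and matches how catalogs display groups.  The built-in
type-33 family (sizes 2–19) is a nested hierarchy derived from
structure-alignment substitution scores; its coarsest split separates
polar (`STANDGRQEKHP`) from hydrophobic (`IVLMWYF`) residues, with
cysteine always its own group.  The package validates every scheme against
the partition invariants and asserts the nesting property of the built-in
family in its tests.

Non-canonical residues (B, J, O, U, X, Z, and the `*` stop symbol) appear
in real database sequences.  Default policy is `drop` with a per-sequence
count kept on the result; a strict `error` policy is available.  Input is
case-insensitive.

## K-mer composition features

For k ∈ {1, 2, 3}, a reduced sequence of length L yields the frequency
vector of its L−k+1 overlapping k-mers over the s^k possible words,
ordered lexicographically by group index.  The denominator is the window
count L−k+1, so every row sums to exactly 1; this normalization makes
sequences of different lengths comparable.  k is capped at 3 — the feature
space grows as s^k and tripeptides are the largest composition used;
larger k raises an explicit error.  Each fitted model uses a single
(scheme, k) encoding; a concatenation helper for multi-descriptor feature
maps exists but is not the default path.  Sequences shorter than k are
skipped with a logged count (an all-skipped class is an error).

## Feature ranking and incremental selection

Each feature is scored by the standard two-group one-way ANOVA F
statistic: with group sizes n_a, n_b and grand mean m,

    MS_between = n_a (m_a − m)² + n_b (m_b − m)²        (df = 1)
    MS_within  = (SS_a + SS_b) / (n − 2)
    F = MS_between / MS_within.

Ranking is by descending F with ties broken by ascending feature index
(determinism).  Degenerate features need care in floating point: an
exactly constant column accumulates O(ε²) rounding noise in *both* sums of
squares, whose ratio is an arbitrary finite number, so zero-variance
detection is scale-aware (a sum of squares below `n·scale²·1e-24` is
treated as zero).  All-constant features score 0; zero-within-variance
features with separated means rank first with their score capped at the
largest finite F.  The implementation is cross-checked in the tests
against `scipy.stats.f_oneway` and an independently written brute-force
formula to 1e-10 relative tolerance.

IFS sweeps dimensions `step, 2·step, …` (the final dimension is always
included) and selects the smallest dimension attaining the maximum
cross-validated accuracy.  Default `step=1`; a coarser step is a speed
knob that changes only the resolution of the curve.  By default the SVM
hyperparameters are fixed by one grid search at full dimension and reused
across the sweep (`retune=True` re-optimizes at every prefix; it is much
slower and rarely changes the selected dimension).

## SVM and grid search

The classifier is `sklearn.svm.SVC` with an RBF kernel.  The search
lattice is C ∈ {2⁻⁴, 2⁻², …, 2¹⁴} and γ ∈ {2⁻¹⁴, 2⁻¹², …, 2²} (exponent
step 2), strictly inside the open intervals 2⁻⁵ < C < 2¹⁵ and
2⁻¹⁵ < γ < 2³; the bounds are part of the method, the granularity is a
package default.  Cells are scored by the accuracy of pooled out-of-fold
predictions under seeded stratified k-fold CV (default 10 folds); the
lattice is traversed in ascending (C, γ) order and only strict
improvements replace the incumbent, so ties resolve to the smallest C,
then the smallest γ.  Compositions are already bounded in [0, 1], so no
further feature scaling is applied.  Class weighting is off by default
(the intended training sets are near-balanced).  Probability estimates
come from the SVM's built-in pairwise-coupling calibration, seeded.

## Cross-validation reporting and selection bias

Pooled metrics (all out-of-fold predictions scored together) are the
default report; per-fold reports are also returned.  One empirical finding
shaped the design: ranking hundreds of features on the full dataset and
then cross-validating on the top-d columns materially inflates the pooled
score (on a label-permuted 480×225 benchmark the inflated estimate was
0.64 instead of 0.5, almost all of it from ranking leakage rather than
grid-search winner's curse).  The final report produced by
`ProteinFamilyModel.fit` therefore **re-ranks features inside each
training fold** at the selected dimension (`nested_cv_report`): under a
permutation null it returns chance, and on real signal it is an honest
estimate of the select-then-classify procedure.  The IFS curve itself uses
the conventional rank-once sweep and serves only to choose the dimension.

## Evaluation metrics

Sn, Sp, F1, Acc and MCC are computed directly from the confusion counts.
A metric whose denominator is zero is returned as *undefined with a
reason*, never silently 0 or NaN — a zero marginal means the evaluation is
degenerate and the caller should see that.  AUC is the Mann–Whitney rank
statistic (ties at half credit), which equals the trapezoidal area under
the ROC curve; the equality is asserted in tests to 1e-12.  ROC points
come from a standard threshold sweep (`sklearn.metrics.roc_curve`).

## Synthetic benchmark

The generator emulates what a composition-based family classifier
exploits:

- **Motif**: every positive carries one realization of a degenerate motif
  (default `HxD-H`: His, any, Asp, spacer, His — the iron-binding facial
  triad pattern of 2OG oxygenases, which is fully conserved in the family,
  hence `motif_noise = 0` by default).  `x` is any canonical letter; `-`
  is a spacer of background letters with length uniform in `spacer_range`
  (default 5–15).  The motif overwrites a uniformly placed window of the
  background sequence.
- **Compositional tilt**: positive backgrounds are drawn from
  `(1 − b)·background + b·uniform(polar group)` with `positive_bias`
  b = 0.25 by default, mirroring the observation that family signal
  concentrates along the polar/hydrophobic partition.
- **Scale**: 240 sequences per class (the scale of curated two-class
  enzyme benchmarks), lengths uniform in 100–300.
- **Background**: uniform 1/20 by default, which gives clean closed-form
  motif match probabilities for tests (for `HxD-H`, a window matches with
  probability (1/20)³); a SwissProt-like composition is available as a
  named preset.

What it deliberately does not emulate: phylogenetic correlation between
sequences, domain architecture, length/composition confounds, or database
redundancy.  Passing tests on this generator therefore demonstrates that
the pipeline recovers a planted motif-plus-composition signal at realistic
n and chance on permuted labels — not that any particular accuracy will be
achieved on real corpora.

With the defaults above, the full pipeline (size-15 dipeptide encoding,
ANOVA rank, IFS at step 15 over the 225 features, grid-searched SVM,
10-fold pooled CV) lands at roughly 89–93% accuracy depending on the seed,
i.e. the same regime as published full-corpus results, and at chance after
label permutation.  Step 15 and the 240/class scale are the package's
desk-scale defaults; both are ordinary knobs.

## Redundancy filter

`identity_filter` is a greedy single-linkage filter: sequences are
processed in input order and one is dropped when its ungapped identity
(matching positions over the shorter length, aligned from the start)
**strictly exceeds** the threshold against an already-retained sequence,
or when it is an exact duplicate of one.  The strict inequality plus the
exact-duplicate clause makes `threshold = 1.0` remove exact duplicates
only (a prefix scores identity 1.0 over the shorter length but is not a
duplicate).  This is a documented approximation of CD-HIT-style
clustering, not a reimplementation: no gapped alignment, no word
filtering, no cluster re-sorting by length.

## Scheme-space scan

`raacfam scan` evaluates every (scheme, k) cell of a factorial grid by
pooled CV accuracy.  By default each cell uses a fixed mid-range operating
point (C = 32, γ = 1/n_features) so the scan compares encodings rather
than per-cell tuning luck and the 18-scheme × 3-k factorial stays cheap;
`--grid` enables the full search per cell.  Per-cell failures are recorded
in the output table and the scan continues.  The best cell is the grid
maximum, ties resolved to the lexicographically smallest (type, size, k).

## Persistence and reproducibility

Models are saved with joblib as a versioned payload embedding the scheme,
k, selected feature indices, chosen (C, γ) and the CV report; loading
validates the format version.  All randomness flows through explicit
seeds: the simulation RNG, the stratified fold shuffler and the SVM
probability calibration are seeded, so simulation output is byte-identical
and fold assignment, chosen hyperparameters and reports are bit-identical
under a fixed seed.

## Known limitations

- The ANOVA-F ranking considers features one at a time; correlated or
  jointly informative features are ranked marginally.
- The identity filter is order-dependent and approximate (see above).
- The grid granularity (exponent step 2) trades resolution for runtime;
  published applications of this method do not state their step.
- Probabilities come from pairwise-coupling calibration on the training
  data and can be optimistic on small sets.
- Accuracy estimates on the synthetic benchmark transfer to real corpora
  only in the qualitative sense described above.
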