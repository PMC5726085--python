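# Methods

This note documents the models, numerical choices and limitations behind
`citescreen` — what the code computes, why the defaults are what they are,
and what the synthetic experiments do and do not show.

## Problem setting

Pool-based screening: the complete list of `n` citations is available up
front and a reviewer labels them incrementally (1 = eligible, 0 =
ineligible).  Because the pool is fixed, corpus-level statistics — document
frequencies for TF-IDF and the spectral embedding — are computed over the
full pool, labelled and unlabelled alike (a transductive setting).  The
goal is to surface eligible citations as early as possible while the
classifier's predictions on the unscreened remainder stay trustworthy.

## Text model

Title and abstract are pooled into one bag of words per citation; the two
fields are not weighted separately.  Tokenisation is deliberately minimal
and reproducible: lowercase, split on any non-alphanumeric run, keep all
tokens of length ≥ 1, no stemming and no stop-word removal (a `stop_words`
hook exists, off by default).  TF-IDF uses the natural logarithm; the base
only rescales the matrix by a constant and cancels in both cosine and
Bhattacharyya similarity, so it is a pure convention.  A token present in
every citation has `f_w = 1` and contributes a zero column; a citation all
of whose tokens do is left as a zero row, flagged degenerate, and excluded
wherever a direction is needed (cosine distances, propagation,
similarity) — it receives zero embedding coordinates.

## Spectral embedding

Rows are renormalised as `r_dw = sqrt(X_dw / Σ_w' X_dw')`, i.e. the
element-wise square root of the L1 term shares.  This makes two desirable
claims literally true: `⟨r_d, r_d'⟩` is the Bhattacharyya coefficient of
the two term-share distributions, and the Gram matrix `C = R Rᵀ` has unit
diagonal.  The plain-L1 alternative (no square root) is retained behind
`sqrt_dialect=False` for comparison; under it the diagonal of `C` is not 1
and the inner product is not a Bhattacharyya coefficient, so the
square-root form is the default.

The symmetric normalisation `C̃ = D^(−1/2) C D^(−1/2)` prevents the
truncated eigendecomposition from representing only the largest clusters.
Useful identities used in tests: `C̃` is PSD with spectrum in `[0, 1]`, and
`D^(1/2)·1` is an exact eigenvector at eigenvalue 1.

Numerics:

* `degree_vector` computes `D` as `R(Rᵀ1)` — `C` is never materialised on
  this path.
* Corpora with ≤ 500 non-degenerate rows (or where `p` is essentially
  full-rank) are solved by a dense `eigh` on the explicit `C̃`; this dense
  path also serves as the internal oracle in tests.
* Larger corpora use ARPACK (implicitly restarted Lanczos) on the composed
  sparse operator, tolerance 1e-10, max 5000 iterations, with a start
  vector drawn from a seeded generator so results are deterministic;
  non-convergence raises an error carrying the iteration budget and
  tolerance.
* Eigenvalues are sorted non-increasing and clipped at 0 before the square
  root when forming `Z = U Λ^(1/2)`.  Eigenvector sign is left arbitrary:
  only distances between rows of `Z` are consumed downstream.
* `p` defaults to 50.  If `p` exceeds the available eigenpairs the
  trailing columns are zero-filled with a warning.

## Label propagation

For every manually labelled citation, the `k = 3` nearest neighbours by
cosine distance are found among *all* citations (the neighbourhood
definition does not exclude labelled ones), but only unlabelled neighbours
receive the label; labelled neighbours are skipped, never re-labelled.  A
target claimed by several sources takes the label of the nearest source;
exact distance ties break on the lower source index, making the result
independent of processing order.  Pseudo-labels are recomputed from
scratch at every active-learning iteration from the current manual set —
nothing persists, and a pseudo-labelled citation later selected for manual
screening simply gets its oracle label (only manual annotations are
charged to the screening budget).  Neighbour search is exact: at the
corpus sizes this problem class presents (≲ 20k citations, 50-dimensional
spectral coordinates) approximate indices are unnecessary.

## Active-learning loop

* **Classifier.** Linear SVM (`LinearSVC`, C = 1, tol 1e-5, fixed
  `random_state`), not tuned per dataset.  Pseudo-labelled instances enter
  with the same weight as manual ones.  Optional inverse-class-frequency
  weighting (`class_weighting="balanced"`) is provided but off by default
  so all six method variants differ only along the sampling-mode and
  propagation-space axes.
* **Classifier space.** Bag-of-words TF-IDF for every variant — the
  variants differ in where *propagation* happens.  Classifying in the
  spectral space is available as an extension (`classifier_space`).
* **Batch sizes.** Seed and batch both default to 1% of `n` with a floor
  of 10, so the 5/10/25/100% reporting checkpoints align with whole
  iterations.  Both accept absolute counts.
* **Cold start.** While the manual set contains one class the SVM cannot
  train; batches are then drawn uniformly at random (still charged to the
  budget) and the remainder is scored as all-negative for the metrics.
  Model-based ranking begins as soon as both classes have been observed.
  This preserves random-seeding semantics without peeking at the oracle.
* **Metrics per iteration.** Computed from hard predictions (sign of the
  decision score) on the unscreened remainder against the gold labels, as
  if screening stopped there; no decision-threshold tuning.  The run
  always continues to exhaustion — stopping criteria are left to
  downstream analysis — so the final record has yield = burden = 1 and
  utility = β/(β+1) = 0.95 exactly.
* **Determinism.** One `numpy.random.default_rng(rng_seed)` drives the
  seed draw and any cold-start batches; liblinear with a fixed
  `random_state` is deterministic; ties in ranking break on corpus index.
  Identical config + seed therefore reproduces trajectories byte-for-byte.

## Evaluation conventions

* Checkpoint "x% manually screened" maps to the first iteration whose
  screened fraction reaches x (iterations are batch-quantised).
* Both the smoothed `average utility@R` (mean over iterations 1..R, the
  headline metric) and the point utility at the checkpoint are reported,
  since either reading is defensible; columns are labelled accordingly.
* SDs across repeated runs are sample SDs (ddof = 1).
* The sign test counts a dataset as a win when the semi-supervised mean
  average-utility strictly exceeds the baseline's; ties are dropped
  (classical convention).  The p-value is the exact binomial tail
  `P(X ≥ wins)` at p₀ = 0.5.
* The manual baseline screens in a seeded random order with no classifier
  assistance (remainder treated as all-negative), giving the familiar
  near-linear utility ramp.

## Synthetic corpus generator

One topic per citation (mixture of multinomials), not a full admixture —
the simplest model that exhibits the observed cluster geometry: eligible
citations concentrated in `ceil(n_topics/5)` reserved topics, plus a
`scatter_frac` share of eligibles drawn from arbitrary topics to emulate
the isolated relevant records that make multi-disciplinary reviews hard.

Defaults: `n = 2000`, vocabulary `m = 500`, eligible ratio 0.05 (mid-range
of the 0.02–0.14 seen in real screening corpora), 10 topics, Poisson mean
document length 120 tokens (a title plus a short abstract),
Dirichlet concentration 0.05 (sharp topics), `scatter_frac = 0.1`.
Generation uses a single PCG64 generator recorded in the metadata, so
corpora are reproducible across platforms.

What the generator does **not** emulate: natural language (tokens are
synthetic word ids), within-class topic drift, label noise, duplicate
records, or metadata features (MeSH terms, publication types).  Tests that
pass on these corpora therefore demonstrate the machinery and the cluster
assumption's consequences, not performance on any particular real review.
In particular, with sharp topics and no scatter, pseudo-label precision is
near 1.0 — real corpora will be noisier.

## Experiment sizes

The built-in experiments use corpus sizes chosen to exercise every code
path at interactive cost: n = 300 for brute-force/dense oracle
equivalence, n = 2000 × 10 seeds for the cluster-assumption and spectrum
checks, and n = 600 × 10 matched-seed pairs for the early-screening
comparison of SemiSpectral-AL-C vs AL-C.  That comparison is genuinely
stochastic: the semi-supervised variant wins or ties most paired runs at
the 10% checkpoint, but individual seeds can favour the plain learner
(pseudo-positives can inflate the predicted-positive set and hence burden
before yield catches up).

## Known limitations

* No out-of-sample (Nyström) extension: citations added after embedding
  require re-embedding.
* Single-label binary screening only; no multi-criterion decisions.
* The uncertainty-mode |decision score| ranking presumes a roughly
  calibrated margin; no probability calibration is attempted.
* `aggregate_runs` requires runs over the same corpus; cross-corpus
  comparisons go through the sign test on per-dataset summaries.
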