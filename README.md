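# citescreen

Semi-supervised active learning for the citation-screening phase of
systematic reviews.

Systematic reviewers must decide, for every citation retrieved by a
literature search, whether it is eligible for the review — often tens of
thousands of title/abstract records of which only 2–14% are eligible.  At
~30 s per abstract this is weeks of expert time (15,544 abstracts ≈ 130 h).
Active-learning screeners cut that workload by training a classifier on the
records screened so far and prioritising what the reviewer sees next, but
they are weakest exactly when they are needed most: in the early iterations,
when almost nothing is labelled.

`citescreen` implements a semi-supervised remedy: exploit the *unlabelled*
pool by copying each manual label to its nearest unlabelled neighbours
(k-NN label propagation), and do the neighbour search in a spectral
embedding that represents topical similarity better than raw bag-of-words.
The pseudo-labelled citations augment the training set of an SVM-based
active learner.

## Method

**Features.** Citations (title + abstract, one bag of words) become a
sparse TF-IDF matrix `X` with `X[d,w] = c_dw · log(1/f_w)`, where `c_dw` is
the term count and `f_w` the fraction of citations containing `w`.

**Spectral embedding.** Rows are renormalised to
`r_dw = sqrt(X[d,w] / Σ_w' X[d,w'])`, so the inner product
`C[d,d'] = ⟨r_d, r_d'⟩ ∈ [0,1]` is the Bhattacharyya coefficient between the
two term-share distributions and `C` is a unit-diagonal PSD Gram matrix.
With `D = diag(Σ_d' C[d,d'])`, the symmetrically normalised operator
`C̃ = D^(−1/2) C D^(−1/2)` has spectrum in `[0,1]` with top eigenvalue
exactly 1.  The embedding keeps the top `p = 50` eigenpairs,
`Z = [u₁√λ₁, …, u_p√λ_p]`, computed with sparse matrix–vector products only
(`C̃x = D^(−1/2)(R(Rᵀ(D^(−1/2)x)))`), so `C̃` is never materialised for large
corpora.

**Label propagation.** Each manually labelled citation copies its label to
its `k = 3` nearest unlabelled neighbours by cosine distance
`1 − ⟨v,u⟩/(‖v‖‖u‖)`, in either the bag-of-words or the spectral space; a
citation claimed by several sources takes the label of the closest one.

**Active learning.** A linear SVM (C = 1) trains on manual + pseudo labels
and ranks the unscreened pool by **certainty** (highest decision score — 
surface likely-eligible records early) or **uncertainty** (smallest
|score| — refine the boundary fastest).  The six variants
(AL-C/U, SemiBoW-AL-C/U, SemiSpectral-AL-C/U) differ only along those two
axes.

**Evaluation.** With superscripts h (human-screened, assumed correct) and a
(classifier predictions on the remainder):

    yield   = (tp_h + tp_a) / (tp_h + tp_a + fn_a)
    burden  = (n_h + tp_a + fp_a) / n
    utility = (β·yield + (1 − burden)) / (β + 1),   β = 19

plus the smoothed `average utility@R` (mean over the first R iterations),
multi-run mean ± SD at the 5/10/25/100% screened checkpoints, and a
one-tailed sign test across datasets (6 wins of 6 → p = 0.015625).

A seeded synthetic-corpus generator (mixture-of-topics multinomial model
with clustered eligible topics, heavy imbalance and optional scattered
eligibles) provides the study conditions for all tests — no external review
data is needed.

## Worked example

`examples/04_screening_simulation.py` generates a clustered corpus
(n = 1000, 5% eligible), embeds it, and compares plain certainty-based
screening with its spectral semi-supervised variant under matched seeds:

```
average utility        @  5%  @ 10%  @ 25%  @100%
AL-C (plain)           0.476  0.694  0.872  0.944
SemiSpectral-AL-C      0.476  0.736  0.889  0.949
Manual                 0.049  0.073  0.176  0.523
```

Reading: after manually screening 10% of the corpus, the semi-supervised
run has accumulated an average utility of 0.736 vs 0.694 without
propagation — it surfaced eligible citations earlier — while unassisted
manual screening in random order sits at 0.073.  Every method ends at point
utility 0.95 once everything is screened (yield = burden = 1 forces
(19 + 0)/20).  The other examples (`examples/01–03`) demonstrate corpus
generation, the embedding's cluster geometry, and pseudo-label precision.

A thin CLI wraps the same library:

```bash
screen generate --n 2000 --ratio 0.05 --rng 7 --out synth.tsv
screen embed    --input synth.tsv --p 50 --out emb.tsv
screen run      --input synth.tsv --mode certainty --semi spectral --rng 7 --out traj.csv
screen simulate --input synth.tsv --repeats 10 --out summary.csv
```

Every command writes a JSON manifest (config, input digest, seeds,
timings) sufficient to reproduce its output bit-identically.

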