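"""Simulate screening: plain certainty-based AL vs spectral semi-supervision.

Both runs share the same random seed batch, so any difference comes from
the pseudo-labels.  Utility = (19 * yield + (1 - burden)) / 20 summarises
each iteration; the average utility up to a checkpoint rewards methods
that surface eligible citations early.
"""

import numpy as np

from citescreen import (
    ALConfig,
    GeneratorParams,
    average_utility,
    build_vocabulary,
    generate_corpus,
    manual_baseline,
    row_normalize,
    run_active_learning,
    spectral_embed,
    tfidf_matrix,
)

synth = generate_corpus(GeneratorParams(n=1000, ratio=0.05, scatter_frac=0.0, rng_seed=13))
vocab = build_vocabulary(synth.corpus)
X = tfidf_matrix(synth.corpus, vocab)
Z = spectral_embed(row_normalize(X), p=50, seed=13).Z
oracle = lambda i: int(synth.labels[i])

checkpoints = (0.05, 0.10, 0.25, 1.0)
header = "  ".join(f"@{int(c * 100):>3d}%" for c in checkpoints)
print(f"average utility        {header}")

for label, semi in (("AL-C (plain)", "none"), ("SemiSpectral-AL-C", "spectral")):
    traj = run_active_learning(
        X, ALConfig(mode="certainty", semi=semi, rng_seed=13), oracle, spectral=Z
    )
    cells = []
    for cp in checkpoints:
        i = traj.checkpoint_index(cp)
        cells.append(f"{average_utility(traj.utilities(), i + 1):.3f}")
    print(f"{label:<22} " + "  ".join(cells))

base = manual_baseline(synth.labels, order_seed=13, step=10)
cells = []
for cp in checkpoints:
    i = base.checkpoint_index(cp)
    cells.append(f"{average_utility(base.utilities(), i + 1):.3f}")
print(f"{'Manual':<22} " + "  ".join(cells))
# Semi-supervised certainty sampling typically dominates early (few manual
# labels) and all methods converge to utility 0.95 at 100% screened; the
# manual baseline climbs roughly linearly in between.
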