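"""Screening-performance metrics: yield, burden, utility, and aggregation.

The screening state at any point splits the corpus into a human-screened
part (superscript h) and an automatically predicted remainder (superscript
a).  Manual labelling is assumed correct, so tp_h + tn_h = n_h.  The
metrics are

    yield  = (tp_h + tp_a) / (tp_h + tp_a + fn_a)
    burden = (n_h + tp_a + fp_a) / n
    utility = (beta * yield + (1 - burden)) / (beta + 1)

with beta = 19 by default: finding every eligible citation is weighted 19
times more heavily than avoiding reviewer workload.  At full manual
screening yield = burden = 1 and utility = (beta)/(beta + 1) = 0.95.

``average_utility`` smooths the per-iteration utility by averaging the
first R iterations; multi-run summaries report the mean and sample
standard deviation of that quantity at fixed checkpoints of the manually
screened fraction, and a one-tailed sign test compares paired method
results across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "ConfusionCounts",
    "IterationRecord",
    "Trajectory",
    "UndefinedMetricError",
    "yield_metric",
    "burden_metric",
    "utility",
    "average_utility",
    "sign_test",
    "screening_hours",
    "manual_baseline",
    "aggregate_runs",
    "DEFAULT_BETA",
    "DEFAULT_CHECKPOINTS",
]

DEFAULT_BETA = 19.0
DEFAULT_CHECKPOINTS = (0.05, 0.10, 0.25, 1.0)


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero (e.g. a corpus with no eligible citations)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts split by human (h) vs automatic (a) labelling.

    Human counts are true labels of screened citations; automatic counts
    compare classifier predictions on the unscreened remainder with the
    gold labels.
    """

    tp_h: int
    tn_h: int
    tp_a: int = 0
    fp_a: int = 0
    fn_a: int = 0
    tn_a: int = 0

    def __post_init__(self) -> None:
        for name in ("tp_h", "tn_h", "tp_a", "fp_a", "fn_a", "tn_a"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_h(self) -> int:
        return self.tp_h + self.tn_h

    @property
    def n_a(self) -> int:
        return self.tp_a + self.fp_a + self.fn_a + self.tn_a

    @property
    def n(self) -> int:
        return self.n_h + self.n_a


def yield_metric(c: ConfusionCounts) -> float:
    """Fraction of all eligible citations identified (screened or predicted)."""
    denom = c.tp_h + c.tp_a + c.fn_a
    if denom == 0:
        raise UndefinedMetricError("yield undefined: no eligible citations")
    return (c.tp_h + c.tp_a) / denom


def burden_metric(c: ConfusionCounts) -> float:
    """Fraction of the corpus a human must screen (done + predicted positive)."""
    if c.n == 0:
        raise UndefinedMetricError("burden undefined: empty corpus")
    return (c.n_h + c.tp_a + c.fp_a) / c.n


def utility(yield_value: float, burden_value: float, beta: float = DEFAULT_BETA) -> float:
    """Weighted combination of yield and (1 - burden); beta weights yield."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0.0 <= yield_value <= 1.0 and 0.0 <= burden_value <= 1.0):
        raise ValueError("yield and burden must lie in [0, 1]")
    return (beta * yield_value + (1.0 - burden_value)) / (beta + 1.0)


def average_utility(utilities: Sequence[float], R: int) -> float:
    """Mean utility over the first R iterations (smoother than point utility)."""
    if not (1 <= R <= len(utilities)):
        raise IndexError(f"R={R} out of bounds for {len(utilities)} iterations")
    return float(np.mean(np.asarray(utilities[:R], dtype=np.float64)))


def sign_test(wins: int, n: int) -> float:
    """One-tailed sign test: P(X >= wins) for X ~ Binomial(n, 1/2).

    With 6 paired datasets and 6 wins this is 1/64 = 0.015625.
    """
    if not (0 <= wins <= n):
        raise ValueError("wins must lie in [0, n]")
    return float(binom.sf(wins - 1, n, 0.5))


def screening_hours(n_citations: int, seconds_per_abstract: float = 30.0) -> float:
    """Manual workload in hours at a fixed per-abstract screening time."""
    return n_citations * seconds_per_abstract / 3600.0


@dataclass(frozen=True)
class IterationRecord:
    """State of one screening iteration: budget spent, pseudo-label count,
    confusion counts on the remainder, and the three metrics."""

    r: int
    n_h: int
    pseudo_count: int
    counts: ConfusionCounts
    yield_value: float
    burden_value: float
    utility_value: float
    new_ids: tuple[int, ...] = ()


class Trajectory:
    """Per-iteration records of a screening run (manual or active learning)."""

    def __init__(self, records: Iterable[IterationRecord], n: int):
        self.records: list[IterationRecord] = list(records)
        self.n = n
        for a, b in zip(self.records, self.records[1:]):
            if b.n_h <= a.n_h:
                raise ValueError("manually screened count must strictly increase")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def utilities(self) -> list[float]:
        return [rec.utility_value for rec in self.records]

    def checkpoint_index(self, fraction: float) -> int:
        """First iteration index whose screened fraction reaches ``fraction``."""
        for i, rec in enumerate(self.records):
            if rec.n_h / self.n >= fraction - 1e-12:
                return i
        raise ValueError(f"no iteration reaches screened fraction {fraction}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": [rec.r for rec in self.records],
                "n_h": [rec.n_h for rec in self.records],
                "pseudo_count": [rec.pseudo_count for rec in self.records],
                "yield": [rec.yield_value for rec in self.records],
                "burden": [rec.burden_value for rec in self.records],
                "utility": [rec.utility_value for rec in self.records],
            }
        )


def manual_baseline(
    gold_labels: np.ndarray,
    order_seed: int,
    step: int = 1,
    beta: float = DEFAULT_BETA,
) -> Trajectory:
    """Conventional manual screening in a seeded random order.

    No classifier assists: at every point the unscreened remainder is
    treated as all-negative (tp_a = fp_a = 0, fn_a = remaining positives),
    so utility climbs approximately linearly with the screened fraction.
    ``step`` controls recording granularity (one record per ``step``
    screened citations).
    """
    gold = np.asarray(gold_labels, dtype=np.int64)
    if gold.min() < 0:
        raise ValueError("manual baseline needs gold labels for every citation")
    n = gold.size
    total_pos = int(gold.sum())
    if total_pos == 0:
        raise UndefinedMetricError("yield undefined: no eligible citations")
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(n)
    records = []
    cum_pos = np.cumsum(gold[order])
    marks = list(range(step, n, step)) + [n]
    prev = 0
    for r, n_h in enumerate(marks, start=1):
        tp_h = int(cum_pos[n_h - 1])
        counts = ConfusionCounts(
            tp_h=tp_h,
            tn_h=n_h - tp_h,
            fn_a=total_pos - tp_h,
            tn_a=(n - n_h) - (total_pos - tp_h),
        )
        y = yield_metric(counts)
        b = burden_metric(counts)
        records.append(
            IterationRecord(
                r=r,
                n_h=n_h,
                pseudo_count=0,
                counts=counts,
                yield_value=y,
                burden_value=b,
                utility_value=utility(y, b, beta),
                new_ids=tuple(int(i) for i in order[prev:n_h]),
            )
        )
        prev = n_h
    return Trajectory(records, n=n)


def aggregate_runs(
    trajectories: Sequence[Trajectory],
    checkpoints: Sequence[float] = DEFAULT_CHECKPOINTS,
) -> pd.DataFrame:
    """Summarise repeated seeded runs at fixed screened-fraction checkpoints.

    A checkpoint "x% manually screened" maps to the first iteration whose
    screened fraction reaches x (iterations are batch-quantised).  Two
    summaries are reported per checkpoint: the average utility over all
    iterations up to it (the smoothed metric) and the point utility at it.
    Standard deviations are sample SDs (ddof=1) across runs.
    """
    if not trajectories:
        raise ValueError("no trajectories to aggregate")
    n = trajectories[0].n
    if any(t.n != n for t in trajectories):
        raise ValueError("trajectories come from different corpora (n mismatch)")
    rows = []
    for cp in checkpoints:
        if not (0.0 < cp <= 1.0):
            raise ValueError(f"checkpoint {cp} outside (0, 1]")
        avg_utils, point_utils = [], []
        for t in trajectories:
            i = t.checkpoint_index(cp)
            avg_utils.append(average_utility(t.utilities(), i + 1))
            point_utils.append(t.utilities()[i])
        avg = np.asarray(avg_utils)
        pt = np.asarray(point_utils)
        ddof = 1 if len(trajectories) > 1 else 0
        rows.append(
            {
                "checkpoint": cp,
                "n_runs": len(trajectories),
                "avg_utility_mean": avg.mean(),
                "avg_utility_sd": avg.std(ddof=ddof),
                "point_utility_mean": pt.mean(),
                "point_utility_sd": pt.std(ddof=ddof),
            }
        )
    return pd.DataFrame(rows)
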