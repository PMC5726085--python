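import numpy as np
import pytest

import citescreen as cs
from citescreen.evaluation import UndefinedMetricError


class TestYieldBurden:
    def test_yield_by_hand(self):
        c = cs.ConfusionCounts(tp_h=5, tn_h=0, tp_a=8, fn_a=2)
        assert cs.yield_metric(c) == pytest.approx(13 / 15)

    def test_full_manual_screening_gives_unit_yield(self):
        c = cs.ConfusionCounts(tp_h=7, tn_h=93)
        assert cs.yield_metric(c) == 1.0

    def test_nothing_found_gives_zero_yield(self):
        c = cs.ConfusionCounts(tp_h=0, tn_h=5, fn_a=3)
        assert cs.yield_metric(c) == 0.0

    def test_yield_undefined_without_positives(self):
        with pytest.raises(UndefinedMetricError):
            cs.yield_metric(cs.ConfusionCounts(tp_h=0, tn_h=5, tn_a=5))

    def test_burden_by_hand(self):
        c = cs.ConfusionCounts(tp_h=10, tn_h=10, tp_a=8, fp_a=12, fn_a=0, tn_a=60)
        assert cs.burden_metric(c) == pytest.approx(0.40)

    def test_burden_at_full_and_zero_workload(self):
        assert cs.burden_metric(cs.ConfusionCounts(tp_h=3, tn_h=97)) == 1.0
        assert (
            cs.burden_metric(cs.ConfusionCounts(tp_h=0, tn_h=0, fn_a=3, tn_a=97)) == 0.0
        )

    def test_counts_partition_the_corpus(self):
        c = cs.ConfusionCounts(tp_h=2, tn_h=8, tp_a=1, fp_a=2, fn_a=3, tn_a=4)
        assert c.n_h + c.n_a == c.n == 20


class TestUtility:
    @pytest.mark.parametrize(
        "y, b, expected",
        [
            (1.0, 0.0, 1.0),
            (1.0, 1.0, 0.95),
            (13 / 15, 0.40, (19 * 13 / 15 + 0.6) / 20),
        ],
    )
    def test_hand_values_at_default_beta(self, y, b, expected):
        assert cs.utility(y, b) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_yield_and_antitone_in_burden(self):
        grid = np.linspace(0, 1, 9)
        for b in grid:
            vals = [cs.utility(y, b) for y in grid]
            assert np.all(np.diff(vals) > 0)
        for y in grid:
            vals = [cs.utility(y, b) for b in grid]
            assert np.all(np.diff(vals) < 0)

    def test_bounded_on_unit_square(self):
        for y in np.linspace(0, 1, 5):
            for b in np.linspace(0, 1, 5):
                assert 0.0 <= cs.utility(y, b) <= 1.0


class TestAverageUtility:
    def test_mean_and_identity(self):
        assert cs.average_utility([0.5, 0.7], 2) == pytest.approx(0.6)
        assert cs.average_utility([0.31, 0.9], 1) == pytest.approx(0.31)

    def test_invariant_to_later_iterations(self):
        head = [0.2, 0.4, 0.6]
        assert cs.average_utility(head + [0.99], 3) == cs.average_utility(
            head + [0.01], 3
        )

    def test_out_of_bounds_R(self):
        with pytest.raises(IndexError):
            cs.average_utility([0.5], 2)


class TestSignTest:
    @pytest.mark.parametrize(
        "wins, n, expected",
        [
            (6, 6, 1 / 64),
            (5, 6, 7 / 64),
            (0, 4, 1.0),
            (3, 3, 1 / 8),
        ],
    )
    def test_exact_binomial_tail(self, wins, n, expected):
        assert cs.sign_test(wins, n) == pytest.approx(expected, abs=1e-12)

    def test_boundary_identities(self):
        for n in (1, 5, 10):
            assert cs.sign_test(0, n) == 1.0
            assert cs.sign_test(n, n) == pytest.approx(0.5**n, abs=1e-15)


class TestManualBaseline:
    def test_endpoint_identity(self):
        gold = np.array([1, 0, 0, 1, 0, 0, 0, 1])
        traj = cs.manual_baseline(gold, order_seed=0)
        last = traj.records[-1]
        assert last.yield_value == 1.0
        assert last.burden_value == 1.0
        assert last.utility_value == pytest.approx(0.95, abs=1e-12)

    def test_expected_yield_near_half_at_half_screened(self):
        rng = np.random.default_rng(0)
        gold = (rng.random(2000) < 0.1).astype(int)
        ys = []
        for seed in range(20):
            traj = cs.manual_baseline(gold, order_seed=seed, step=100)
            i = traj.checkpoint_index(0.5)
            ys.append(traj.records[i].yield_value)
        assert np.mean(ys) == pytest.approx(0.5, abs=0.05)

    def test_no_positives_rejected(self):
        with pytest.raises(UndefinedMetricError):
            cs.manual_baseline(np.zeros(10, dtype=int), order_seed=0)

    def test_utility_grows_roughly_linearly(self):
        rng = np.random.default_rng(1)
        gold = (rng.random(1000) < 0.1).astype(int)
        traj = cs.manual_baseline(gold, order_seed=3, step=50)
        utils = traj.utilities()
        fracs = [rec.n_h / traj.n for rec in traj]
        slope, intercept = np.polyfit(fracs, utils, 1)
        residuals = np.array(utils) - (slope * np.array(fracs) + intercept)
        assert np.abs(residuals).max() < 0.05


class TestAggregateRuns:
    def _traj(self, utilities, n=100, step=25):
        records = []
        for r, u in enumerate(utilities, start=1):
            n_h = min(step * r, n)
            tp_h = 1 if n_h == n else 0
            records.append(
                cs.IterationRecord(
                    r=r,
                    n_h=n_h,
                    pseudo_count=0,
                    counts=cs.ConfusionCounts(
                        tp_h=tp_h, tn_h=n_h - tp_h, fn_a=1 - tp_h, tn_a=n - n_h - (1 - tp_h)
                    ),
                    yield_value=0.0,
                    burden_value=n_h / n,
                    utility_value=u,
                )
            )
        return cs.Trajectory(records, n=n)

    def test_identical_runs_have_zero_sd(self):
        trajs = [self._traj([0.2, 0.4, 0.6, 0.95]) for _ in range(10)]
        out = cs.aggregate_runs(trajs, checkpoints=(0.25, 1.0))
        assert np.all(out["avg_utility_sd"] < 1e-12)

    def test_mean_and_sample_sd_by_hand(self):
        trajs = [self._traj([0.4]), self._traj([0.6])]
        out = cs.aggregate_runs(trajs, checkpoints=(0.25,))
        assert out.loc[0, "avg_utility_mean"] == pytest.approx(0.5)
        assert out.loc[0, "avg_utility_sd"] == pytest.approx(0.1414, abs=5e-4)

    def test_final_checkpoint_uses_last_iteration(self):
        traj = self._traj([0.1, 0.2, 0.3, 0.9])
        out = cs.aggregate_runs([traj], checkpoints=(1.0,))
        assert out.loc[0, "point_utility_mean"] == pytest.approx(0.9)
        assert out.loc[0, "avg_utility_mean"] == pytest.approx(np.mean([0.1, 0.2, 0.3, 0.9]))

    def test_checkpoint_maps_to_first_reaching_iteration(self):
        traj = self._traj([0.1, 0.2, 0.3, 0.9])
        assert traj.checkpoint_index(0.05) == 0
        assert traj.checkpoint_index(0.25) == 0
        assert traj.checkpoint_index(0.26) == 1
        assert traj.checkpoint_index(1.0) == 3

    def test_mismatched_corpora_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cs.aggregate_runs([self._traj([0.5]), self._traj([0.5], n=200, step=50)])


def test_screening_hours_for_a_large_review():
    assert cs.screening_hours(15544) == pytest.approx(129.53, abs=0.01)
    assert round(cs.screening_hours(15544)) == 130
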