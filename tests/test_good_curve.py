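"""Metrics (MCC, rank correlation) and GOOD-curve construction."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from pepgood import (GeneratorConfig, ModelSpec, ThresholdGrid,
                     build_good_curve, evaluate_partition, generate_dataset,
                     mcc, pairwise_similarity, partition_sweep, spearman_rho)
from pepgood.good_curve import mcc_from_predictions
from pepgood.partitioning import Partition
from pepgood.peptides import PeptideDataset, PeptideRecord


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(tp=5, tn=5, fp=0, fn=0) == 1.0

    def test_one_class_predictions_zero_by_convention(self):
        assert mcc(tp=5, tn=0, fp=0, fn=5) == 0.0

    def test_formula_example(self):
        assert mcc(3, 2, 1, 2) == pytest.approx(4 / np.sqrt(240))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(-1, 1, 1, 1)

    def test_matches_sklearn_on_random_tables(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 8, size=4))
            if tp + tn + fp + fn == 0:
                continue
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            assert mcc(tp, tn, fp, fn) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == 1.0

    def test_monotone_decreasing(self):
        assert spearman_rho([1, 2, 3], [3, 1, 0]) == -1.0

    def test_textbook_example(self):
        # sum of squared rank differences = 2 -> 1 - 12/60
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert spearman_rho([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])

    def test_matches_rank_formula_oracle(self, rng):
        # tie-free case: closed form 1 - 6*sum(d^2)/(n(n^2-1))
        for _ in range(200):
            n = int(rng.integers(3, 12))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            d2 = np.sum((np.argsort(np.argsort(x))
                         - np.argsort(np.argsort(y))) ** 2.0)
            expected = 1 - 6 * d2 / (n * (n ** 2 - 1))
            assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_tie_aware_matches_scipy(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12)


def _separable_dataset(n=60, seed=0):
    """Labels are a threshold on a feature the model can see (first ECFP
    bits of a homopolymer marker)."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        # class 1: lysine-rich; class 0: glycine-rich -> separable in ECFP
        if i % 2:
            seq = "K" * int(rng.integers(5, 9)) + "A"
            label = 1.0
        else:
            seq = "G" * int(rng.integers(5, 9)) + "A"
            label = 0.0
        recs.append(PeptideRecord(id=f"s{i}", label=label, sequence=seq))
    return PeptideDataset("separable", "classification", recs)


class TestEvaluatePartition:
    def test_separable_task_scores_one(self):
        ds = _separable_dataset()
        ids = ds.ids
        p = Partition(0.5, ids[:40], ids[40:], True, 1 / 3)
        for seed in (0, 7):
            pt = evaluate_partition(ds, p, "ecfp", ModelSpec("svm"), seed)
            assert pt.metric_value == 1.0

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(3)
        ds = _separable_dataset(n=200)
        labels = rng.permutation([r.label for r in ds])
        recs = [PeptideRecord(id=r.id, label=float(l), sequence=r.sequence)
                for r, l in zip(ds, labels)]
        shuffled = PeptideDataset("null", "classification", recs)
        ids = shuffled.ids
        p = Partition(0.5, ids[:150], ids[150:], True, 0.25)
        pt = evaluate_partition(shuffled, p, "ecfp", ModelSpec("svm"), 0)
        assert abs(pt.metric_value) < 0.2

    def test_invalid_partition_rejected(self, small_dataset):
        ids = small_dataset.ids
        p = Partition(0.5, ids[:50], ids[50:], False, 1 / 6)
        with pytest.raises(ValueError, match="not valid"):
            evaluate_partition(small_dataset, p)

    def test_regression_uses_rank_correlation(self, regression_dataset):
        ids = regression_dataset.ids
        p = Partition(0.5, ids[:45], ids[45:], True, 0.25)
        pt = evaluate_partition(regression_dataset, p, "ecfp",
                                ModelSpec("svm"), 0)
        assert -1.0 <= pt.metric_value <= 1.0


@pytest.fixture(scope="module")
def curve_setup():
    ds = generate_dataset(GeneratorConfig(n=120, seed=2))
    sim = pairwise_similarity(ds, "ecfp")
    sweep = partition_sweep(sim, ThresholdGrid(0.2, 1.0, 0.1))
    return ds, sweep


class TestBuildGoodCurve:
    def test_point_count_is_seeds_times_valid_thresholds(self, curve_setup):
        ds, sweep = curve_setup
        n_valid = len(sweep.valid_partitions())
        assert n_valid >= 2
        curve = build_good_curve(ds, sweep, seeds=[0, 1, 2])
        assert len(curve.points) == 3 * n_valid

    def test_reproducible_given_seeds(self, curve_setup):
        ds, sweep = curve_setup
        c1 = build_good_curve(ds, sweep, seeds=[0, 1])
        c2 = build_good_curve(ds, sweep, seeds=[0, 1])
        assert [p.metric_value for p in c1.points] == \
            [p.metric_value for p in c2.points]
        assert c1.monotonicity_mean == c2.monotonicity_mean

    def test_dynamic_range_copied_from_sweep(self, curve_setup):
        ds, sweep = curve_setup
        from pepgood.partitioning import dynamic_range
        curve = build_good_curve(ds, sweep, seeds=[0])
        assert curve.dynamic_range == dynamic_range(sweep)[0]

    def test_too_few_valid_partitions_flags_unusable(self):
        ds = _separable_dataset(20)
        sim = pairwise_similarity(ds, "ecfp")
        sweep = partition_sweep(sim, ThresholdGrid(0.001, 0.002, 0.001))
        curve = build_good_curve(ds, sweep, seeds=[0])
        if len(sweep.valid_partitions()) < 2:
            assert not curve.usable
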