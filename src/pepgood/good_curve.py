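"""GOOD curves: model performance as a function of the train/test
similarity threshold.

For each valid partition of a threshold sweep, a downstream model is
trained on the train side and scored on the test side — Matthews
correlation (MCC) for classification, rank correlation of predictions
against labels (SPCC) for regression.  A similarity function whose
thresholds order the difficulty of the split should produce a curve that
rises with the threshold; the curve's *monotonicity* is Spearman's rho
between threshold and performance, computed per seed and summarized as
mean +/- sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from . import partitioning as _part
from .models import ModelSpec, Representation, featurize, make_estimator
from .peptides import CLASSIFICATION, PeptideDataset

DEFAULT_SEEDS = (0, 1, 2, 3, 4)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); if any factor of
    the denominator is zero the coefficient is 0 by convention.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + tn + fp + fn < 1:
        raise ValueError("empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def mcc_from_predictions(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return mcc(tp, tn, fp, fn)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman rank correlation.

    Constant input makes the correlation undefined; 0 is returned with a
    warning in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined, "
                      "returning 0")
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class EvalPoint:
    """Model performance at one (threshold, seed)."""

    threshold: float
    seed: int
    metric_value: float

    def __post_init__(self):
        if not -1 - 1e-9 <= self.metric_value <= 1 + 1e-9:
            raise ValueError("metric outside [-1, 1]")


@dataclass
class GoodCurve:
    """Per-threshold, per-seed performance plus curve-level summaries."""

    function_spec: str
    points: List[EvalPoint] = field(default_factory=list)
    monotonicity_mean: float = float("nan")
    monotonicity_sd: float = float("nan")
    dynamic_range: float = 0.0
    n_valid: int = 0
    usable: bool = True

    def thresholds(self) -> List[float]:
        return sorted({p.threshold for p in self.points})

    def to_records(self) -> List[dict]:
        return [vars(p) | {"function_spec": self.function_spec}
                for p in self.points]


def evaluate_partition(ds: PeptideDataset, p: _part.Partition,
                       representation: Representation = "ecfp",
                       model_spec: Optional[ModelSpec] = None,
                       seed: int = 0,
                       hyperparameters: Optional[dict] = None) -> EvalPoint:
    """Train on the partition's train side, score the test side.

    Classification is scored with MCC, regression with the rank correlation
    of predictions against labels.  Deterministic given the seed.
    """
    if not p.valid:
        raise ValueError(f"partition at threshold {p.threshold} is not valid")
    model_spec = model_spec or ModelSpec()
    train = [ds.get(i) for i in p.train_ids]
    test = [ds.get(i) for i in p.test_ids]
    x_train = featurize(train, representation)
    x_test = featurize(test, representation)
    y_train = np.array([r.label for r in train])
    y_test = np.array([r.label for r in test])
    est = make_estimator(model_spec, ds.task, seed, hyperparameters)
    est.fit(x_train, y_train)
    y_pred = est.predict(x_test)
    value = score_predictions(ds.task, y_test, y_pred)
    return EvalPoint(threshold=p.threshold, seed=seed, metric_value=value)


def score_predictions(task: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if task == CLASSIFICATION:
        return mcc_from_predictions(y_true, y_pred)
    if np.all(y_pred == y_pred[0]) or np.all(y_true == y_true[0]):
        return 0.0  # degenerate predictions carry no ranking signal
    return spearman_rho(y_true, y_pred)


def build_good_curve(ds: PeptideDataset, sweep: _part.PartitionSweep,
                     representation: Representation = "ecfp",
                     model_spec: Optional[ModelSpec] = None,
                     seeds: Sequence[int] = DEFAULT_SEEDS) -> GoodCurve:
    """Evaluate every (valid threshold x seed) cell and summarize the curve.

    Monotonicity is Spearman's rho between threshold and metric computed
    within each seed, reported as mean +/- sd across seeds.  The dynamic
    range is inherited from the sweep.  Fewer than two valid partitions
    make the curve unusable (flagged, not raised).
    """
    model_spec = model_spec or ModelSpec()
    valid = sweep.valid_partitions()
    dr, n_valid = _part.dynamic_range(sweep)
    spec_name = f"{model_spec.name}"
    curve = GoodCurve(function_spec=spec_name, dynamic_range=dr,
                      n_valid=n_valid)
    if len(valid) < 2:
        curve.usable = False
        return curve
    monos = []
    for seed in seeds:
        ts, vals = [], []
        for p in valid:
            pt = evaluate_partition(ds, p, representation, model_spec, seed)
            curve.points.append(pt)
            ts.append(pt.threshold)
            vals.append(pt.metric_value)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            monos.append(spearman_rho(ts, vals) if len(set(vals)) > 1 else 0.0)
    curve.monotonicity_mean = float(np.mean(monos))
    curve.monotonicity_sd = float(np.std(monos, ddof=1)) if len(monos) > 1 else 0.0
    return curve
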