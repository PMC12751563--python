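"""Benchmark protocols: interpolation and extrapolation runners with HPO.

*Interpolation* evaluates every (representation x model x valid threshold
x seed) cell of a partition sweep: the model is trained on the train side
and scored on the held-out test side of each split.  *Extrapolation*
trains on the standard-peptide dataset and scores on the complete
modified-peptide dataset over repeated runs (default 25), each training on
a fresh 80% subsample drawn without replacement, isolating the noise due
to training-set composition.

Hyperparameter optimization is a seeded serial random search over the
model's space, scored by mean cross-validated performance (5 folds,
stratified for classification), with early stopping on a patience counter.
A Bayesian search can be plugged in through the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import good_curve as _gc
from .models import ModelSpec, Representation, featurize, make_estimator
from .partitioning import PartitionSweep
from .peptides import CLASSIFICATION, PeptideDataset
from .ranking import PerformanceTable


@dataclass
class ExperimentConfig:
    """Protocol-level settings (seeds, HPO budget, extrapolation runs)."""

    seeds: Sequence[int] = (0, 1, 2, 3, 4)
    hpo_budget: int = 20
    hpo_folds: int = 5
    hpo_patience: int = 20
    extrapolation_runs: int = 25
    subsample_fraction: float = 0.8
    hpo: bool = True

    def __post_init__(self):
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.hpo_budget < 1 or self.hpo_folds < 2:
            raise ValueError("hpo_budget >= 1 and hpo_folds >= 2 required")
        if self.extrapolation_runs < 1:
            raise ValueError("extrapolation_runs must be >= 1")


def _sample_config(space: Dict[str, tuple], rng: np.random.Generator) -> Dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "log":
            lo, hi = spec[1], spec[2]
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "float":
            out[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "int":
            out[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "cat":
            out[name] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"unknown space entry {spec!r}")
    return out


def _cv_score(x: np.ndarray, y: np.ndarray, spec: ModelSpec, task: str,
              hp: Dict, folds: int, seed: int) -> float:
    if task == CLASSIFICATION:
        splitter = StratifiedKFold(folds, shuffle=True, random_state=seed)
        split = splitter.split(x, y)
    else:
        splitter = KFold(folds, shuffle=True, random_state=seed)
        split = splitter.split(x)
    scores = []
    for tr, va in split:
        est = make_estimator(spec, task, seed, hp)
        est.fit(x[tr], y[tr])
        scores.append(_gc.score_predictions(task, y[va], est.predict(x[va])))
    return float(np.mean(scores))


def hpo(x: np.ndarray, y: np.ndarray, spec: ModelSpec, task: str,
        cfg: ExperimentConfig = ExperimentConfig(), seed: int = 0) -> Dict:
    """Seeded serial random search over ``spec.hpo_space``.

    Maximizes the mean cross-validated metric; stops at the budget or
    after ``hpo_patience`` consecutive non-improving draws.  Falls back to
    the spec's fixed hyperparameters (with a warning) when the data are
    too small to cross-validate.
    """
    if len(y) < 5 * cfg.hpo_folds or (
            task == CLASSIFICATION
            and np.unique(y, return_counts=True)[1].min() < cfg.hpo_folds):
        warnings.warn("too few examples for HPO; using default hyperparameters")
        return dict(spec.hyperparameters)
    rng = np.random.default_rng(seed)
    best_hp = dict(spec.hyperparameters)
    best_score = _cv_score(x, y, spec, task, best_hp, cfg.hpo_folds, seed)
    stale = 0
    for _ in range(cfg.hpo_budget):
        hp = _sample_config(spec.hpo_space, rng)
        score = _cv_score(x, y, spec, task, hp, cfg.hpo_folds, seed)
        if score > best_score:
            best_score, best_hp = score, hp
            stale = 0
        else:
            stale += 1
            if stale > cfg.hpo_patience:
                break
    return best_hp


def _rep_name(rep: Representation, i: int) -> str:
    if isinstance(rep, str):
        return rep
    name = getattr(rep, "__name__", None)
    return name or f"representation-{i}"


def run_interpolation(ds: PeptideDataset, sweep: PartitionSweep,
                      representations: Sequence[Representation],
                      specs: Sequence[ModelSpec],
                      cfg: ExperimentConfig = ExperimentConfig()
                      ) -> PerformanceTable:
    """Full factorial (representation x model x valid threshold x seed).

    Each cell optionally runs HPO on the cell's training split before the
    final fit; results are returned as a long-format paired table.
    """
    valid = sweep.valid_partitions()
    if not valid:
        raise ValueError("no valid partitions in the sweep")
    rows = []
    for ri, rep in enumerate(representations):
        rep_name = _rep_name(rep, ri)
        for spec in specs:
            for p in valid:
                for seed in cfg.seeds:
                    hp = None
                    if cfg.hpo:
                        train = [ds.get(i) for i in p.train_ids]
                        x = featurize(train, rep)
                        y = np.array([r.label for r in train])
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            hp = hpo(x, y, spec, ds.task, cfg, seed)
                    point = _gc.evaluate_partition(ds, p, rep, spec, seed, hp)
                    rows.append({
                        "representation": f"{rep_name}+{spec.name}",
                        "dataset": ds.name, "threshold": p.threshold,
                        "seed": seed, "metric": point.metric_value,
                    })
    return PerformanceTable(pd.DataFrame(rows),
                            unit_columns=("dataset", "threshold", "seed"))


def run_extrapolation(standard_ds: PeptideDataset,
                      modified_ds: PeptideDataset,
                      representations: Sequence[Representation],
                      specs: Sequence[ModelSpec],
                      cfg: ExperimentConfig = ExperimentConfig()
                      ) -> PerformanceTable:
    """Train on the standard dataset, score on the whole modified dataset.

    Per run r in 1..``extrapolation_runs``, a ``subsample_fraction`` of the
    standard dataset is drawn without replacement (seeded by r), the model
    is trained on it and evaluated on the complete modified dataset.
    """
    if standard_ds.task != modified_ds.task:
        raise ValueError("datasets must share the task type")
    n = len(standard_ds)
    n_sub = int(np.floor(cfg.subsample_fraction * n))
    if n_sub < 2:
        raise ValueError("subsample too small")
    test = list(modified_ds.records)
    y_test = np.array([r.label for r in test])
    rows = []
    for ri, rep in enumerate(representations):
        rep_name = _rep_name(rep, ri)
        x_test_cache = featurize(test, rep)
        for spec in specs:
            for run in range(1, cfg.extrapolation_runs + 1):
                rng = np.random.default_rng(run)
                idx = rng.choice(n, size=n_sub, replace=False)
                train = [standard_ds.records[i] for i in sorted(idx)]
                x = featurize(train, rep)
                y = np.array([r.label for r in train])
                hp = None
                if cfg.hpo:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        hp = hpo(x, y, spec, standard_ds.task, cfg, seed=run)
                est = make_estimator(spec, standard_ds.task, run, hp)
                est.fit(x, y)
                metric = _gc.score_predictions(standard_ds.task, y_test,
                                               est.predict(x_test_cache))
                rows.append({
                    "representation": f"{rep_name}+{spec.name}",
                    "dataset": standard_ds.name, "run": run,
                    "metric": metric,
                })
    return PerformanceTable(pd.DataFrame(rows),
                            unit_columns=("dataset", "run"))
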