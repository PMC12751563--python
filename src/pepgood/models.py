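"""Downstream models and feature representations.

Models are pluggable behind a train/predict contract; the built-in
algorithms are a support-vector machine and gradient-boosted trees
(LightGBM), each usable for binary classification or regression.

A *representation* turns records into a feature matrix.  Built-ins compute
fingerprints in-process; embedding representations are supplied as a
precomputed id -> vector mapping (pretrained language-model inference is
outside this package).  A representation may also be a callable
``f(records) -> ndarray`` for custom features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Sequence, Union

import numpy as np
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.svm import SVC, SVR

from . import fingerprints as _fp
from .monomers import seq_to_smiles
from .peptides import CLASSIFICATION, PeptideDataset, PeptideRecord

Representation = Union[str, Mapping[str, np.ndarray],
                       Callable[[Sequence[PeptideRecord]], np.ndarray]]

# Desk-scale hyperparameter search spaces; fully overridable per spec.
# Forms: ("log", lo, hi) | ("float", lo, hi) | ("int", lo, hi) | ("cat", [...])
DEFAULT_HPO_SPACES: Dict[str, Dict[str, tuple]] = {
    "svm": {
        "C": ("log", 1e-2, 1e3),
        "kernel": ("cat", ["rbf", "linear"]),
        "gamma": ("log", 1e-4, 1e1),
    },
    "gradient_boosting": {
        "n_estimators": ("int", 50, 500),
        "max_depth": ("int", 3, 12),
        "learning_rate": ("log", 1e-3, 0.3),
        "num_leaves": ("int", 15, 127),
    },
}


@dataclass
class ModelSpec:
    """Algorithm choice plus fixed hyperparameters and an HPO search space."""

    algorithm: str = "svm"
    hyperparameters: Dict = field(default_factory=dict)
    hpo_space: Optional[Dict[str, tuple]] = None

    def __post_init__(self):
        if self.algorithm not in ("svm", "gradient_boosting"):
            raise ValueError(f"unsupported algorithm {self.algorithm!r}")
        if self.hpo_space is None:
            self.hpo_space = dict(DEFAULT_HPO_SPACES[self.algorithm])

    @property
    def name(self) -> str:
        return self.algorithm


def make_estimator(spec: ModelSpec, task: str, seed: int,
                   hyperparameters: Optional[Dict] = None):
    """Instantiate a seeded scikit-learn-compatible estimator."""
    hp = dict(spec.hyperparameters)
    if hyperparameters:
        hp.update(hyperparameters)
    if spec.algorithm == "svm":
        if task == CLASSIFICATION:
            return SVC(random_state=seed, **hp)
        return SVR(**hp)
    hp.setdefault("n_jobs", 1)
    hp.setdefault("verbose", -1)
    if task == CLASSIFICATION:
        return LGBMClassifier(random_state=seed, **hp)
    return LGBMRegressor(random_state=seed, **hp)


def _fp_matrix(records: Sequence[PeptideRecord], diameter: int, nbits: int,
               counted: bool) -> np.ndarray:
    x = np.zeros((len(records), nbits), dtype=np.float64)
    for row, rec in enumerate(records):
        smi = rec.smiles if rec.smiles is not None else seq_to_smiles(rec.sequence)
        fp = _fp.ecfp(smi, diameter=diameter, nbits=nbits, counted=counted)
        if counted:
            for bit, count in fp.counts:
                x[row, bit] = count
        else:
            for bit in fp.bits:
                x[row, bit] = 1.0
    return x


def _parse_fp_spec(spec: str) -> tuple:
    # "ecfp", "ecfp-16", "ecfp-count", "ecfp-count-8"
    parts = spec.split("-")
    counted = "count" in parts
    nums = [p for p in parts if p.isdigit()]
    diameter = int(nums[0]) if nums else 16
    return diameter, counted


def featurize(records: Sequence[PeptideRecord],
              representation: Representation = "ecfp",
              nbits: int = 2048) -> np.ndarray:
    """Feature matrix (len(records) x d) for a representation spec.

    String specs name fingerprint representations (``"ecfp"``,
    ``"ecfp-count"``, optionally with a diameter suffix like
    ``"ecfp-4"``).  A mapping supplies precomputed per-id embeddings; a
    callable receives the records and returns the matrix.
    """
    if callable(representation):
        x = np.asarray(representation(records), dtype=float)
    elif isinstance(representation, str):
        if not representation.startswith("ecfp"):
            raise ValueError(f"unknown representation {representation!r}")
        diameter, counted = _parse_fp_spec(representation)
        x = _fp_matrix(records, diameter, nbits, counted)
    else:
        missing = [r.id for r in records if r.id not in representation]
        if missing:
            raise KeyError(f"no feature vector for ids {missing[:5]}")
        x = np.array([np.asarray(representation[r.id], dtype=float)
                      for r in records])
    if x.shape[0] != len(records):
        raise ValueError("representation returned wrong number of rows")
    return x


def features_for_ids(ds: PeptideDataset, ids: Sequence[str],
                     representation: Representation = "ecfp") -> np.ndarray:
    recs = [ds.get(i) for i in ids]
    return featurize(recs, representation)
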