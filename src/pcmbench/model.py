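"""Design-matrix assembly and the random-forest PCM learner.

The design matrix has one row per activity record: the ligand block
(fingerprint + optional physicochemical properties) followed by the protein
block (the encoded binding-site residue string).  Peptide-only datasets use
the protein block alone.  Rows are fed to the learner in a seed-controlled
randomized order so repeats of an experiment are independent even though
the forest itself is order-invariant.

The forest configuration mirrors the benchmark defaults: 1500 trees (1000
for peptide-only sets), half of the columns sampled at each split
(``max(1, floor(0.5 * n_columns))``), per-bootstrap class balancing for
classification, and out-of-bag predictions retained as a training-time
cross-validation estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .datasets import PCMDataset
from .encoding import DescriptorSetSpec, encode_sequence
from .ligands import LigandFeatureSpec, ligand_feature_names, ligand_feature_vector

__all__ = [
    "ModelConfig",
    "assemble_design_matrix",
    "PCMForest",
    "train_model",
    "predict",
]


@dataclass(frozen=True)
class ModelConfig:
    """Random-forest hyperparameters for PCM benchmarking.

    ``n_trees`` defaults to 1500 and should be dropped to 1000 for
    peptide-only sets (:meth:`for_dataset` does this automatically).
    """

    n_trees: int = 1500
    mtry_fraction: float = 0.5
    class_balance: bool = True
    seed: int = 0
    task: str = "regression"

    def __post_init__(self):
        if not (0 < self.mtry_fraction <= 1):
            raise ValueError("mtry_fraction must be in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")

    @classmethod
    def for_dataset(cls, dataset: PCMDataset, seed: int = 0, **overrides) -> "ModelConfig":
        defaults = dict(n_trees=1000 if dataset.peptide_only else 1500,
                        task=dataset.task, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


def _structure_features(structure: str, ligand_spec: LigandFeatureSpec):
    """Ligand features for a SMILES or a `bits:` surrogate fingerprint."""
    if structure.startswith("bits:"):
        bits = structure[len("bits:"):]
        vec = np.array([float(c) for c in bits])
        names = tuple(f"fp{b}" for b in range(len(vec)))
        return vec, names
    return (ligand_feature_vector(structure, ligand_spec),
            ligand_feature_names(ligand_spec))


def assemble_design_matrix(dataset: PCMDataset,
                           ligand_spec: LigandFeatureSpec | None,
                           protein_spec: DescriptorSetSpec,
                           seed: int = 0):
    """Build (X, y, record keys, feature names) for one dataset.

    Rows follow the dataset's record order permuted by ``seed``.  ``y`` is a
    float vector for regression and an object array of class labels for
    classification.  Encoding failures name the offending record.
    """
    if not dataset.activities:
        raise ValueError("dataset has no activity records")
    ligand_spec = ligand_spec or LigandFeatureSpec()
    target_rows, feature_names = {}, None
    for t in dataset.targets:
        try:
            enc = encode_sequence(protein_spec, t.residue_string, target_id=t.target_id)
        except ValueError as exc:
            raise ValueError(f"target {t.target_id}: {exc}") from exc
        target_rows[t.target_id] = enc.feature_vector
        protein_names = tuple(f"target_{n}" for n in enc.feature_names)
    ligand_rows = {}
    if not dataset.peptide_only:
        for cid, structure in dataset.compounds:
            try:
                vec, names = _structure_features(structure, ligand_spec)
            except ValueError as exc:
                raise ValueError(f"compound {cid}: {exc}") from exc
            ligand_rows[cid] = vec
            ligand_names = tuple(f"ligand_{n}" for n in names)
    rows, y, keys = [], [], []
    for idx, rec in enumerate(dataset.activities):
        blocks = []
        if not dataset.peptide_only:
            blocks.append(ligand_rows[rec.compound_id])
        blocks.append(target_rows[rec.target_id])
        rows.append(np.concatenate(blocks))
        y.append(rec.value if dataset.task == "regression" else rec.class_label)
        keys.append(idx)
    X = np.vstack(rows)
    y = np.array(y) if dataset.task == "regression" else np.array(y, dtype=object)
    feature_names = (() if dataset.peptide_only else ligand_names) + protein_names
    order = np.random.default_rng(seed).permutation(len(keys))
    return X[order], y[order], [keys[i] for i in order], feature_names


class PCMForest(BaseEstimator):
    """Random forest for PCM bioactivity models, scikit-learn style.

    Parameters mirror :class:`ModelConfig`; ``fit`` accepts a plain feature
    matrix and response vector (labels for classification).  Fitted
    attributes: ``forest_``, ``oob_prediction_`` (regression) or
    ``oob_vote_fractions_``/``oob_class_prediction_`` (classification),
    ``mtry_`` (per-split candidate count) and ``feature_names_``.
    """

    def __init__(self, task="regression", n_trees=1500, mtry_fraction=0.5,
                 class_balance=True, seed=0):
        self.task = task
        self.n_trees = n_trees
        self.mtry_fraction = mtry_fraction
        self.class_balance = class_balance
        self.seed = seed

    @classmethod
    def from_config(cls, config: ModelConfig) -> "PCMForest":
        return cls(task=config.task, n_trees=config.n_trees,
                   mtry_fraction=config.mtry_fraction,
                   class_balance=config.class_balance, seed=config.seed)

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in length")
        config = ModelConfig(n_trees=self.n_trees, mtry_fraction=self.mtry_fraction,
                             class_balance=self.class_balance, seed=self.seed,
                             task=self.task)
        self.mtry_ = max(1, int(np.floor(config.mtry_fraction * X.shape[1])))
        # randomized row feeding, seed-controlled; kept although the forest
        # itself is order-invariant so that repeats stay independent
        order = np.random.default_rng(config.seed).permutation(X.shape[0])
        inverse = np.argsort(order)
        Xs, ys = X[order], y[order]
        common = dict(n_estimators=config.n_trees, max_features=config.mtry_fraction,
                      bootstrap=True, oob_score=True, random_state=config.seed,
                      n_jobs=1)
        if config.task == "regression":
            forest = RandomForestRegressor(**common)
            forest.fit(Xs, ys.astype(float))
            self.oob_prediction_ = forest.oob_prediction_[inverse]
        else:
            if len(set(ys)) < 2:
                raise ValueError("classification training data has a single class")
            forest = RandomForestClassifier(
                class_weight="balanced_subsample" if config.class_balance else None,
                **common)
            forest.fit(Xs, ys)
            votes = forest.oob_decision_function_[inverse]
            self.oob_vote_fractions_ = votes
            self.classes_ = forest.classes_
            with np.errstate(invalid="ignore"):
                self.oob_class_prediction_ = np.where(
                    np.isnan(votes).any(axis=1), None,
                    forest.classes_[np.nan_to_num(votes).argmax(axis=1)])
        self.forest_ = forest
        self.config_ = config
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = tuple(feature_names) if feature_names else None
        return self

    def _check_matrix(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape}")
        return X

    def predict(self, X):
        return self.forest_.predict(self._check_matrix(X))

    def predict_vote_fractions(self, X):
        if self.task != "classification":
            raise ValueError("vote fractions are defined for classification only")
        return self.forest_.predict_proba(self._check_matrix(X))


def train_model(X, y, config: ModelConfig, feature_names=None) -> PCMForest:
    """Functional wrapper: fit a :class:`PCMForest` from a config."""
    return PCMForest.from_config(config).fit(X, y, feature_names=feature_names)


def predict(model: PCMForest, X):
    """Predictions; for classification, (labels, vote fractions)."""
    if model.task == "classification":
        return model.predict(X), model.predict_vote_fractions(X)
    return model.predict(X)
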