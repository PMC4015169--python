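"""Validation protocols and the metric suite.

Three split protocols are provided:

* repeated 70–30 validation — ten (by default) random 70% train / 30% test
  splits of the activity records;
* leave-one-sequence-out (LOSO) — one fold per target, holding out that
  target together with *all* of its activity records, which probes
  extrapolation in target space;
* leave-a-fraction-of-targets-out — targets shuffled and partitioned into
  ``ceil(1/fraction)`` disjoint groups (the tractable LOSO variant for very
  large mutant panels).

Regression models are scored with RMSE and the through-origin correlation
coefficient R0² (which, unlike the Pearson correlation, punishes a constant
offset in otherwise well-ranked predictions); training-time performance is
the out-of-bag Q².  Classification models are scored with the Matthews
correlation coefficient and sensitivity.  Y-scrambling permutes the
response over records as a chance-correlation control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import PCMDataset
from .model import ModelConfig, PCMForest, assemble_design_matrix

__all__ = [
    "SplitPlan",
    "make_70_30_plan",
    "make_loso_plan",
    "make_leave_fraction_targets_plan",
    "rmse",
    "r0_squared",
    "q_squared_oob",
    "confusion_and_mcc",
    "y_scramble",
    "run_protocol",
    "MetricReport",
]


# ---------------------------------------------------------------------------
# split plans


@dataclass(frozen=True)
class SplitPlan:
    """Folds of record indices (into ``dataset.activities``)."""

    protocol: str
    folds: tuple  # ((train indices, test indices), ...)
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self):
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("train and test folds overlap")
            if not test:
                raise ValueError("empty test fold")


def make_70_30_plan(dataset: PCMDataset, seed: int = 0,
                    n_repeats: int = 10, test_fraction: float = 0.3) -> SplitPlan:
    """Repeated random record-level splits; test size rounds half-up."""
    n = len(dataset.activities)
    if n < 10:
        raise ValueError("need at least 10 records for a 70-30 plan")
    n_test = int(math.floor(test_fraction * n + 0.5))
    if n_test < 1 or n_test >= n:
        raise ValueError("test fold would be empty or cover the whole data")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        folds.append((tuple(int(i) for i in perm[n_test:]),
                      tuple(int(i) for i in perm[:n_test])))
    return SplitPlan(protocol="seventy_thirty", folds=tuple(folds), seed=seed,
                     n_repeats=n_repeats)


def _records_by_target(dataset: PCMDataset) -> dict:
    groups: dict = {t.target_id: [] for t in dataset.targets}
    for idx, rec in enumerate(dataset.activities):
        groups[rec.target_id].append(idx)
    return groups


def make_loso_plan(dataset: PCMDataset) -> SplitPlan:
    """One fold per target; the test fold is all records of that target."""
    if dataset.n_targets < 2:
        raise ValueError("LOSO needs at least 2 targets")
    groups = _records_by_target(dataset)
    empty = [tid for tid, idxs in groups.items() if not idxs]
    if empty:
        raise ValueError(f"targets without records: {empty}")
    all_idx = set(range(len(dataset.activities)))
    folds = []
    for t in dataset.targets:
        test = groups[t.target_id]
        folds.append((tuple(sorted(all_idx - set(test))), tuple(test)))
    return SplitPlan(protocol="loso", folds=tuple(folds),
                     n_repeats=len(folds))


def make_leave_fraction_targets_plan(dataset: PCMDataset, fraction: float = 0.1,
                                     seed: int = 0) -> SplitPlan:
    """Partition the shuffled targets into ``ceil(1/fraction)`` held-out groups."""
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    n_groups = math.ceil(1.0 / fraction)
    if dataset.n_targets < n_groups:
        raise ValueError(
            f"need at least {n_groups} targets for fraction {fraction}")
    rng = np.random.default_rng(seed)
    tids = [t.target_id for t in dataset.targets]
    order = rng.permutation(len(tids))
    groups = np.array_split(order, n_groups)
    by_target = _records_by_target(dataset)
    all_idx = set(range(len(dataset.activities)))
    folds = []
    for grp in groups:
        test = [i for j in grp for i in by_target[tids[j]]]
        folds.append((tuple(sorted(all_idx - set(test))), tuple(sorted(test))))
    return SplitPlan(protocol="leave_fraction_targets", folds=tuple(folds),
                     seed=seed, n_repeats=n_groups)


# ---------------------------------------------------------------------------
# metrics


def _pair(observed, predicted):
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("observed and predicted must be equal-length vectors")
    return y, p


def rmse(observed, predicted) -> float:
    """Root-mean-square error on the log-unit scale."""
    y, p = _pair(observed, predicted)
    return float(np.sqrt(np.mean((y - p) ** 2)))


def r0_squared(observed, predicted, regress_predicted_on_observed=False) -> float:
    """Coefficient of determination of the through-origin regression.

    Default orientation regresses observed on predicted: the slope is
    ``k = sum(y * yhat) / sum(yhat**2)`` and
    ``R0² = 1 - sum((y - k yhat)²) / sum((y - ybar)²)``.  The alternate
    orientation is available behind the flag.
    """
    y, p = _pair(observed, predicted)
    if regress_predicted_on_observed:
        y, p = p, y
    if y.size < 3:
        raise ValueError("need at least 3 points")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0:
        raise ValueError("observed values are constant; R0^2 undefined")
    ssp = float(np.sum(p ** 2))
    if ssp == 0:
        raise ValueError("predictions are identically zero; slope undefined")
    k = float(np.sum(y * p)) / ssp
    return 1.0 - float(np.sum((y - k * p) ** 2)) / denom


def q_squared_oob(observed, oob_predicted) -> float:
    """Out-of-bag Q² = 1 - PRESS / total sum of squares."""
    y, p = _pair(observed, oob_predicted)
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0:
        raise ValueError("observed values are constant; Q^2 undefined")
    return 1.0 - float(np.sum((y - p) ** 2)) / denom


def confusion_and_mcc(observed, predicted, positive: str = "active"):
    """2x2 confusion counts, MCC and sensitivity.

    MCC is defined as 0 when any marginal factor of the denominator is 0
    (the standard convention); sensitivity is TP / (TP + FN).
    """
    obs = [str(v) for v in observed]
    pred = [str(v) for v in predicted]
    if len(obs) != len(pred) or not obs:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    labels = {"active", "inactive"}
    unknown = (set(obs) | set(pred)) - labels
    if unknown:
        raise ValueError(f"unknown class labels {sorted(unknown)}")
    tp = sum(o == positive and p == positive for o, p in zip(obs, pred))
    tn = sum(o != positive and p != positive for o, p in zip(obs, pred))
    fp = sum(o != positive and p == positive for o, p in zip(obs, pred))
    fn = sum(o == positive and p != positive for o, p in zip(obs, pred))
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in denom_factors):
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(denom_factors))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    return {"tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "mcc": float(mcc), "sensitivity": float(sens)}


def y_scramble(dataset: PCMDataset, seed: int = 0) -> PCMDataset:
    """Permute the response over records, leaving (compound, target) pairs."""
    if len(dataset.activities) < 2:
        raise ValueError("need at least 2 records to scramble")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset.activities))
    recs = dataset.activities
    scrambled = [
        replace(recs[i], value=recs[j].value, class_label=recs[j].class_label)
        for i, j in enumerate(perm)
    ]
    return PCMDataset(name=f"{dataset.name}_yscrambled", task=dataset.task,
                      compounds=dataset.compounds, targets=dataset.targets,
                      activities=scrambled, peptide_only=dataset.peptide_only,
                      metadata={**dataset.metadata, "y_scrambled": True})


# ---------------------------------------------------------------------------
# protocol runner


@dataclass
class MetricReport:
    """Per-fold and per-target validation metrics for one benchmark cell."""

    dataset_name: str
    descriptor_label: str
    protocol: str
    task: str
    per_fold: list = field(default_factory=list)  # one dict per fold
    per_target: dict = field(default_factory=dict)  # target -> list of dicts
    failed_folds: int = 0
    seeds: dict = field(default_factory=dict)
    r0_orientation: str = "observed_on_predicted"

    def _fold_values(self, metric: str) -> np.ndarray:
        vals = [f[metric] for f in self.per_fold
                if metric in f and np.isfinite(f[metric])]
        return np.asarray(vals, dtype=float)

    def mean(self, metric: str) -> float:
        vals = self._fold_values(metric)
        return float(vals.mean()) if vals.size else float("nan")

    def sd(self, metric: str) -> float:
        vals = self._fold_values(metric)
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    def summary(self) -> dict:
        metrics = (("rmse", "r0_squared", "q_squared") if self.task == "regression"
                   else ("mcc", "sensitivity"))
        out = {"dataset": self.dataset_name, "descriptor": self.descriptor_label,
               "protocol": self.protocol, "n_folds": len(self.per_fold),
               "failed_folds": self.failed_folds}
        for m in metrics:
            out[f"mean_{m}"] = self.mean(m)
            out[f"sd_{m}"] = self.sd(m)
        return out

    def per_target_mean(self, metric: str) -> dict:
        out = {}
        for tid, rows in self.per_target.items():
            vals = [r[metric] for r in rows
                    if metric in r and np.isfinite(r[metric])]
            if vals:
                out[tid] = float(np.mean(vals))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat table, one row per fold x target (plus fold-level rows)."""
        rows = []
        for i, f in enumerate(self.per_fold):
            rows.append({"fold": i, "target": "<all>", **f})
        for tid, recs in self.per_target.items():
            for r in recs:
                rows.append({"target": tid, **r})
        frame = pd.DataFrame(rows)
        frame.insert(0, "protocol", self.protocol)
        frame.insert(0, "descriptor", self.descriptor_label)
        frame.insert(0, "dataset", self.dataset_name)
        return frame

    def to_json(self) -> dict:
        return {"dataset": self.dataset_name, "descriptor": self.descriptor_label,
                "protocol": self.protocol, "task": self.task,
                "r0_orientation": self.r0_orientation, "seeds": self.seeds,
                "per_fold": self.per_fold,
                "per_target": self.per_target,
                "failed_folds": self.failed_folds,
                "summary": self.summary()}


def _regression_metrics(y_obs, y_pred) -> dict:
    out = {"rmse": rmse(y_obs, y_pred), "n": int(len(y_obs))}
    try:
        out["r0_squared"] = r0_squared(y_obs, y_pred)
    except ValueError:
        out["r0_squared"] = float("nan")
    return out


def _classification_metrics(y_obs, y_pred) -> dict:
    stats = confusion_and_mcc(y_obs, y_pred)
    stats["n"] = int(len(y_obs))
    return stats


def run_protocol(dataset: PCMDataset, protein_spec, ligand_spec,
                 config: ModelConfig, plan: SplitPlan) -> MetricReport:
    """Train one model per fold and collect fold- and target-level metrics.

    Folds whose training data is single-class (classification) are recorded
    as failed and excluded from the aggregates with a warning.
    """
    X, y, keys, feature_names = assemble_design_matrix(
        dataset, ligand_spec, protein_spec, seed=config.seed)
    row_of = {key: i for i, key in enumerate(keys)}
    target_of = {i: rec.target_id for i, rec in enumerate(dataset.activities)}
    report = MetricReport(
        dataset_name=dataset.name,
        descriptor_label=getattr(protein_spec, "set_label", str(protein_spec)),
        protocol=plan.protocol, task=dataset.task,
        seeds={"plan": plan.seed, "model": config.seed})
    for i, (train, test) in enumerate(plan.folds):
        fold_seed = int((config.seed * 1009 + i) % (2 ** 31 - 1))
        tr = [row_of[k] for k in train]
        te = [row_of[k] for k in test]
        model = PCMForest.from_config(config.with_seed(fold_seed))
        try:
            model.fit(X[tr], y[tr], feature_names=feature_names)
        except ValueError as exc:
            warnings.warn(f"fold {i} failed and is excluded: {exc}")
            report.failed_folds += 1
            continue
        y_pred = model.predict(X[te])
        y_obs = y[te]
        if dataset.task == "regression":
            fold_stats = _regression_metrics(y_obs.astype(float), y_pred)
            with np.errstate(invalid="ignore"):
                oob = model.oob_prediction_
            ok = np.isfinite(oob)
            fold_stats["q_squared"] = (
                q_squared_oob(y[tr].astype(float)[ok], oob[ok])
                if ok.any() else float("nan"))
        else:
            fold_stats = _classification_metrics(y_obs, y_pred)
        fold_stats["fold_seed"] = fold_seed
        report.per_fold.append(fold_stats)
        # per-target granularity within the fold
        fold_targets: dict = {}
        for pos, k in enumerate(test):
            fold_targets.setdefault(target_of[k], []).append(pos)
        for tid, positions in fold_targets.items():
            obs_t = y_obs[positions]
            pred_t = y_pred[positions]
            stats = (_regression_metrics(obs_t.astype(float), pred_t)
                     if dataset.task == "regression"
                     else _classification_metrics(obs_t, pred_t))
            stats["fold"] = i
            report.per_target.setdefault(tid, []).append(stats)
    return report
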