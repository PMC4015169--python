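"""Orchestration: run every (descriptor x protocol) cell and aggregate.

The benchmark grid runs one validation protocol per descriptor set,
collects the per-cell :class:`~pcmbench.validation.MetricReport` objects,
reduces them to a descriptor x experiment table of mean metrics (two
validation parameters per experiment), ranks the table column-wise and
derives the pairwise significance matrix.  A run manifest captures the
configuration, seeds and input checksum needed to reproduce a run bit for
bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datasets import PCMDataset
from .encoding import DescriptorSetSpec, standard_descriptor_specs
from .ligands import LigandFeatureSpec
from .model import ModelConfig
from .ranking import RankTable, SignificanceMatrix, build_rank_table, significance_matrix
from .validation import (MetricReport, make_70_30_plan,
                         make_leave_fraction_targets_plan, make_loso_plan,
                         run_protocol, y_scramble)

__all__ = ["BenchmarkResult", "run_benchmark", "dataset_checksum"]

_REGRESSION_METRICS = ("rmse", "r0_squared")
_CLASSIFICATION_METRICS = ("mcc", "sensitivity")


def dataset_checksum(dataset: PCMDataset) -> str:
    parts = [dataset.name, dataset.task, str(dataset.peptide_only)]
    parts += [f"{c}:{s}" for c, s in dataset.compounds]
    parts += [f"{t.target_id}:{t.residue_string}" for t in dataset.targets]
    parts += [f"{r.compound_id}|{r.target_id}|{r.value}|{r.class_label}"
              for r in dataset.activities]
    return hashlib.sha256("\n".join(parts).encode()).hexdigest()


def _make_plan(dataset, protocol: str, seed: int, n_repeats: int,
               leave_fraction: float):
    if protocol == "seventy_thirty":
        return make_70_30_plan(dataset, seed=seed, n_repeats=n_repeats)
    if protocol == "loso":
        return make_loso_plan(dataset)
    if protocol == "leave_fraction_targets":
        return make_leave_fraction_targets_plan(dataset, fraction=leave_fraction,
                                                seed=seed)
    raise ValueError(f"unknown protocol {protocol!r}")


@dataclass
class BenchmarkResult:
    reports: dict  # (descriptor label, protocol) -> MetricReport
    metric_table: pd.DataFrame  # descriptors x experiments (mean metrics)
    rank_table: RankTable
    significance: SignificanceMatrix
    manifest: dict
    failed_cells: list = field(default_factory=list)

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (label, protocol), report in self.reports.items():
            stem = f"report_{label}_{protocol}".replace("+", "_plus_")
            (directory / f"{stem}.json").write_text(
                json.dumps(report.to_json(), indent=2) + "\n")
            report.to_frame().to_csv(directory / f"{stem}.csv", index=False)
        self.metric_table.to_csv(directory / "metric_table.csv")
        self.rank_table.to_frame().to_csv(directory / "rank_table.csv")
        self.significance.to_frame().to_csv(directory / "significance_matrix.csv")
        self.significance.to_frame(bonferroni=True).to_csv(
            directory / "significance_matrix_bonferroni.csv")
        (directory / "run_manifest.json").write_text(
            json.dumps(self.manifest, indent=2) + "\n")
        return directory


def run_benchmark(dataset: PCMDataset, descriptors=None, protocols=("seventy_thirty",),
                  seed: int = 0, n_repeats: int = 10, leave_fraction: float = 0.1,
                  ligand_spec: LigandFeatureSpec | None = None,
                  scramble: bool = False, **config_overrides) -> BenchmarkResult:
    """Run the benchmark grid on one dataset.

    ``descriptors`` maps display labels to :class:`DescriptorSetSpec`s (or
    is a list of bundled set names); defaults to the full 16-configuration
    inventory.  ``scramble`` runs the y-scrambled null instead of the real
    responses.  Cells that fail are excluded (and listed in
    ``failed_cells``) while the run continues.
    """
    if descriptors is None:
        descriptors = standard_descriptor_specs()
    elif not isinstance(descriptors, dict):
        inventory = standard_descriptor_specs()
        labels = list(descriptors)
        unknown = [n for n in labels if n not in inventory]
        if unknown:
            raise ValueError(f"unknown descriptor labels {unknown}; "
                             f"available: {sorted(inventory)}")
        descriptors = {n: inventory[n] for n in labels}
    if scramble:
        dataset = y_scramble(dataset, seed=seed)
    metrics = (_REGRESSION_METRICS if dataset.task == "regression"
               else _CLASSIFICATION_METRICS)
    reports, failed = {}, []
    columns: dict = {}
    for label, spec in descriptors.items():
        config = ModelConfig.for_dataset(dataset, seed=seed, **config_overrides)
        for protocol in protocols:
            try:
                plan = _make_plan(dataset, protocol, seed, n_repeats, leave_fraction)
                report = run_protocol(dataset, spec, ligand_spec, config, plan)
            except Exception as exc:  # cell failure must not kill the run
                warnings.warn(f"cell ({label}, {protocol}) failed: {exc}")
                failed.append({"descriptor": label, "protocol": protocol,
                               "error": str(exc)})
                continue
            reports[(label, protocol)] = report
            for metric in metrics:
                col = f"{dataset.name}_{protocol}_{metric}"
                columns.setdefault(col, {})[label] = report.mean(metric)
    metric_table = pd.DataFrame(columns)
    complete = metric_table.dropna()
    rank_table = build_rank_table(complete) if complete.shape[0] >= 2 else None
    signif = significance_matrix(rank_table) if rank_table is not None else None
    manifest = {
        "toolkit_version": __version__,
        "dataset": dataset.name,
        "dataset_checksum": dataset_checksum(dataset),
        "task": dataset.task,
        "descriptors": list(descriptors),
        "protocols": list(protocols),
        "seed": seed,
        "n_repeats": n_repeats,
        "leave_fraction": leave_fraction,
        "scrambled": scramble,
        "config_overrides": config_overrides,
        "failed_cells": failed,
    }
    return BenchmarkResult(reports=reports, metric_table=metric_table,
                           rank_table=rank_table, significance=signif,
                           manifest=manifest, failed_cells=failed)
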