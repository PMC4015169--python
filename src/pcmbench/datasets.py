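"""PCM dataset containers, binding-site extraction and summary statistics.

A :class:`PCMDataset` holds compounds (SMILES or surrogate bit strings),
targets (equal-length residue strings, typically a binding site carved out
of a multiple sequence alignment) and a sparse activity table, for either a
regression task (pIC50 / pEC50 / pKi / fold change, log units) or an
active/inactive classification task.

Coordinates are 1-based: alignment columns and residue positions follow the
residue-numbering idiom of the field and are converted internally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import DescriptorSetSpec, encode_sequence
from .tables import DescriptorTable

__all__ = [
    "ActivityRecord",
    "TargetEntry",
    "PCMDataset",
    "extract_binding_site",
    "variable_positions",
    "completeness",
    "avg_tanimoto_distance",
    "avg_euclidean_distance",
    "classify_activity",
    "read_dataset",
    "write_dataset",
]

CLASS_LABELS = ("active", "inactive")


@dataclass(frozen=True)
class ActivityRecord:
    """One measured (compound, target) bioactivity.

    Exactly one of ``value`` (log-unit real) and ``class_label`` is set,
    matching the dataset's task type.
    """

    compound_id: str
    target_id: str
    value: float | None = None
    class_label: str | None = None
    assay_tag: str = ""

    def __post_init__(self):
        if (self.value is None) == (self.class_label is None):
            raise ValueError(
                f"record ({self.compound_id}, {self.target_id}): exactly one "
                "of value/class_label must be set")
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.value is not None and not np.isfinite(self.value):
            raise ValueError(
                f"record ({self.compound_id}, {self.target_id}): non-finite value")


@dataclass(frozen=True)
class TargetEntry:
    target_id: str
    residue_string: str
    source_note: str = ""

    def __post_init__(self):
        if not self.residue_string:
            raise ValueError(f"target {self.target_id!r} has an empty residue string")


@dataclass
class PCMDataset:
    """Compounds x targets x activities with a task type.

    ``peptide_only`` marks sets (like dipeptide inhibitor panels) whose
    records carry no small-molecule block; their design matrices use only
    the protein-side encoding.
    """

    name: str
    task: str
    compounds: list = field(default_factory=list)  # (compound_id, structure)
    targets: list = field(default_factory=list)  # TargetEntry
    activities: list = field(default_factory=list)  # ActivityRecord
    peptide_only: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.peptide_only and self.compounds:
            raise ValueError("peptide_only datasets must not carry compounds")
        lengths = {len(t.residue_string) for t in self.targets}
        if len(lengths) > 1:
            raise ValueError(
                f"all targets must share one residue-string length, got {sorted(lengths)}")
        cids = [c[0] for c in self.compounds]
        tids = [t.target_id for t in self.targets]
        if len(set(cids)) != len(cids):
            raise ValueError("duplicate compound ids")
        if len(set(tids)) != len(tids):
            raise ValueError("duplicate target ids")
        cset, tset = set(cids), set(tids)
        seen = set()
        for rec in self.activities:
            if self.task == "regression" and rec.value is None:
                raise ValueError("regression dataset contains a class-labelled record")
            if self.task == "classification" and rec.class_label is None:
                raise ValueError("classification dataset contains a valued record")
            if rec.target_id not in tset:
                raise ValueError(f"record references unknown target {rec.target_id!r}")
            if not self.peptide_only and rec.compound_id not in cset:
                raise ValueError(f"record references unknown compound {rec.compound_id!r}")
            key = (rec.compound_id, rec.target_id)
            if key in seen:
                raise ValueError(f"duplicate (compound, target) pair {key}")
            seen.add(key)

    # -- convenience ------------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def target_map(self) -> dict:
        return {t.target_id: t for t in self.targets}

    def compound_map(self) -> dict:
        return dict(self.compounds)

    def responses(self) -> np.ndarray:
        if self.task == "regression":
            return np.array([r.value for r in self.activities])
        return np.array([r.class_label for r in self.activities], dtype=object)

    def merge_duplicates(self) -> "PCMDataset":
        """Median-merge duplicate (compound, target) records (opt-in)."""
        if self.task != "regression":
            raise ValueError("median-merge applies to regression datasets only")
        groups: dict = {}
        for rec in self.activities:
            groups.setdefault((rec.compound_id, rec.target_id), []).append(rec)
        merged = [
            recs[0] if len(recs) == 1 else replace(
                recs[0], value=float(np.median([r.value for r in recs])))
            for recs in groups.values()
        ]
        return PCMDataset(name=self.name, task=self.task, compounds=self.compounds,
                          targets=self.targets, activities=merged,
                          peptide_only=self.peptide_only, metadata=self.metadata)


# ---------------------------------------------------------------------------
# alignment handling


def _alignment_rows(alignment) -> list:
    """Normalize an alignment to [(id, row string), ...]."""
    rows = []
    for item in alignment:
        if isinstance(item, tuple):
            rows.append((str(item[0]), str(item[1])))
        elif hasattr(item, "seq"):  # Bio.SeqRecord
            rows.append((item.id, str(item.seq)))
        else:
            rows.append((f"seq{len(rows) + 1}", str(item)))
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r[1]) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    return rows


def extract_binding_site(alignment, columns) -> tuple:
    """Carve binding-site residue strings out of an alignment.

    ``columns`` are 1-based alignment columns.  Any requested column that is
    gapped (``'-'``) in *any* sequence is dropped for *all* sequences, so the
    resulting residue strings share one length.  Returns
    ``(entries, dropped_columns)``.
    """
    rows = _alignment_rows(alignment)
    length = len(rows[0][1])
    columns = sorted(set(int(c) for c in columns))
    if not columns:
        raise ValueError("no columns requested")
    if columns[0] < 1 or columns[-1] > length:
        raise ValueError(
            f"columns out of range 1..{length}: {[c for c in columns if c < 1 or c > length]}")
    dropped = [c for c in columns if any(row[c - 1] == "-" for _, row in rows)]
    kept = [c for c in columns if c not in dropped]
    if not kept:
        raise ValueError("every requested column is gapped in some sequence")
    entries = [
        TargetEntry(target_id=rid,
                    residue_string="".join(row[c - 1] for c in kept),
                    source_note=f"alignment columns {kept}")
        for rid, row in rows
    ]
    return entries, dropped


def variable_positions(sequences) -> list:
    """1-based columns at which >= 2 distinct residues occur."""
    seqs = [str(s.seq) if hasattr(s, "seq") else str(s) for s in sequences]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    return [i + 1 for i in range(len(seqs[0]))
            if len({s[i] for s in seqs}) > 1]


# ---------------------------------------------------------------------------
# summary statistics (the dataset-description arithmetic)


def completeness(dataset: PCMDataset) -> dict:
    """Fraction of the compound x target matrix with a measured activity.

    Returned raw and rounded two ways (2 decimals and nearest percent),
    since published dataset tables round inconsistently.
    """
    n_rows = len(dataset.activities)
    n_targets = dataset.n_targets
    n_compounds = dataset.n_compounds if not dataset.peptide_only else 1
    if n_targets == 0 or n_compounds == 0 or n_rows == 0:
        raise ValueError("empty dataset")
    raw = n_rows / (n_compounds * n_targets)
    return {"raw": raw, "rounded_2dp": round(raw, 2),
            "percent": round(100 * raw)}


def avg_tanimoto_distance(targets) -> float:
    """Mean pairwise feature-set Tanimoto distance between residue strings.

    Each sequence is viewed as the set of its (position, residue) elements;
    for equal-length sequences with ``m`` matching positions the Tanimoto
    distance is ``1 - m / (2L - m)``.
    """
    seqs = [t.residue_string if isinstance(t, TargetEntry) else str(t)
            for t in targets]
    if len(seqs) < 2:
        raise ValueError("need at least 2 targets")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("targets must share one residue-string length")
    L = len(seqs[0])
    dists = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            m = sum(a == b for a, b in zip(seqs[i], seqs[j]))
            dists.append(1.0 - m / (2 * L - m))
    return float(np.mean(dists))


def avg_euclidean_distance(targets, table: DescriptorTable) -> float:
    """Mean pairwise Euclidean distance between encoded targets.

    Distances are divided by ``sqrt(encoded length)`` so the statistic is
    comparable across descriptor widths.
    """
    if table.kind != "continuous":
        raise ValueError("need a continuous descriptor table")
    spec = DescriptorSetSpec(base_tables=(table,))
    seqs = [t.residue_string if isinstance(t, TargetEntry) else str(t)
            for t in targets]
    if len(seqs) < 2:
        raise ValueError("need at least 2 targets")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("targets must share one residue-string length")
    mat = np.vstack([encode_sequence(spec, s).feature_vector for s in seqs])
    width = mat.shape[1]
    dists = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            dists.append(np.linalg.norm(mat[i] - mat[j]) / np.sqrt(width))
    return float(np.mean(dists))


def classify_activity(value: float, threshold: float = 7.0) -> str:
    """Activity class from a log-unit affinity: active iff value > threshold."""
    return "active" if value > threshold else "inactive"


# ---------------------------------------------------------------------------
# bundle IO: a directory with a JSON manifest + delimited text files


def write_dataset(dataset: PCMDataset, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "targets.fasta", "w") as fh:
        for t in dataset.targets:
            fh.write(f">{t.target_id} {t.source_note}\n{t.residue_string}\n")
    rows = []
    for rec in dataset.activities:
        rows.append({"compound_id": rec.compound_id, "target_id": rec.target_id,
                     "value": "" if rec.value is None else repr(rec.value),
                     "class": rec.class_label or "",
                     "assay_tag": rec.assay_tag})
    pd.DataFrame(rows).to_csv(directory / "activities.csv", index=False)
    if dataset.compounds:
        with open(directory / "compounds.smi", "w") as fh:
            for cid, structure in dataset.compounds:
                fh.write(f"{structure}\t{cid}\n")
    manifest = {
        "name": dataset.name, "task": dataset.task,
        "peptide_only": dataset.peptide_only,
        "files": {"targets": "targets.fasta", "activities": "activities.csv",
                  **({"compounds": "compounds.smi"} if dataset.compounds else {})},
        "metadata": {k: v for k, v in dataset.metadata.items()
                     if isinstance(v, (str, int, float, bool, list))},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return directory


def read_dataset(directory) -> PCMDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    targets = []
    with open(directory / manifest["files"]["targets"]) as fh:
        tid, note, seq = None, "", []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if tid is not None:
                    targets.append(TargetEntry(tid, "".join(seq), note))
                head = line[1:].split(None, 1)
                tid, note = head[0], head[1] if len(head) > 1 else ""
                seq = []
            else:
                seq.append(line.strip())
        if tid is not None:
            targets.append(TargetEntry(tid, "".join(seq), note))
    frame = pd.read_csv(directory / manifest["files"]["activities"],
                        dtype=str, keep_default_na=False)
    activities = []
    for row in frame.to_dict("records"):
        value = float(row["value"]) if str(row["value"]) != "" else None
        label = str(row["class"]) if str(row["class"]) else None
        activities.append(ActivityRecord(
            compound_id=row["compound_id"], target_id=row["target_id"],
            value=value, class_label=label,
            assay_tag=str(row["assay_tag"]) if str(row["assay_tag"]) else ""))
    compounds = []
    if "compounds" in manifest["files"]:
        with open(directory / manifest["files"]["compounds"]) as fh:
            for line in fh:
                structure, cid = line.rstrip("\n").split("\t")
                compounds.append((cid, structure))
    return PCMDataset(name=manifest["name"], task=manifest["task"],
                      compounds=compounds, targets=targets,
                      activities=activities,
                      peptide_only=manifest["peptide_only"],
                      metadata=manifest.get("metadata", {}))
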