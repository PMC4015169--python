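"""Turning residue strings into fixed-length numeric feature vectors.

A :class:`DescriptorSetSpec` names one or more descriptor tables and an
encoding mode:

* ``plain``                — position-major layout, ``L * k`` features
  (pos1·comp1 ... pos1·compk, pos2·comp1, ...);
* ``concat``               — two or more tables side by side per position,
  ``L * sum(k_i)`` features, set order preserved within each position block;
* ``plus_target_average``  — the plain layout of a single continuous table
  followed by a global block of ``k`` per-component means and ``k`` sample
  standard deviations over all residues (``L * k + 2k`` features).

The sixteen benchmark descriptor configurations (13 individual sets plus the
three combinations — feature codes with Z-scales (3), Z-scales (3) with its
target average, and ProtFP PCA3 with binned Z-scales) are exposed by
:func:`standard_descriptor_specs`.

:class:`SequenceEncoder` wraps the same logic as a scikit-learn transformer
operating on lists of residue strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import DescriptorTable, canonical_name, load_descriptor_table

__all__ = [
    "DescriptorSetSpec",
    "EncodedTarget",
    "encode_residue",
    "encode_sequence",
    "target_average_block",
    "combine_concat",
    "standard_descriptor_specs",
    "SequenceEncoder",
]

_MODES = ("plain", "concat", "plus_target_average")


@dataclass(frozen=True)
class DescriptorSetSpec:
    """Recipe for encoding a residue string.

    ``base_tables`` may hold bundled set names or :class:`DescriptorTable`
    instances.  ``bin_config`` optionally maps a base-table name to a bin
    count, in which case that table is binned before use.
    """

    base_tables: tuple
    mode: str = "plain"
    bin_config: dict = field(default_factory=dict)
    set_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "base_tables", tuple(self.base_tables))
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if self.mode == "concat" and len(self.base_tables) < 2:
            raise ValueError("concat mode requires at least 2 base tables")
        if self.mode == "plus_target_average" and len(self.base_tables) != 1:
            raise ValueError("plus_target_average mode requires exactly 1 base table")
        if self.mode == "plain" and len(self.base_tables) != 1:
            raise ValueError("plain mode requires exactly 1 base table")
        if not self.set_label:
            object.__setattr__(self, "set_label", self.describe())

    def describe(self) -> str:
        names = [t.name if isinstance(t, DescriptorTable) else canonical_name(str(t))
                 for t in self.base_tables]
        if self.mode == "concat":
            return "+".join(names)
        if self.mode == "plus_target_average":
            return f"{names[0]}+avg"
        return names[0]

    def tables(self) -> list:
        out = []
        for t in self.base_tables:
            table = t if isinstance(t, DescriptorTable) else load_descriptor_table(t)
            name = table.name
            if name in self.bin_config:
                from .tables import bin_table

                table = bin_table(table, self.bin_config[name])
            out.append(table)
        return out

    def encoded_width(self, sequence_length: int) -> int:
        """Closed-form feature count for a sequence of the given length."""
        ks = [t.n_components for t in self.tables()]
        width = sequence_length * sum(ks)
        if self.mode == "plus_target_average":
            width += 2 * ks[0]
        return width


@dataclass(frozen=True)
class EncodedTarget:
    target_id: str
    residue_string: str
    feature_vector: np.ndarray
    feature_names: tuple

    def __post_init__(self):
        if len(self.feature_vector) != len(self.feature_names):
            raise ValueError("feature vector and names disagree in length")


def encode_residue(table: DescriptorTable, aa: str, impute: bool = False) -> np.ndarray:
    """Length-``k`` component vector for a single residue.

    Non-natural residues (B, J, O, U, X, Z) and the gap character error
    unless ``impute`` is set (then the per-component mean is substituted).
    """
    if len(aa) != 1:
        raise ValueError(f"expected a single residue, got {aa!r}")
    return table.row(aa, impute=impute)


def target_average_block(table: DescriptorTable, residue_string: str,
                         impute: bool = False) -> np.ndarray:
    """Global block: per-component mean then sample SD over all residues.

    SDs use the n-1 denominator; a length-1 sequence has no sample SD, and
    the SD half of the block is set to 0 with a warning.
    """
    if table.kind != "continuous":
        raise ValueError("target averages require a continuous table")
    rows = np.vstack([encode_residue(table, aa, impute=impute)
                      for aa in residue_string])
    means = rows.mean(axis=0)
    if rows.shape[0] < 2:
        warnings.warn("sequence of length 1: standard deviations set to 0")
        sds = np.zeros_like(means)
    else:
        sds = rows.std(axis=0, ddof=1)
    return np.concatenate([means, sds])


def encode_sequence(spec: DescriptorSetSpec, residue_string: str,
                    target_id: str = "", impute: bool = False) -> EncodedTarget:
    """Encode one residue string under a descriptor-set spec."""
    if not residue_string:
        raise ValueError("cannot encode an empty residue string")
    tables = spec.tables()
    blocks, names = [], []
    for pos, aa in enumerate(residue_string, start=1):
        for table in tables:
            try:
                blocks.append(encode_residue(table, aa, impute=impute))
            except ValueError as exc:
                raise ValueError(
                    f"position {pos} of {target_id or residue_string!r}: {exc}"
                ) from exc
            names.extend(f"p{pos}_{lab}" for lab in table.component_labels)
    if spec.mode == "plus_target_average":
        table = tables[0]
        blocks.append(target_average_block(table, residue_string, impute=impute))
        names.extend(f"mean_{lab}" for lab in table.component_labels)
        names.extend(f"sd_{lab}" for lab in table.component_labels)
    vector = np.concatenate(blocks)
    return EncodedTarget(target_id=target_id, residue_string=residue_string,
                         feature_vector=vector, feature_names=tuple(names))


def combine_concat(spec_a: DescriptorSetSpec, spec_b: DescriptorSetSpec,
                   set_label: str = "") -> DescriptorSetSpec:
    """Pair two plain specs into a per-position concatenation."""
    if spec_a.mode != "plain" or spec_b.mode != "plain":
        raise ValueError("only plain specs can be concatenated (no nesting)")
    return DescriptorSetSpec(
        base_tables=spec_a.base_tables + spec_b.base_tables, mode="concat",
        bin_config={**spec_a.bin_config, **spec_b.bin_config},
        set_label=set_label or f"{spec_a.set_label}+{spec_b.set_label}")


def standard_descriptor_specs(n_bins: int = 4) -> dict:
    """The 16 benchmark descriptor configurations, keyed by display label."""
    individual = [
        "zscales3", "zscales5", "zscalesbinned", "vhse", "mswhim", "fasgai",
        "tscales", "stscales", "blosum", "protfppca3", "protfppca5",
        "protfppca8", "protfpfeature",
    ]
    specs = {}
    for name in individual:
        table = load_descriptor_table(name, n_bins=n_bins)
        specs[name] = DescriptorSetSpec(base_tables=(table,), set_label=name)
    specs["protfpfeature+zscales3"] = combine_concat(
        specs["protfpfeature"], specs["zscales3"])
    specs["zscales3+avg"] = DescriptorSetSpec(
        base_tables=(load_descriptor_table("zscales3"),),
        mode="plus_target_average", set_label="zscales3+avg")
    specs["protfppca3+zscalesbinned"] = combine_concat(
        specs["protfppca3"], specs["zscalesbinned"])
    return specs


class SequenceEncoder(TransformerMixin, BaseEstimator):
    """scikit-learn transformer from residue strings to feature matrices.

    Parameters
    ----------
    spec : DescriptorSetSpec or str, default "zscales3"
        Encoding recipe, or the name of a bundled descriptor set (used in
        plain mode).
    impute : bool, default False
        Substitute per-component means for non-natural residues instead of
        raising.
    """

    def __init__(self, spec="zscales3", impute=False):
        self.spec = spec
        self.impute = impute

    def _resolved_spec(self) -> DescriptorSetSpec:
        if isinstance(self.spec, DescriptorSetSpec):
            return self.spec
        return DescriptorSetSpec(base_tables=(load_descriptor_table(self.spec),))

    def fit(self, X, y=None):
        X = list(X)
        if not X:
            raise ValueError("need at least one sequence")
        lengths = {len(s) for s in X}
        if len(lengths) != 1:
            raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
        self.sequence_length_ = lengths.pop()
        spec = self._resolved_spec()
        first = encode_sequence(spec, X[0], impute=self.impute)
        self.feature_names_ = first.feature_names
        self.n_features_out_ = len(first.feature_names)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            raise ValueError("SequenceEncoder is not fitted")
        spec = self._resolved_spec()
        rows = []
        for seq in X:
            if len(seq) != self.sequence_length_:
                raise ValueError(
                    f"sequence {seq!r} has length {len(seq)}, encoder was "
                    f"fitted for length {self.sequence_length_}")
            rows.append(encode_sequence(spec, seq, impute=self.impute).feature_vector)
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
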