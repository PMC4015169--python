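"""Amino-acid descriptor tables.

A descriptor table maps each of the 20 natural amino acids to a fixed-length
numeric vector (a "scale").  Thirteen bundled sets are exposed by name —
three Z-scale variants, VHSE, MS-WHIM, FASGAI, T-scales, ST-scales, BLOSUM
indices, three ProtFP-PCA variants and the single-feature ProtFP (Feature)
encoding — together with operations that derive new tables from existing
ones (equal-width binning to one-hot indicators, categorical feature codes).

Continuous tables are shipped as delimited resource files under
``pcmbench/data`` and validated against frozen SHA-256 checksums on load.
Files whose name carries a ``_synthetic`` suffix contain deterministic
stand-in values (see :mod:`pcmbench._scalegen`), not the originally
published constants.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

NATURAL_AAS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "NATURAL_AAS",
    "DescriptorTable",
    "load_descriptor_table",
    "bundled_table_names",
    "bin_table",
    "feature_hash_table",
    "shuffle_table_rows",
]


@dataclass(frozen=True)
class DescriptorTable:
    """Per-amino-acid numeric components for one descriptor set.

    Parameters
    ----------
    name : str
        Identifier of the set (e.g. ``"zscales3"``).
    kind : {"continuous", "binary", "categorical"}
        ``categorical`` implies a single integer code per amino acid.
    values : dict[str, numpy.ndarray]
        One length-``k`` vector per one-letter amino-acid code; exactly the
        20 natural amino acids.
    component_labels : tuple[str, ...]
        ``k`` column labels (e.g. ``("Z1", "Z2", "Z3")``).
    provenance : str
        Citation / derivation note, including a version tag.
    """

    name: str
    kind: str
    values: dict
    component_labels: tuple
    provenance: str = ""

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown table kind {self.kind!r}")
        if set(self.values) != set(NATURAL_AAS):
            missing = sorted(set(NATURAL_AAS) - set(self.values))
            extra = sorted(set(self.values) - set(NATURAL_AAS))
            raise ValueError(
                f"table {self.name!r} must cover exactly the 20 natural amino "
                f"acids (missing {missing}, unexpected {extra})")
        k = len(self.component_labels)
        clean = {}
        for aa, row in self.values.items():
            arr = np.asarray(row, dtype=float)
            if arr.ndim != 1 or arr.size != k:
                raise ValueError(
                    f"table {self.name!r}: row for {aa!r} has length "
                    f"{arr.size}, expected {k}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"table {self.name!r}: non-finite value for {aa!r}")
            clean[aa] = arr
        object.__setattr__(self, "values", clean)
        object.__setattr__(self, "component_labels", tuple(self.component_labels))
        if self.kind == "categorical":
            if k != 1:
                raise ValueError("categorical tables must have a single component")
            codes = [float(v[0]) for v in self.values.values()]
            if len(set(codes)) != 20:
                raise ValueError("categorical codes must be 20 distinct values")

    @property
    def n_components(self) -> int:
        return len(self.component_labels)

    def row(self, aa: str, impute: bool = False) -> np.ndarray:
        """Return the component vector for one residue.

        Non-natural residues and the gap character error unless ``impute`` is
        set, in which case the per-component mean over the 20 natural amino
        acids is substituted (continuous tables only).
        """
        try:
            return self.values[aa]
        except KeyError:
            if impute and self.kind == "continuous":
                return self.matrix().mean(axis=0)
            raise ValueError(
                f"residue {aa!r} is not one of the 20 natural amino acids "
                f"supported by table {self.name!r}") from None

    def matrix(self) -> np.ndarray:
        """20 x k matrix in alphabetical one-letter order."""
        return np.vstack([self.values[aa] for aa in NATURAL_AAS])

    def to_csv(self, path) -> None:
        lines = ["aa," + ",".join(self.component_labels)]
        for aa in NATURAL_AAS:
            lines.append(aa + "," + ",".join(repr(float(v)) for v in self.values[aa]))
        Path(path).write_text("\n".join(lines) + "\n")


def _read_table_file(path, name: str, kind: str = "continuous",
                     provenance: str = "") -> DescriptorTable:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split(",")
    if header[0].strip().lower() != "aa":
        raise ValueError(f"{path}: first header column must be 'aa'")
    labels = [h.strip() for h in header[1:]]
    values = {}
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        if len(cells) != len(labels) + 1:
            raise ValueError(f"{path}: ragged row {ln!r}")
        aa = cells[0]
        if aa in values:
            raise ValueError(f"{path}: duplicate amino acid {aa!r}")
        try:
            values[aa] = [float(c) for c in cells[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell in row {ln!r}") from exc
    return DescriptorTable(name=name, kind=kind, values=values,
                           component_labels=tuple(labels), provenance=provenance)


# ---------------------------------------------------------------------------
# bundled registry

_CHECKSUMS = {
    "zscales5.csv": "24beecae54820a36e07ef5f00b3f9afd3a79422768b62c26eb5c0d17ff651aaa",
    "vhse.csv": "4a7f01e63b4da0e1b94bd32e1cb7efc6edd86f09f2a8214e83a3f70df0da5d8c",
    "mswhim.csv": "08c4e3e82592b31a6d7f56f1b72dd85f46618502a7272a094856fc3a0a90ff61",
    "fasgai_synthetic.csv": "8bb2d6f5f7d0f1c9d0d2602bf4afe76a336efc85a23a0c3cd60f161c4e434365",
    "tscales_synthetic.csv": "400bc7e871c3493642ebcd9d07adf3c8bdc7b0698338cf5c895f9cc7e6485241",
    "stscales_synthetic.csv": "d4a4cc48bfc85c741d7c0845fb115b7df5f127835d3ce6751d0e6982652db16a",
    "blosum_synthetic.csv": "d219c30f77c2715ccc62ac78050c4c383e88a4549d33371ddc61f89f95f6fbce",
    "protfp_pca_synthetic.csv": "1ec33412c7dba63e46cf8d427d9dcf3382de6574f82f97aae9d40eb9b0b3d9a8",
}

# name -> (file, number of leading components to keep, provenance)
_FILE_SETS = {
    "zscales3": ("zscales5.csv", 3,
                 "Z-scales, first 3 PCs; Sandberg et al. 1998, transcription v1"),
    "zscales5": ("zscales5.csv", 5,
                 "Z-scales, 5 PCs; Sandberg et al. 1998, transcription v1"),
    "vhse": ("vhse.csv", 8, "VHSE; Mei et al. 2005, transcription v1"),
    "mswhim": ("mswhim.csv", 3, "MS-WHIM; Zaliani & Gancia 1999, transcription v1"),
    "fasgai": ("fasgai_synthetic.csv", 6,
               "FASGAI-like synthetic stand-in (varimax factors of an AA "
               "property matrix), pcmbench v1"),
    "tscales": ("tscales_synthetic.csv", 8,
                "T-scale-like synthetic stand-in (PCA of an AA topological "
                "matrix), pcmbench v1"),
    "stscales": ("stscales_synthetic.csv", 5,
                 "ST-scale-like synthetic stand-in (PCA of an AA topological+"
                 "size matrix), pcmbench v1"),
    "blosum": ("blosum_synthetic.csv", 10,
               "BLOSUM-index-like synthetic stand-in (varimax PCA of BLOSUM62 "
               "rows), pcmbench v1"),
    "protfppca3": ("protfp_pca_synthetic.csv", 3,
                   "ProtFP-PCA-like synthetic stand-in (PCA of an AA property "
                   "matrix), first 3 PCs, pcmbench v1"),
    "protfppca5": ("protfp_pca_synthetic.csv", 5,
                   "ProtFP-PCA-like synthetic stand-in, first 5 PCs, pcmbench v1"),
    "protfppca8": ("protfp_pca_synthetic.csv", 8,
                   "ProtFP-PCA-like synthetic stand-in, 8 PCs, pcmbench v1"),
}

_DERIVED_SETS = ("zscalesbinned", "protfpfeature")

#: canonical identifiers of the 13 bundled descriptor sets
BUNDLED_SETS = tuple(sorted(_FILE_SETS)) + _DERIVED_SETS

_ALIASES = {
    "zscales(3)": "zscales3", "zscales(5)": "zscales5",
    "zscales(binned)": "zscalesbinned", "zscalesbin": "zscalesbinned",
    "protfp(pca3)": "protfppca3", "protfp(pca5)": "protfppca5",
    "protfp(pca8)": "protfppca8", "protfp(feature)": "protfpfeature",
    "tscale": "tscales", "stscale": "stscales",
}


def canonical_name(name: str) -> str:
    key = "".join(ch for ch in name.lower() if ch not in " _-")
    key = _ALIASES.get(key, key)
    key = "".join(ch for ch in key if ch not in "()")
    return _ALIASES.get(key, key)


def bundled_table_names() -> tuple:
    """Canonical names of the 13 bundled descriptor sets."""
    return BUNDLED_SETS


def _data_path(filename: str) -> Path:
    return Path(resources.files("pcmbench").joinpath("data", filename))


def _verify_checksum(path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = _CHECKSUMS[path.name]
    if digest != expected:
        raise ValueError(
            f"bundled resource {path.name} failed its checksum "
            f"({digest} != {expected}); the file has been modified")


def load_descriptor_table(name, n_bins: int = 4) -> DescriptorTable:
    """Load a bundled descriptor set by name, or a conforming CSV by path.

    ``name`` is matched case- and punctuation-insensitively against the 13
    bundled sets ("Z-scales (3)", "zscales3" and "Z_SCALES-3" are all the
    same set).  Anything else is treated as a path to a resource file with
    header ``aa,<component labels...>`` and 20 data rows.

    ``n_bins`` only affects the derived "Z-scales (Binned)" set.
    """
    key = canonical_name(str(name))
    if key == "zscalesbinned":
        return bin_table(load_descriptor_table("zscales3"), n_bins=n_bins)
    if key == "protfpfeature":
        return feature_hash_table()
    if key in _FILE_SETS:
        filename, k, provenance = _FILE_SETS[key]
        path = _data_path(filename)
        _verify_checksum(path)
        table = _read_table_file(path, name=key, provenance=provenance)
        if k < table.n_components:
            table = DescriptorTable(
                name=key, kind="continuous",
                values={aa: v[:k] for aa, v in table.values.items()},
                component_labels=table.component_labels[:k],
                provenance=provenance)
        return table
    path = Path(str(name))
    if path.exists():
        return _read_table_file(path, name=path.stem)
    raise ValueError(
        f"unknown descriptor set {name!r}; bundled sets are {BUNDLED_SETS}")


def bin_table(table: DescriptorTable, n_bins: int) -> DescriptorTable:
    """Replace each continuous component by a one-hot bin indicator.

    For every component, ``n_bins`` equal-width bins span the [min, max]
    range over the 20 amino acids; the top bin is closed on the right so the
    maximum falls in the last bin.  The result is a binary table with
    ``k * n_bins`` components.
    """
    if table.kind != "continuous":
        raise ValueError("only continuous tables can be binned")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mat = table.matrix()
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    if np.any(hi - lo == 0):
        j = int(np.argmax(hi - lo == 0))
        raise ValueError(
            f"component {table.component_labels[j]!r} has zero range over the "
            "20 amino acids; binning is degenerate")
    width = (hi - lo) / n_bins
    labels = tuple(
        f"{lab}_bin{b + 1}"
        for lab in table.component_labels for b in range(n_bins))
    values = {}
    for aa in NATURAL_AAS:
        row = table.values[aa]
        onehot = np.zeros(table.n_components * n_bins)
        for j, v in enumerate(row):
            b = min(int((v - lo[j]) / width[j]), n_bins - 1)
            onehot[j * n_bins + b] = 1.0
        values[aa] = onehot
    return DescriptorTable(
        name=f"{table.name}_binned{n_bins}", kind="binary", values=values,
        component_labels=labels,
        provenance=f"equal-width {n_bins}-bin one-hot of {table.name}")


def feature_hash_table(one_hot: bool = False) -> DescriptorTable:
    """The feature-based encoding: one categorical code per amino acid.

    Codes are assigned by alphabetical one-letter order (A=1 ... Y=20), so
    every pair of distinct residues is equidistant in the induced Hamming
    sense.  With ``one_hot`` the 20-level indicator expansion is returned
    instead (useful for distance computations).
    """
    if one_hot:
        values = {aa: np.eye(20)[i] for i, aa in enumerate(NATURAL_AAS)}
        return DescriptorTable(
            name="protfpfeature_onehot", kind="binary", values=values,
            component_labels=tuple(f"is_{aa}" for aa in NATURAL_AAS),
            provenance="one-hot variant of the feature-based encoding")
    values = {aa: np.array([float(i + 1)]) for i, aa in enumerate(NATURAL_AAS)}
    return DescriptorTable(
        name="protfpfeature", kind="categorical", values=values,
        component_labels=("FEAT",),
        provenance="feature-based encoding, alphabetical codes 1..20")


def shuffle_table_rows(table: DescriptorTable, seed: int) -> DescriptorTable:
    """Return a copy with the 20 rows permuted among the amino acids.

    The permuted table carries no physicochemical meaning; it is the negative
    control used in descriptor-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(20)
    values = {aa: table.values[NATURAL_AAS[perm[i]]].copy()
              for i, aa in enumerate(NATURAL_AAS)}
    if np.all(perm == np.arange(20)):  # pragma: no cover
        warnings.warn("row shuffle produced the identity permutation")
    return DescriptorTable(
        name=f"{table.name}_shuffled{seed}", kind=table.kind, values=values,
        component_labels=table.component_labels,
        provenance=f"row-shuffled control of {table.name} (seed {seed})")
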