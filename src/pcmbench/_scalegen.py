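"""Deterministic generation of the synthetic stand-in descriptor tables.

Five of the bundled amino-acid descriptor sets (FASGAI, T-scales, ST-scales,
BLOSUM indices and the ProtFP PCA components) are published only in their
original papers and no machine-readable source for their numeric values is
bundled here.  For those sets this module generates *synthetic stand-in*
tables that mirror the way each set is derived conceptually:

* ``protfp_pca_synthetic`` — PCA of a 20 x 12 physicochemical property matrix
  (hydropathy, residue mass, volume, pI, formal charge, H-bond donor/acceptor
  counts, aromaticity, heavy-atom/rotatable-bond/ring counts, beta-branching).
* ``fasgai_synthetic``    — the same property matrix factored with a
  varimax-rotated PCA (six factors), mimicking a factor analysis.
* ``tscales_synthetic``   — PCA (8 components) of a topological property
  matrix (elemental side-chain composition, rotatable bonds, rings, ...).
* ``stscales_synthetic``  — PCA (5 components) of the topological matrix
  augmented with size terms.
* ``blosum_synthetic``    — varimax-rotated PCA (10 components) of the 20
  standardized rows of the BLOSUM62 substitution matrix.

The stand-ins preserve the component counts, the continuous-value character
and the qualitative similarity structure of the originals, but their numeric
values are NOT the published ones; every consumer-facing provenance string
says so.  Generation is fully deterministic (numpy SVD with a fixed sign
convention), so the shipped CSV files can be re-derived and checksummed.

Run ``python -m pcmbench._scalegen`` to rewrite the CSVs in place.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# columns: KD hydropathy, residue mass (Da), vdW volume (A^3), isoelectric
# point, net charge at pH 7, H-bond donors, H-bond acceptors, aromatic flag,
# side-chain heavy atoms, side-chain rotatable bonds, rings, beta-branch flag
_PHYSCHEM = {
    "A": [1.8, 71.08, 88.6, 6.00, 0, 0, 0, 0, 1, 0, 0, 0],
    "C": [2.5, 103.14, 108.5, 5.07, 0, 1, 0, 0, 2, 1, 0, 0],
    "D": [-3.5, 115.09, 111.1, 2.77, -1, 1, 4, 0, 4, 2, 0, 0],
    "E": [-3.5, 129.12, 138.4, 3.22, -1, 1, 4, 0, 5, 3, 0, 0],
    "F": [2.8, 147.18, 189.9, 5.48, 0, 0, 0, 1, 7, 2, 1, 0],
    "G": [-0.4, 57.05, 60.1, 5.97, 0, 0, 0, 0, 0, 0, 0, 0],
    "H": [-3.2, 137.14, 153.2, 7.59, 0.1, 1, 1, 1, 6, 2, 1, 0],
    "I": [4.5, 113.16, 166.7, 6.02, 0, 0, 0, 0, 4, 2, 0, 1],
    "K": [-3.9, 128.17, 168.6, 9.74, 1, 3, 0, 0, 5, 4, 0, 0],
    "L": [3.8, 113.16, 166.7, 5.98, 0, 0, 0, 0, 4, 2, 0, 0],
    "M": [1.9, 131.20, 162.9, 5.74, 0, 0, 0, 0, 4, 3, 0, 0],
    "N": [-3.5, 114.10, 114.1, 5.41, 0, 2, 2, 0, 4, 2, 0, 0],
    "P": [-1.6, 97.12, 112.7, 6.30, 0, 0, 0, 0, 3, 0, 1, 0],
    "Q": [-3.5, 128.13, 143.8, 5.65, 0, 2, 2, 0, 5, 3, 0, 0],
    "R": [-4.5, 156.19, 173.4, 10.76, 1, 5, 1, 0, 7, 4, 0, 0],
    "S": [-0.8, 87.08, 89.0, 5.68, 0, 1, 1, 0, 2, 1, 0, 0],
    "T": [-0.7, 101.10, 116.1, 5.60, 0, 1, 1, 0, 3, 1, 0, 1],
    "V": [4.2, 99.13, 140.0, 5.96, 0, 0, 0, 0, 3, 1, 0, 1],
    "W": [-0.9, 186.21, 227.8, 5.89, 0, 1, 0, 1, 10, 2, 2, 0],
    "Y": [-1.3, 163.18, 193.6, 5.66, 0, 2, 1, 1, 8, 2, 1, 0],
}

# columns: side-chain C, N, O, S atom counts, rotatable bonds, rings,
# beta-branch flag, aromatic-atom count, heavy-atom count
_TOPO = {
    "A": [1, 0, 0, 0, 0, 0, 0, 0, 1],
    "C": [1, 0, 0, 1, 1, 0, 0, 0, 2],
    "D": [2, 0, 2, 0, 2, 0, 0, 0, 4],
    "E": [3, 0, 2, 0, 3, 0, 0, 0, 5],
    "F": [7, 0, 0, 0, 2, 1, 0, 6, 7],
    "G": [0, 0, 0, 0, 0, 0, 0, 0, 0],
    "H": [4, 2, 0, 0, 2, 1, 0, 5, 6],
    "I": [4, 0, 0, 0, 2, 0, 1, 0, 4],
    "K": [4, 1, 0, 0, 4, 0, 0, 0, 5],
    "L": [4, 0, 0, 0, 2, 0, 0, 0, 4],
    "M": [3, 0, 0, 1, 3, 0, 0, 0, 4],
    "N": [2, 1, 1, 0, 2, 0, 0, 0, 4],
    "P": [3, 0, 0, 0, 0, 1, 0, 0, 3],
    "Q": [3, 1, 1, 0, 3, 0, 0, 0, 5],
    "R": [4, 3, 0, 0, 4, 0, 0, 0, 7],
    "S": [1, 0, 1, 0, 1, 0, 0, 0, 2],
    "T": [2, 0, 1, 0, 1, 0, 1, 0, 3],
    "V": [3, 0, 0, 0, 1, 0, 1, 0, 3],
    "W": [9, 1, 0, 0, 2, 2, 0, 9, 10],
    "Y": [7, 0, 1, 0, 2, 1, 0, 6, 8],
}


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Make the largest-magnitude loading of each component positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


def _pca_scores(x: np.ndarray, k: int) -> np.ndarray:
    xs = _standardize(x)
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T.copy()
    _, scores = _fix_signs(loadings, scores)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return scores / sd


def _varimax(loadings: np.ndarray, gamma: float = 1.0, n_iter: int = 100,
             tol: float = 1e-8) -> np.ndarray:
    """Classic varimax rotation matrix for a loading matrix (p x k)."""
    p, k = loadings.shape
    rot = np.eye(k)
    var = 0.0
    for _ in range(n_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam ** 3 - (gamma / p) * lam @ np.diag(np.sum(lam ** 2, axis=0)))
        )
        rot = u @ vt
        new_var = float(np.sum(s))
        if new_var - var < tol:
            break
        var = new_var
    return rot


def _varimax_scores(x: np.ndarray, k: int) -> np.ndarray:
    xs = _standardize(x)
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    loadings = (vt[:k].T * s[:k]).copy()
    rot = _varimax(loadings)
    scores = (u[:, :k] @ rot)
    loadings = loadings @ rot
    _, scores = _fix_signs(loadings, scores)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return scores / sd


def _blosum62_rows() -> np.ndarray:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    alpha = mat.alphabet
    idx = [alpha.index(a) for a in AA_ORDER]
    arr = np.asarray(mat)[np.ix_(idx, idx)].astype(float)
    return arr


def generate_tables() -> dict:
    """Return {set key: (component labels, 20 x k score matrix)}."""
    phys = np.array([_PHYSCHEM[a] for a in AA_ORDER], dtype=float)
    topo = np.array([_TOPO[a] for a in AA_ORDER], dtype=float)
    size = phys[:, 1:3]  # mass, volume

    out = {}
    out["protfp_pca_synthetic"] = (
        [f"PC{i}" for i in range(1, 9)], _pca_scores(phys, 8))
    out["fasgai_synthetic"] = (
        [f"F{i}" for i in range(1, 7)], _varimax_scores(phys, 6))
    out["tscales_synthetic"] = (
        [f"T{i}" for i in range(1, 9)], _pca_scores(topo, 8))
    out["stscales_synthetic"] = (
        [f"ST{i}" for i in range(1, 6)],
        _pca_scores(np.hstack([topo, size]), 5))
    out["blosum_synthetic"] = (
        [f"BLOSUM{i}" for i in range(1, 11)],
        _varimax_scores(_blosum62_rows(), 10))
    return out


def write_tables(directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    for key, (labels, scores) in generate_tables().items():
        lines = ["aa," + ",".join(labels)]
        for i, aa in enumerate(AA_ORDER):
            vals = ",".join(f"{v:.3f}" for v in scores[i])
            lines.append(f"{aa},{vals}")
        (directory / f"{key}.csv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    from pathlib import Path

    write_tables(Path(__file__).parent / "data")
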