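"""Descriptor ranking across benchmark experiments and its significance.

Every experiment (one dataset x protocol x validation parameter) ranks the
descriptor sets from best (rank 1) to worst, with ties averaged, so a full
benchmark with four datasets yields 14 ranks per descriptor (two metrics per
experiment; LOSO is skipped for peptide-only sets).  Descriptors are then
aggregated by their median rank and the MAD (median absolute deviation from
the median) of those ranks, and every unordered pair of descriptors is
compared with a two-sided Wilcoxon signed-rank test on the paired rank
vectors.

The Wilcoxon test enumerates the exact null distribution for up to 25
non-zero paired differences (a dynamic program over the signed-rank sum, so
tied ranks are handled exactly) and switches to the normal approximation
with continuity and tie correction above that.  Zero differences are
discarded before ranking (Wilcoxon's original convention); the Pratt
variant, which ranks zeros and then drops them, is available behind a flag.
No multiplicity adjustment is applied to the pairwise matrix, but a
Bonferroni-adjusted copy is included as supplementary output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "rank_experiment",
    "RankTable",
    "build_rank_table",
    "aggregate_ranks",
    "wilcoxon_signed_rank",
    "significance_matrix",
    "SignificanceMatrix",
]

#: metrics where larger values indicate better models
HIGHER_IS_BETTER = {"r0_squared": True, "q_squared": True, "mcc": True,
                    "sensitivity": True, "rmse": False}


def rank_experiment(values, better: str = "higher") -> np.ndarray:
    """Fractional ranks with 1 = best; ties get the average position."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 descriptors to rank")
    if not np.all(np.isfinite(vals)):
        raise ValueError("cannot rank non-finite metric values")
    if better not in ("higher", "lower"):
        raise ValueError("better must be 'higher' or 'lower'")
    return rankdata(-vals if better == "higher" else vals, method="average")


@dataclass
class RankTable:
    """Descriptor x experiment fractional ranks plus their aggregation."""

    descriptors: list
    experiments: list
    ranks: np.ndarray  # shape (n_descriptors, n_experiments)

    def __post_init__(self):
        self.ranks = np.asarray(self.ranks, dtype=float)
        d, e = len(self.descriptors), len(self.experiments)
        if self.ranks.shape != (d, e):
            raise ValueError("rank matrix shape disagrees with the labels")
        expected = d * (d + 1) / 2
        sums = self.ranks.sum(axis=0)
        if not np.allclose(sums, expected):
            raise ValueError(
                f"each experiment's ranks must sum to {expected}; got {sums}")

    def median_rank(self) -> dict:
        return {d: float(np.median(self.ranks[i]))
                for i, d in enumerate(self.descriptors)}

    def mad(self) -> dict:
        out = {}
        for i, d in enumerate(self.descriptors):
            med = np.median(self.ranks[i])
            out[d] = float(np.median(np.abs(self.ranks[i] - med)))
        return out

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.ranks, index=self.descriptors,
                             columns=self.experiments)
        frame["median_rank"] = list(self.median_rank().values())
        frame["mad"] = list(self.mad().values())
        return frame.sort_values("median_rank")


def build_rank_table(metric_table: pd.DataFrame,
                     better: dict | None = None) -> RankTable:
    """Rank a descriptor x experiment metric table column by column.

    ``metric_table`` has one row per descriptor and one column per
    experiment; column names ending in a known metric name (e.g.
    ``"ace_7030_rmse"``) determine the rank direction, otherwise ``better``
    must map the column to ``"higher"``/``"lower"``.
    """
    better = better or {}
    rank_cols = []
    for col in metric_table.columns:
        if col in better:
            direction = better[col]
        else:
            metric = next((m for m in HIGHER_IS_BETTER if str(col).endswith(m)), None)
            if metric is None:
                raise ValueError(f"cannot infer rank direction for column {col!r}")
            direction = "higher" if HIGHER_IS_BETTER[metric] else "lower"
        rank_cols.append(rank_experiment(metric_table[col].to_numpy(), direction))
    return RankTable(descriptors=list(metric_table.index),
                     experiments=list(metric_table.columns),
                     ranks=np.column_stack(rank_cols))


def aggregate_ranks(ranks: np.ndarray):
    """(median rank, MAD) per row of a rank matrix."""
    ranks = np.atleast_2d(np.asarray(ranks, dtype=float))
    if ranks.size == 0:
        raise ValueError("empty rank matrix")
    med = np.median(ranks, axis=1)
    mad = np.median(np.abs(ranks - med[:, None]), axis=1)
    return med, mad


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

_EXACT_LIMIT = 25


def _exact_sf_cdf(doubled_ranks, w2: float):
    """P(W <= w) and P(W >= w) for the signed-rank sum under the null.

    Works on ranks doubled to integers so average ties stay exact; dynamic
    program over the distribution of the sum of a uniformly random subset.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        counts[r:] = counts[r:] + counts[:counts.size - r]
    n_assignments = counts.sum()
    w = int(round(w2))
    cdf = counts[: w + 1].sum() / n_assignments
    sf = counts[w:].sum() / n_assignments
    return cdf, sf


def wilcoxon_signed_rank(x, y=None, zero_method: str = "wilcox") -> dict:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Pass either paired vectors ``x, y`` or a vector of differences.  Returns
    a dict with the statistic (sum of positive signed ranks), the two-sided
    p-value, the number of non-zero pairs used and the method.  All-zero
    differences give p = 1 with a warning.
    """
    d = np.asarray(x, dtype=float) - (np.asarray(y, dtype=float) if y is not None else 0.0)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("need a 1-D vector of paired differences")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            warnings.warn("all paired differences are zero; p = 1")
            return {"statistic": 0.0, "p_value": 1.0, "n": 0, "method": "degenerate"}
        ranks = rankdata(np.abs(d), method="average")
    else:
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return {"statistic": 0.0, "p_value": 1.0, "n": 0, "method": "degenerate"}
        ranks = rankdata(np.abs(d), method="average")
        ranks = ranks[d != 0]
        d = d[d != 0]
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    if n < 5:
        warnings.warn("fewer than 5 non-zero pairs; the p-value is coarse")
    if n <= _EXACT_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        cdf, sf = _exact_sf_cdf(doubled, 2 * w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_term = 0.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        from scipy.stats import norm

        p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "normal_approx"
    return {"statistic": w_plus, "p_value": float(p), "n": int(n), "method": method}


@dataclass
class SignificanceMatrix:
    """Symmetric two-sided p-value matrix over descriptor pairs."""

    descriptors: list
    p_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self, bonferroni: bool = False) -> pd.DataFrame:
        p = self.p_values.copy()
        if bonferroni:
            d = len(self.descriptors)
            m = d * (d - 1) / 2
            off = ~np.eye(d, dtype=bool)
            p[off] = np.minimum(1.0, p[off] * m)
        return pd.DataFrame(p, index=self.descriptors, columns=self.descriptors)


def significance_matrix(rank_table: RankTable,
                        zero_method: str = "wilcox") -> SignificanceMatrix:
    """Pairwise Wilcoxon signed-rank tests on the descriptors' rank vectors.

    No multiplicity adjustment is applied (``to_frame(bonferroni=True)``
    provides the adjusted view as supplementary output).
    """
    d = len(rank_table.descriptors)
    if d < 2:
        raise ValueError("need at least 2 descriptors")
    p = np.full((d, d), np.nan)
    meta = {"zero_method": zero_method, "n_experiments": len(rank_table.experiments),
            "adjustment": "none"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(d):
            for j in range(i + 1, d):
                res = wilcoxon_signed_rank(rank_table.ranks[i],
                                           rank_table.ranks[j],
                                           zero_method=zero_method)
                p[i, j] = p[j, i] = res["p_value"]
    return SignificanceMatrix(descriptors=list(rank_table.descriptors),
                              p_values=p, metadata=meta)
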