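"""Node-level network metrics and leading-eigenvector community detection.

Strength is the weighted degree; eigenvector centrality is the principal
eigenvector of the weight matrix, max-normalized to 1.  Communities come from
Newman's leading-eigenvector method: recursive spectral bisection of the
(generalized) weighted modularity matrix

    B_ij = A_ij - s_i s_j / (2W),   s_i = strength(i),  W = total edge weight,

splitting by the sign of the leading eigenvector and stopping when the
leading eigenvalue is non-positive or the split does not increase modularity

    Q = (1 / 2W) sum_ij [A_ij - s_i s_j / (2W)] delta(c_i, c_j).

No Kernighan–Lin refinement is applied: the plain sign-split recursion is
deterministic and directly checkable against exhaustive modularity
maximization on small graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .events import AssociationMatrix

__all__ = [
    "Partition",
    "strength",
    "strengths",
    "eigenvector_centrality",
    "modularity",
    "leading_eigenvector_communities",
    "membership_agreement",
    "spearman_rank_correlation",
    "round_half_up",
]

#: a leading eigenvalue at or below this is treated as zero (indivisible group)
EIG_TOL = 1e-10


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class Partition:
    """Community labels (contiguous from 0) with the partition's modularity."""

    labels: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for node, c in self.labels.items():
            out[c].add(node)
        return out


def strength(matrix: AssociationMatrix, node: str) -> float:
    """Sum of one node's edge weights (weighted degree)."""
    return float(matrix.weights[matrix.index(node)].sum())


def strengths(matrix: AssociationMatrix) -> np.ndarray:
    return matrix.weights.sum(axis=1)


def eigenvector_centrality(matrix: AssociationMatrix) -> np.ndarray:
    """Principal eigenvector of the weight matrix, scaled so max = 1.

    Computed on the full matrix even when the graph is disconnected: the
    dominant component carries the mass.  An all-zero matrix yields all
    zeros with a warning.
    """
    w = matrix.weights
    if not np.any(w):
        warnings.warn("all-zero network: eigenvector centrality undefined, "
                      "returning zeros")
        return np.zeros(len(matrix.roster))
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, -1]
    # Perron vector of a non-negative matrix: fix global sign, clip noise
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return v / v.max()


def modularity(matrix: AssociationMatrix, labels: dict[str, int]) -> float:
    """Weighted modularity Q of a partition."""
    missing = [n for n in matrix.roster if n not in labels]
    if missing:
        raise ValueError(f"partition does not cover roster: missing {missing}")
    A = matrix.weights
    two_w = A.sum()
    if two_w == 0:
        raise ValueError("modularity undefined for a network with zero total weight")
    s = A.sum(axis=1)
    lab = np.array([labels[n] for n in matrix.roster])
    same = lab[:, None] == lab[None, :]
    B = A - np.outer(s, s) / two_w
    return float(B[same].sum() / two_w)


def _leading_eig(Bg: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(Bg)
    return float(vals[-1]), vecs[:, -1]


def leading_eigenvector_communities(
    matrix: AssociationMatrix, tol: float = EIG_TOL
) -> Partition:
    """Recursive leading-eigenvector community detection.

    Each group is split by the sign of the leading eigenvector of its
    generalized modularity matrix (zero entries go to the positive block);
    the split is kept only when the leading eigenvalue exceeds ``tol`` and
    the modularity gain is positive.  Returns labels renumbered contiguously
    in roster order, plus the partition's Q.
    """
    A = matrix.weights
    n = len(matrix.roster)
    if n == 0:
        raise ValueError("empty network")
    two_w = A.sum()
    if two_w == 0:
        # no edges: nothing to split on
        return Partition({node: 0 for node in matrix.roster}, 0.0)
    s = A.sum(axis=1)
    B = A - np.outer(s, s) / two_w

    groups: list[np.ndarray] = []

    def split(indices: np.ndarray) -> None:
        if len(indices) == 1:
            groups.append(indices)
            return
        Bg = B[np.ix_(indices, indices)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        lead_val, vec = _leading_eig(Bg)
        if lead_val <= tol:
            groups.append(indices)
            return
        sign = np.where(vec >= 0, 1.0, -1.0)
        delta_q = float(sign @ Bg @ sign) / (2.0 * two_w)
        pos = indices[sign > 0]
        neg = indices[sign < 0]
        if delta_q <= 0 or len(pos) == 0 or len(neg) == 0:
            groups.append(indices)
            return
        split(pos)
        split(neg)

    split(np.arange(n))

    label_of = np.empty(n, dtype=int)
    for g, idx in enumerate(groups):
        label_of[idx] = g
    # renumber contiguously in roster order
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, node in enumerate(matrix.roster):
        raw = int(label_of[i])
        if raw not in remap:
            remap[raw] = len(remap)
        labels[node] = remap[raw]
    return Partition(labels, modularity(matrix, labels))


def membership_agreement(
    partition_a: dict[str, int],
    partition_b: dict[str, int],
    roster: list[str] | None = None,
) -> tuple[int, int]:
    """Share of individuals placed in matching communities by two partitions.

    Labels are aligned by maximum-overlap optimal assignment, so the result
    is invariant to label permutation.  Returns (percent same, rounded to the
    nearest integer; number mismatched).
    """
    if roster is None:
        roster = sorted(set(partition_a) & set(partition_b))
    if not roster:
        raise ValueError("partitions share no individuals")
    for name, part in (("first", partition_a), ("second", partition_b)):
        missing = [n for n in roster if n not in part]
        if missing:
            raise ValueError(f"{name} partition missing individuals: {missing}")
    la = sorted({partition_a[n] for n in roster})
    lb = sorted({partition_b[n] for n in roster})
    overlap = np.zeros((len(la), len(lb)), dtype=int)
    ia = {l: i for i, l in enumerate(la)}
    ib = {l: i for i, l in enumerate(lb)}
    for n in roster:
        overlap[ia[partition_a[n]], ib[partition_b[n]]] += 1
    rows, cols = linear_sum_assignment(-overlap)
    n_same = int(overlap[rows, cols].sum())
    n_mismatch = len(roster) - n_same
    return round_half_up(100.0 * n_same / len(roster)), n_mismatch


def spearman_rank_correlation(x, y) -> float:
    """Spearman's r: Pearson correlation of mid-ranks (ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)
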