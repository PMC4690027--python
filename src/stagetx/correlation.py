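"""Pairwise correlation profiling and UPGMA clustering of stages.

Stage similarity is quantified by Pearson's r between log2(count+1)
expression vectors, with 95% confidence intervals from Fisher's
z'-transformation: z' = atanh(r) is approximately normal with standard
error 1/sqrt(n-3), so the interval is tanh(atanh(r) +/- z* / sqrt(n-3)).
Stages are then clustered by UPGMA on the rescaled distance 1 - r; because
r can be negative, distances may exceed 1.

UPGMA merges the closest pair of clusters at each step; the distance from
the merged cluster to any other is the size-weighted arithmetic mean of its
parts' distances, and the merged node sits at half the merge distance
(ultrametric convention).  Ties are broken by lexicographic cluster-label
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .filters import ExpressionProfile


@dataclass(frozen=True)
class CorrelationResult:
    stage_a: str
    stage_b: str
    r: float
    n: int
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.r <= self.ci_high):
            raise ValueError("confidence interval must contain r")


@dataclass
class DendrogramNode:
    height: float
    label: str | None = None
    children: list["DendrogramNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)


@dataclass
class Dendrogram:
    """Ultrametric binary merge tree over stage labels."""

    root: DendrogramNode

    def merge_order(self) -> list[tuple[frozenset, float]]:
        """(leaf set, height) per internal node, sorted by height."""
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append((frozenset(node.leaf_labels), node.height))
                for c in node.children:
                    walk(c)

        walk(self.root)
        return sorted(out, key=lambda t: t[1])


def pearson_r(x, y) -> float:
    """Product-moment correlation; rejects constant vectors (r undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def fisher_ci(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher z' confidence interval for a Pearson correlation.

    Parameters
    ----------
    r : correlation, |r| < 1 (atanh diverges at +/-1).
    n : number of paired observations, >= 4 (the z' standard error is
        1/sqrt(n-3)).
    """
    if not -1 < r < 1:
        raise ValueError("|r| must be < 1 for the z' transform")
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    zstar = stats.norm.ppf(0.5 + confidence / 2.0)
    z = np.arctanh(r)
    half = zstar / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def build_correlation_profile(
    profile: ExpressionProfile, confidence: float = 0.95
) -> list[CorrelationResult]:
    """One CorrelationResult per unordered stage pair, in column order."""
    stages = profile.stage_labels
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    n = len(profile.values)
    out = []
    for a, b in combinations(stages, 2):
        r = pearson_r(profile.values[a], profile.values[b])
        lo, hi = fisher_ci(r, n, confidence)
        out.append(CorrelationResult(a, b, r, n, lo, hi, confidence))
    return out


def distance_matrix(results: list[CorrelationResult]) -> pd.DataFrame:
    """Symmetric 1 - r distance matrix over the stages of ``results``."""
    stages: list[str] = []
    for res in results:
        for s in (res.stage_a, res.stage_b):
            if s not in stages:
                stages.append(s)
    mat = pd.DataFrame(0.0, index=stages, columns=stages)
    for res in results:
        d = 1.0 - res.r
        mat.loc[res.stage_a, res.stage_b] = d
        mat.loc[res.stage_b, res.stage_a] = d
    return mat


def upgma_dendrogram(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA tree from a symmetric zero-diagonal distance matrix."""
    d = distances.to_numpy(dtype=float)
    labels = list(distances.columns)
    if list(distances.index) != labels:
        raise ValueError("distance matrix index and columns must match")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix diagonal must be zero")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")

    clusters: list[DendrogramNode] = [DendrogramNode(0.0, label=l) for l in labels]
    sizes = [1] * len(labels)
    dist: dict[frozenset, float] = {}
    for i, j in combinations(range(len(labels)), 2):
        dist[frozenset((labels[i], labels[j]))] = d[i, j]

    def key(node: DendrogramNode) -> tuple:
        return tuple(sorted(node.leaf_labels))

    def pair_dist(a: DendrogramNode, b: DendrogramNode) -> float:
        return _cluster_dist[(id(a), id(b))]

    # pairwise distances between current clusters, updated by weighted means
    _cluster_dist: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(clusters)), 2):
        v = d[i, j]
        _cluster_dist[(id(clusters[i]), id(clusters[j]))] = v
        _cluster_dist[(id(clusters[j]), id(clusters[i]))] = v

    while len(clusters) > 1:
        # closest pair; ties by lexicographic (sorted-label) cluster order
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            cand = (pair_dist(ca, cb), min(key(ca), key(cb)), max(key(ca), key(cb)))
            if best is None or cand < best[0]:
                best = (cand, a, b)
        _, ia, ib = best
        ca, cb = clusters[ia], clusters[ib]
        dmerge = pair_dist(ca, cb)
        merged = DendrogramNode(dmerge / 2.0, children=[ca, cb])
        na, nb = sizes[ia], sizes[ib]
        for k, other in enumerate(clusters):
            if k in (ia, ib):
                continue
            v = (na * pair_dist(ca, other) + nb * pair_dist(cb, other)) / (na + nb)
            _cluster_dist[(id(merged), id(other))] = v
            _cluster_dist[(id(other), id(merged))] = v
        for idx in sorted((ia, ib), reverse=True):
            clusters.pop(idx)
            sizes.pop(idx)
        clusters.append(merged)
        sizes.append(na + nb)

    return Dendrogram(root=clusters[0])


def write_correlation_table(results: list[CorrelationResult], path) -> None:
    rows = [
        (r.stage_a, r.stage_b, r.r, r.n, r.ci_low, r.ci_high, r.confidence)
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["stage_a", "stage_b", "r", "n", "ci_low", "ci_high", "confidence"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
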