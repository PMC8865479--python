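"""Community comparison of virome libraries.

Bray-Curtis dissimilarities between library abundance profiles, UPGMA
dendrogram, principal-coordinate analysis (PCoA), rank-based ANOSIM with a
permutation p-value, and UpSet-style shared-species accounting.

Distance matrices are carried as :class:`skbio.DistanceMatrix` so they
interoperate with the wider ecology tooling; the statistics themselves are
computed here with the conventions documented per function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix

__all__ = [
    "AnosimResult",
    "SetSummary",
    "bray_curtis",
    "upgma",
    "pcoa",
    "anosim",
    "shared_sets",
]


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class SetSummary:
    """Disjoint intersection cardinalities of per-library species sets."""

    intersections: dict[frozenset, int]
    per_library_totals: dict[str, int]
    exclusives: dict[str, set]  # group label -> species only in that group
    core: set  # species present in every library


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between the rows of a count table.

    d(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum_i x_i + sum_i y_i).
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative abundances")
    sums = X.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("all-zero row: Bray-Curtis undefined")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(X[i], X[i + 1 :]).sum(axis=1)
        D[i, i + 1 :] = 1.0 - 2.0 * mins / (sums[i] + sums[i + 1 :])
    D = D + D.T
    return DistanceMatrix(D, ids=[str(i) for i in matrix.index])


# ---------------------------------------------------------------------------
# UPGMA


def _upgma_merge(d: np.ndarray, labels: Sequence[str]):
    """Average-linkage agglomeration; returns the merge tree.

    Ties between candidate pairs break on the smallest lexicographic pair of
    cluster labels (a cluster is labelled by its smallest leaf). Returns the
    root node as nested tuples (left, right, height) with leaves as strings.
    """
    clusters: dict[int, tuple] = {i: labels[i] for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    heights = {i: 0.0 for i in range(len(labels))}
    minlab = {i: labels[i] for i in range(len(labels))}
    dist = {(i, j): d[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))}
    nxt = len(labels)
    while len(clusters) > 1:
        best = None
        for (i, j), v in dist.items():
            if i not in clusters or j not in clusters:
                continue
            pair = tuple(sorted((minlab[i], minlab[j])))
            key = (v, pair)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        v = dist[(min(i, j), max(i, j))]
        h = v / 2.0
        if minlab[j] < minlab[i]:
            i, j = j, i
        node = (clusters[i], clusters[j], h, heights[i], heights[j])
        for k in list(clusters):
            if k in (i, j):
                continue
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            newd = (dist[a] * sizes[i] + dist[b] * sizes[j]) / (sizes[i] + sizes[j])
            dist[(min(nxt, k), max(nxt, k))] = newd
        clusters.pop(i)
        clusters.pop(j)
        clusters[nxt] = node
        sizes[nxt] = sizes[i] + sizes[j]
        heights[nxt] = h
        minlab[nxt] = min(minlab[i], minlab[j])
        nxt += 1
    (root,) = clusters.values()
    return root


def _to_newick(node, parent_height: float) -> str:
    """Serialise; branch length = parent cluster height - this cluster height."""
    if isinstance(node, str):
        return f"{node}:{parent_height:.12g}"
    left, right, h, _, _ = node
    inner = f"({_to_newick(left, h)},{_to_newick(right, h)})"
    return f"{inner}:{parent_height - h:.12g}"


def upgma(d: DistanceMatrix) -> str:
    """UPGMA dendrogram as a rooted Newick string (ultrametric heights)."""
    labels = list(d.ids)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least two items")
    root = _upgma_merge(d.data, labels)
    if isinstance(root, str):
        return f"({root});"
    left, right, h, _, _ = root
    return f"({_to_newick(left, h)},{_to_newick(right, h)});"


# ---------------------------------------------------------------------------
# PCoA


def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (Gower centering + eigendecomposition).

    Negative eigenvalues (possible for non-Euclidean input such as
    Bray-Curtis) are reported in the eigenvalue vector but their axes are
    dropped. Axis signs follow the convention that the first nonzero loading
    of each axis is positive. Returns (coordinates, all eigenvalues
    descending).
    """
    D = d.data
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least three items")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-10
    keep = vals > tol
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, k] = -col
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=list(d.ids), columns=cols), vals


# ---------------------------------------------------------------------------
# ANOSIM


def anosim(
    d: DistanceMatrix,
    groups: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities with a label-permutation p-value.

    R = (rbar_between - rbar_within) / (M/2) with ranks over all
    M = n(n-1)/2 pairwise distances (average ranks on ties), the standard
    rank-based statistic. p = (1 + #{R* >= R_obs}) / (1 + n_perm).
    """
    ids = list(d.ids)
    labels = np.array([groups[i] for i in ids] if isinstance(groups, Mapping) else list(groups))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d.data[iu, ju])
    M = len(ranks)
    denom = M / 2.0

    def stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = stat(labels)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    within_all = perms[:, iu] == perms[:, ju]
    rb = np.where(~within_all, ranks, np.nan)
    rw = np.where(within_all, ranks, np.nan)
    r_perm = (np.nanmean(rb, axis=1) - np.nanmean(rw, axis=1)) / denom
    p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (1 + n_perm)
    return AnosimResult(R=float(r_obs), p_value=float(p), n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# shared-species (UpSet) accounting


def shared_sets(
    presence: pd.DataFrame,
    threshold: float = 1,
    group_labels: Mapping[str, str] | None = None,
) -> SetSummary:
    """Disjoint intersection counts of per-library species sets.

    A species is present in a library when its count >= ``threshold``.
    Intersections are disjoint (each species counted in exactly the cell of
    the libraries that contain it), so the cells sum to the species union.
    With ``group_labels``, species confined to a single group's libraries
    are reported as that group's exclusives.
    """
    libs = list(presence.index)
    members: dict[str, frozenset] = {}
    for sp in presence.columns:
        inset = frozenset(lib for lib in libs if presence.loc[lib, sp] >= threshold)
        if inset:
            members[sp] = inset
    inter: dict[frozenset, int] = {}
    for sp, s in members.items():
        inter[s] = inter.get(s, 0) + 1
    totals = {lib: sum(1 for s in members.values() if lib in s) for lib in libs}
    core = {sp for sp, s in members.items() if s == frozenset(libs)}
    exclusives: dict[str, set] = {}
    if group_labels:
        for grp in sorted(set(group_labels.values())):
            glibs = {l for l in libs if group_labels[l] == grp}
            exclusives[grp] = {sp for sp, s in members.items() if s <= glibs}
    return SetSummary(
        intersections=inter, per_library_totals=totals, exclusives=exclusives, core=core
    )
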