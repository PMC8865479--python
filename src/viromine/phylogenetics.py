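"""Hallmark-gene phylogenetics on protein sequences.

Progressive multiple alignment (k-mer guide tree, profile-profile global
alignment under BLOSUM62 with affine gaps 11/1), removal of columns with
more than 50% gaps, Poisson-corrected pairwise distances, and
neighbor-joining trees. Distance trees are deliberately lightweight
surrogates operating on the same filtered alignments a model-based
inference would consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix

from .ecology import _upgma_merge
from .synthetic_data import AA20

__all__ = [
    "MultipleAlignment",
    "progressive_align",
    "filter_gap_columns",
    "protein_distance",
    "nj_tree",
]

log = logging.getLogger(__name__)

GAP = "-"
MAX_POISSON_DISTANCE = 10.0


@dataclass
class MultipleAlignment:
    names: list[str]
    rows: list[str]

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for n, r in zip(self.names, self.rows):
                fh.write(f">{n}\n{r}\n")


# ---------------------------------------------------------------------------
# progressive alignment

_S21 = None  # BLOSUM62 over AA20 + gap row/col of zeros


def _score21() -> np.ndarray:
    global _S21
    if _S21 is None:
        from Bio.Align import substitution_matrices

        B = substitution_matrices.load("BLOSUM62")
        alpha = str(B.alphabet)
        idx = [alpha.index(a) for a in AA20]
        S = np.zeros((21, 21))
        S[:20, :20] = np.array(B)[np.ix_(idx, idx)]
        _S21 = S
    return _S21


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(columns, 21) frequency matrix; index 20 is the gap character."""
    aa_idx = {a: i for i, a in enumerate(AA20)}
    L = len(rows[0])
    F = np.zeros((L, 21))
    for r in rows:
        for j, c in enumerate(r):
            F[j, aa_idx.get(c, 20)] += 1
    return F / len(rows)


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float = 11.0, gap_extend: float = 1.0
) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two profiles (Gotoh three-state DP).

    Column-column scores are the expected BLOSUM62 score over residue pairs,
    with gap characters contributing zero. Returns the gapped row sets.
    """
    S = _score21()
    Fa = _profile_freqs(rows_a)
    Fb = _profile_freqs(rows_b)
    score = Fa @ S @ Fb.T  # (La, Lb)
    La, Lb = score.shape
    NEG = -1e18
    open_cost = gap_open + gap_extend  # first gapped column
    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)  # gap in B (consumes A)
    Y = np.full((La + 1, Lb + 1), NEG)  # gap in A (consumes B)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = -open_cost - (i - 1) * gap_extend
    for j in range(1, Lb + 1):
        Y[0, j] = -open_cost - (j - 1) * gap_extend
    for i in range(1, La + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        srow = score[i - 1]
        for j in range(1, Lb + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best_prev + srow[j - 1]
            Xi[j] = max(Mi1[j] - open_cost, Xi1[j] - gap_extend)
            Yi[j] = max(Mi[j - 1] - open_cost, Yi[j - 1] - gap_extend)
    # traceback
    i, j = La, Lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    path = []
    while i > 0 or j > 0:
        if state == 0:
            path.append("M")
            prev = [M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            path.append("X")
            if i > 1 and abs(X[i, j] - (X[i - 1, j] - gap_extend)) < 1e-9:
                state = 1
            else:
                state = 0
            i -= 1
        else:
            path.append("Y")
            if j > 1 and abs(Y[i, j] - (Y[i, j - 1] - gap_extend)) < 1e-9:
                state = 2
            else:
                state = 0
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    path.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in path:
        if op in ("M", "X"):
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            ia += 1
        else:
            for o in out_a:
                o.append(GAP)
        if op in ("M", "Y"):
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
        else:
            for o in out_b:
                o.append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_distance(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    sets = [set(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            D[i, j] = D[j, i] = 1.0 - len(sets[i] & sets[j]) / denom
    return D


def progressive_align(seqs: dict[str, str] | Sequence[tuple[str, str]]) -> MultipleAlignment:
    """Progressive multiple alignment along a k-mer-distance UPGMA guide tree."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    names = [n for n, _ in items]
    if len(items) == 1:
        log.warning("single sequence: trivial alignment")
        return MultipleAlignment(names=names, rows=[items[0][1]])
    D = _kmer_distance([s for _, s in items])
    guide = _upgma_merge(D, names)
    by_name = dict(items)

    def build(node) -> tuple[list[str], list[str]]:
        if isinstance(node, str):
            return [node], [by_name[node]]
        left, right, *_ = node
        na, ra = build(left)
        nb, rb = build(right)
        ga, gb = _align_profiles(ra, rb)
        return na + nb, ga + gb

    out_names, rows = build(guide)
    order = {n: i for i, n in enumerate(names)}
    pairs = sorted(zip(out_names, rows), key=lambda p: order[p[0]])
    return MultipleAlignment(names=[n for n, _ in pairs], rows=[r for _, r in pairs])


# ---------------------------------------------------------------------------
# gap-column filter


def filter_gap_columns(msa: MultipleAlignment, max_gap_fraction: float = 0.5) -> MultipleAlignment:
    """Remove columns whose gap fraction strictly exceeds the threshold.

    A column at exactly the threshold (e.g. 3 gaps of 6 rows at 0.5) is
    retained. The old->new column mapping is stored on the result as
    ``column_map``.
    """
    n = len(msa.rows)
    keep = [
        j
        for j in range(msa.column_count)
        if sum(1 for r in msa.rows if r[j] == GAP) / n <= max_gap_fraction
    ]
    if not keep:
        raise ValueError("all columns removed by gap filter")
    out = MultipleAlignment(
        names=list(msa.names), rows=["".join(r[j] for j in keep) for r in msa.rows]
    )
    out.column_map = {old: new for new, old in enumerate(keep)}  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# distances + NJ


def protein_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) over shared ungapped columns.

    Saturated pairs (p >= 1 - e^-10) clamp to 10 with a warning; a pair with
    no mutually ungapped column is an error.
    """
    n = len(msa.rows)
    if n < 2:
        raise ValueError("need at least two rows")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = [
                (a, b)
                for a, b in zip(msa.rows[i], msa.rows[j])
                if a != GAP and b != GAP
            ]
            if not shared:
                raise ValueError(
                    f"rows {msa.names[i]!r} and {msa.names[j]!r} share no ungapped columns"
                )
            p = sum(1 for a, b in shared if a != b) / len(shared)
            if p >= 1.0 - np.exp(-MAX_POISSON_DISTANCE):
                log.warning("saturated pair (%s, %s): distance clamped", msa.names[i], msa.names[j])
                d = MAX_POISSON_DISTANCE
            else:
                d = -np.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, ids=list(msa.names))


def nj_tree(d: DistanceMatrix) -> str:
    """Neighbor-joining tree (Newick, unrooted trifurcating root).

    Standard Q-matrix minimisation; ties break on the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its smallest
    leaf). A negative branch length is clamped to zero and the deficit moved
    to the sister branch.
    """
    labels = list(d.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least three taxa")
    active = {i: (labels[i], labels[i]) for i in range(n)}  # id -> (newick, minlab)
    dist = {(i, j): float(d.data[i, j]) for i in range(n) for j in range(i + 1, n)}

    def get(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))]

    nxt = n
    while len(active) > 3:
        ids = sorted(active)
        m = len(ids)
        r = {i: sum(get(i, k) for k in ids if k != i) for i in ids}
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                i, j = ids[a], ids[b]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                pair = tuple(sorted((active[i][1], active[j][1])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        node = (
            f"({active[i][0]}:{li:.10g},{active[j][0]}:{lj:.10g})",
            min(active[i][1], active[j][1]),
        )
        for k in ids:
            if k in (i, j):
                continue
            dist[(min(nxt, k), max(nxt, k))] = (get(i, k) + get(j, k) - dij) / 2.0
        del active[i], active[j]
        active[nxt] = node
        nxt += 1
    (i, j, k) = sorted(active)
    li = (get(i, j) + get(i, k) - get(j, k)) / 2.0
    lj = (get(i, j) + get(j, k) - get(i, k)) / 2.0
    lk = (get(i, k) + get(j, k) - get(i, j)) / 2.0
    li, lj, lk = (max(0.0, x) for x in (li, lj, lk))
    return (
        f"({active[i][0]}:{li:.10g},{active[j][0]}:{lj:.10g},{active[k][0]}:{lk:.10g});"
    )
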