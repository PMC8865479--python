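"""Progressive alignment, gap-column filtering, Poisson distances, NJ trees."""

import random

import numpy as np
import pytest
from skbio import DistanceMatrix

from viromine import synthetic_data as sd
from viromine.phylogenetics import (
    MultipleAlignment,
    filter_gap_columns,
    nj_tree,
    progressive_align,
    protein_distance,
)

BLOSUM = None


def affine_global_oracle(a, b, open_=11, ext=1):
    """Exhaustive three-state DP for two sequences (tiny inputs only)."""
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    NEG = -1e9
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0
    for i in range(1, la + 1):
        X[i][0] = -(open_ + ext) - (i - 1) * ext
    for j in range(1, lb + 1):
        Y[0][j] = -(open_ + ext) - (j - 1) * ext
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + B[a[i - 1], b[j - 1]]
            X[i][j] = max(M[i - 1][j] - (open_ + ext), X[i - 1][j] - ext)
            Y[i][j] = max(M[i][j - 1] - (open_ + ext), Y[i][j - 1] - ext)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def alignment_score(rows, open_=11, ext=1):
    """Score a pairwise alignment with BLOSUM62 + affine gaps."""
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    a, b = rows
    score = 0.0
    in_gap = None
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            which = "a" if x == "-" else "b"
            score -= (open_ + ext) if in_gap != which else ext
            in_gap = which
        else:
            score += B[x, y]
            in_gap = None
    return score


class TestProgressiveAlign:
    def test_identical_sequences_align_gapless(self):
        msa = progressive_align({"a": "MKVLWAAL", "b": "MKVLWAAL"})
        assert msa.rows == ["MKVLWAAL", "MKVLWAAL"]

    def test_single_sequence_returns_trivial_alignment(self):
        msa = progressive_align({"only": "MKV"})
        assert msa.rows == ["MKV"]

    def test_pairwise_score_matches_exhaustive_dp(self):
        rng = random.Random(0)
        for _ in range(15):
            a = "".join(rng.choice(sd.AA20) for _ in range(rng.randint(3, 12)))
            b = "".join(rng.choice(sd.AA20) for _ in range(rng.randint(2, 12)))
            msa = progressive_align({"a": a, "b": b})
            assert alignment_score(msa.rows) == pytest.approx(affine_global_oracle(a, b))

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(1)
        base = sd.random_protein(rng, 80)
        seqs = {f"s{i}": sd.mutate_protein(base, 0.2, rng) for i in range(5)}
        msa = progressive_align(seqs)
        for name, row in zip(msa.names, msa.rows):
            assert row.replace("-", "") == seqs[name]

    def test_related_homologs_align_mostly_gapless(self):
        rng = np.random.default_rng(2)
        base = sd.random_protein(rng, 100)
        seqs = {f"s{i}": sd.mutate_protein(base, float(rng.uniform(0.05, 0.35)), rng) for i in range(5)}
        msa = progressive_align(seqs)
        # substitution-only homologs: every column should be homologous,
        # i.e. the alignment needs no gaps at >=90% of positions
        gapless = sum(1 for j in range(msa.column_count) if all(r[j] != "-" for r in msa.rows))
        assert gapless / msa.column_count >= 0.9
        assert msa.column_count <= 110


class TestFilterGapColumns:
    def test_exactly_half_gaps_retained(self):
        msa = MultipleAlignment(names=list("abcdef"), rows=["A-", "A-", "A-", "AC", "AC", "AC"])
        assert filter_gap_columns(msa).column_count == 2

    def test_majority_gap_column_removed(self):
        msa = MultipleAlignment(names=list("abcd"), rows=["A-", "A-", "A-", "AC"])
        out = filter_gap_columns(msa)
        assert out.column_count == 1
        assert out.column_map == {0: 0}

    def test_matches_per_column_counting_oracle(self):
        rng = random.Random(3)
        for _ in range(30):
            n, L = rng.randint(2, 8), rng.randint(5, 40)
            rows = [
                "".join(rng.choice("ACDE-") for _ in range(L)) for _ in range(n)
            ]
            if all(set(r) <= {"-"} for r in rows):
                continue
            msa = MultipleAlignment(names=[f"s{i}" for i in range(n)], rows=rows)
            keep = [j for j in range(L) if sum(r[j] == "-" for r in rows) / n <= 0.5]
            if not keep:
                with pytest.raises(ValueError):
                    filter_gap_columns(msa)
                continue
            out = filter_gap_columns(msa)
            assert out.rows == ["".join(r[j] for j in keep) for r in rows]

    def test_idempotent(self):
        rng = random.Random(4)
        rows = ["".join(rng.choice("AC-") for _ in range(30)) for _ in range(5)]
        msa = MultipleAlignment(names=[f"s{i}" for i in range(5)], rows=rows)
        once = filter_gap_columns(msa)
        twice = filter_gap_columns(once)
        assert once.rows == twice.rows


class TestProteinDistance:
    def test_identical_rows_distance_zero(self):
        msa = MultipleAlignment(names=["a", "b"], rows=["MKVA", "MKVA"])
        assert protein_distance(msa).data[0, 1] == 0

    def test_poisson_correction_closed_form(self):
        msa = MultipleAlignment(names=["a", "b"], rows=["A" * 9 + "C", "A" * 9 + "D"])
        assert protein_distance(msa).data[0, 1] == pytest.approx(-np.log(0.9))

    def test_saturation_clamps_to_maximum(self):
        msa = MultipleAlignment(names=["a", "b"], rows=["ACDEFGHIKL", "LKIHGFEDCA"])
        assert protein_distance(msa).data[0, 1] == 10.0

    def test_disjoint_gap_patterns_rejected(self):
        msa = MultipleAlignment(names=["a", "b"], rows=["AA--", "--CC"])
        with pytest.raises(ValueError):
            protein_distance(msa)


def random_additive_case(rng):
    import dendropy

    n = int(rng.integers(4, 11))
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=random.Random(int(rng.integers(2**31))),
    )
    for e in t.edges():
        e.length = float(rng.uniform(0.05, 1.0))
    pdm = t.phylogenetic_distance_matrix()
    taxa = list(t.taxon_namespace)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.distance(taxa[i], taxa[j])
    return t, DistanceMatrix(D, ids=[x.label for x in taxa])


class TestNjTree:
    def test_four_taxon_additive_distances_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives these path distances
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        nwk = nj_tree(DistanceMatrix(D, ids=list("ABCD")))
        assert nwk == "(C:3,D:4,(A:1,B:2):1);"

    def test_star_distances_resolve_with_zero_internal_branch(self):
        D = np.ones((4, 4)) - np.eye(4)
        nwk = nj_tree(DistanceMatrix(D, ids=list("ABCD")))
        assert ":0)" in nwk.replace(":0,", ":0)") or ":0" in nwk

    def test_additive_recovery_property(self):
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(7)
        for _ in range(20):
            true, dmat = random_additive_case(rng)
            est = dendropy.Tree.get(
                data=nj_tree(dmat), schema="newick", taxon_namespace=true.taxon_namespace
            )
            true.is_rooted = est.is_rooted = False
            true.update_bipartitions()
            est.update_bipartitions()
            assert treecompare.symmetric_difference(true, est) == 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))


def test_two_clades_recovered_monophyletic(community):
    """Hallmark homologs from two diverged clades cluster by clade."""
    import dendropy

    rng = np.random.default_rng(11)
    anc = sd.random_protein(rng, 150)
    c1 = sd.mutate_protein(anc, 0.2, rng)
    c2 = sd.mutate_protein(anc, 0.2, rng)
    seqs = {}
    for i in range(3):
        seqs[f"a{i}"] = sd.mutate_protein(c1, 0.05, rng)
        seqs[f"b{i}"] = sd.mutate_protein(c2, 0.05, rng)
    msa = progressive_align(seqs)
    d = protein_distance(filter_gap_columns(msa))
    t = dendropy.Tree.get(data=nj_tree(d), schema="newick")
    t.is_rooted = False
    t.encode_bipartitions()
    taxa = {x.label for x in t.taxon_namespace}
    clade_a = frozenset(l for l in taxa if l.startswith("a"))
    splits = [
        frozenset(x.label for x in b.leafset_taxa(t.taxon_namespace)) for b in t.bipartition_encoding
    ]
    assert any(s == clade_a or (taxa - s) == clade_a for s in splits)
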