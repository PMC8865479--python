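"""ORF prediction, read mapping, contig merging, hallmark calls."""

import numpy as np

from viromine import synthetic_data as sd
from viromine.annotation import call_hallmarks, map_reads, merge_contigs, predict_orfs
from viromine.assembly import Contig
from viromine.homology_triage import AlignmentHit
from viromine.read_processing import Read, reverse_complement

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq, min_size=300):
    """Independent enumerator: every first-ATG-after-stop to next in-frame stop."""
    found = set()
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(3):
            atg = None
            p = off
            while p + 3 <= len(s):
                c = s[p : p + 3]
                if c in STOPS:
                    if atg is not None and p + 3 - atg >= min_size:
                        found.add((strand, atg, p + 3, True))
                    atg = None
                elif c == "ATG" and atg is None:
                    atg = p
                p += 3
            if atg is not None:
                end = off + 3 * ((len(s) - off) // 3)
                if end - atg >= min_size:
                    found.add((strand, atg, end, False))
    return found


def orf_key(o, L):
    if o.strand == "+":
        return (o.strand, o.start, o.end, o.has_stop)
    return (o.strand, L - o.end, L - o.start, o.has_stop)


class TestPredictOrfs:
    def test_minimum_size_is_300_nt_including_stop(self):
        rng = np.random.default_rng(0)
        prot98 = sd.random_protein(rng, 98).replace("M", "L")
        nt = "ATG" + sd.back_translate(prot98, rng)[3:]  # 300 nt with stop
        contig = Contig("c", "TTTT" + nt + "TTTT", "L", ["r"])
        sizes = [o.nt_length for o in predict_orfs(contig) if o.strand == "+"]
        assert 300 in sizes

    def test_297_nt_orf_not_reported(self):
        rng = np.random.default_rng(1)
        prot97 = sd.random_protein(rng, 97).replace("M", "L")
        nt = "ATG" + sd.back_translate(prot97, rng)[3:]
        assert len(nt) == 297
        contig = Contig("c", "TT" + nt + "TT", "L", ["r"])
        assert predict_orfs(contig) == []

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            seq = sd.random_dna(rng, int(rng.integers(400, 3000)))
            contig = Contig("c", seq, "L", ["r"])
            got = {orf_key(o, len(seq)) for o in predict_orfs(contig)}
            assert got == brute_force_orfs(seq)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        seq = sd.random_dna(rng, 2000)
        fwd = predict_orfs(Contig("c", seq, "L", ["r"]))
        rev = predict_orfs(Contig("c", reverse_complement(seq), "L", ["r"]))
        L = len(seq)
        mirrored = {(("-" if o.strand == "+" else "+"), L - o.end, L - o.start) for o in rev}
        assert {(o.strand, o.start, o.end) for o in fwd} == mirrored

    def test_aa_sequence_consistent_with_coordinates(self):
        rng = np.random.default_rng(4)
        seq = sd.random_dna(rng, 3000)
        from Bio.Seq import Seq

        for o in predict_orfs(Contig("c", seq, "L", ["r"])):
            nt = seq[o.start : o.end]
            if o.strand == "-":
                nt = reverse_complement(nt)
            aa = str(Seq(nt).translate())
            if o.has_stop:
                assert aa.endswith("*") and aa[:-1] == o.aa_sequence
            else:
                assert aa == o.aa_sequence
            assert o.aa_sequence.startswith("M")
            assert (o.end - o.start) % 3 == 0


class TestMapReads:
    def test_exact_read_maps_with_coverage(self):
        rng = np.random.default_rng(5)
        ref = Contig("ref", sd.random_dna(rng, 800), "L", ["x"])
        read = Read("r1", ref.sequence[100:350], [30] * 250, "L")
        counts, cov, assign = map_reads([read], [ref])
        assert counts["ref"] == 1
        assert assign["r1"] == "ref"
        assert cov["ref"][100:350].sum() == 250

    def test_reverse_strand_read_maps(self):
        rng = np.random.default_rng(6)
        ref = Contig("ref", sd.random_dna(rng, 600), "L", ["x"])
        read = Read("r1", reverse_complement(ref.sequence[50:300]), [30] * 250, "L")
        counts, _, _ = map_reads([read], [ref])
        assert counts["ref"] == 1

    def test_unrelated_read_unmapped(self):
        rng = np.random.default_rng(7)
        ref = Contig("ref", sd.random_dna(rng, 800), "L", ["x"])
        read = Read("r1", sd.random_dna(rng, 250), [30] * 250, "L")
        counts, _, assign = map_reads([read], [ref])
        assert counts["ref"] == 0 and "r1" not in assign

    def test_tiling_reads_conserve_coverage(self):
        rng = np.random.default_rng(8)
        ref = Contig("ref", sd.random_dna(rng, 1000), "L", ["x"])
        reads = [Read(f"r{i}", ref.sequence[p : p + 100], [30] * 100, "L") for i, p in enumerate(range(0, 900, 90))]
        counts, cov, _ = map_reads(reads, [ref])
        assert counts["ref"] == len(reads)
        assert cov["ref"].sum() == sum(100 for _ in reads)

    def test_read_counted_once_on_tie(self):
        rng = np.random.default_rng(9)
        seq = sd.random_dna(rng, 500)
        refs = [Contig("a", seq, "L", ["x"]), Contig("b", seq, "L", ["y"])]
        read = Read("r1", seq[100:350], [30] * 250, "L")
        counts, _, assign = map_reads([read], refs)
        assert counts["a"] + counts["b"] == 1
        assert assign["r1"] == "a"  # first reference in input order wins


def mkhit(qid, subject, sspan, frame=1, bits=200.0):
    return AlignmentHit(
        query_id=qid,
        subject_id=subject,
        frame=frame,
        bit_score=bits,
        e_value=1e-30,
        identity=0.95,
        query_span=(0, sspan[1] - sspan[0]),
        subject_span=sspan,
        subject_lineage=("r", "o", "Siphoviridae", "sp"),
        db_role="viral",
    )


class TestMergeContigs:
    def test_ordered_disjoint_spans_merge_with_spacer(self):
        c1 = Contig("c1", "A" * 300, "L", ["r1"])
        c2 = Contig("c2", "C" * 300, "L", ["r2"])
        hits = {"c1": mkhit("c1", "prot", (0, 100)), "c2": mkhit("c2", "prot", (150, 250))}
        out = merge_contigs([c1, c2], hits)
        merged = [c for c in out if c.id.startswith("merged")]
        assert len(merged) == 1
        assert merged[0].sequence == "A" * 300 + "N" * 10 + "C" * 300
        assert merged[0].member_reads == ["r1", "r2"]

    def test_different_subjects_unmerged(self):
        c1 = Contig("c1", "A" * 300, "L", ["r1"])
        c2 = Contig("c2", "C" * 300, "L", ["r2"])
        hits = {"c1": mkhit("c1", "p1", (0, 100)), "c2": mkhit("c2", "p2", (150, 250))}
        out = merge_contigs([c1, c2], hits)
        assert {c.id for c in out} == {"c1", "c2"}

    def test_overlapping_spans_unmerged(self):
        c1 = Contig("c1", "A" * 300, "L", ["r1"])
        c2 = Contig("c2", "C" * 300, "L", ["r2"])
        hits = {"c1": mkhit("c1", "p", (0, 100)), "c2": mkhit("c2", "p", (50, 150))}
        out = merge_contigs([c1, c2], hits)
        assert {c.id for c in out} == {"c1", "c2"}

    def test_fragmented_simulator_genome_merges_collinearly(self, community, viral_searcher):
        g = next(g for g in community.genomes if g.family_label == "Myoviridae")
        f = next(f for f in g.features if f.role == "hallmark")
        # two non-overlapping fragments of the hallmark gene region
        fa = Contig("fa", g.sequence[f.start : f.start + 220], "L", ["r1"])
        fb = Contig("fb", g.sequence[f.start + 300 : f.start + 520], "L", ["r2"])
        hits = {}
        for c in (fa, fb):
            h = viral_searcher.search_translated(c.id, c.sequence)
            hits[c.id] = next(x for x in h if x.subject_id == f"{g.id}|{f.gene_id}")
        out = merge_contigs([fa, fb], hits)
        merged = [c for c in out if c.id.startswith("merged")]
        assert len(merged) == 1
        assert merged[0].sequence.index(fa.sequence) < merged[0].sequence.index(fb.sequence)


class TestCallHallmarks:
    def test_simulator_hallmark_orf_called_complete(self, community):
        g = next(g for g in community.genomes if g.family_label == "Siphoviridae")
        f = next(f for f in g.features if f.role == "hallmark")
        contig = Contig("c", g.sequence[f.start - 10 : f.end + 10], "L", ["r"])
        orfs = predict_orfs(contig)
        calls = call_hallmarks(orfs, community.dbs["profiles"])
        assert any(c.hallmark == "TerL" and c.complete_cds for c in calls)

    def test_truncated_orf_called_but_not_complete(self, community):
        g = next(g for g in community.genomes if g.family_label == "Siphoviridae")
        f = next(f for f in g.features if f.role == "hallmark")
        # cut inside the gene: ORF runs off the contig edge, no stop codon
        contig = Contig("c", g.sequence[f.start - 10 : f.end - 60], "L", ["r"])
        orfs = predict_orfs(contig)
        calls = call_hallmarks(orfs, community.dbs["profiles"])
        assert calls and all(not c.complete_cds for c in calls)

    def test_complete_cds_implies_start_and_stop(self, community):
        g = next(g for g in community.genomes if g.category in sd.HALLMARK_BY_CATEGORY)
        contig = Contig("c", g.sequence, "L", ["r"])
        orfs = {o.id: o for o in predict_orfs(contig)}
        for c in call_hallmarks(list(orfs.values()), community.dbs["profiles"]):
            if c.complete_cds:
                o = orfs[c.orf_id]
                assert o.has_start and o.has_stop
                assert o.aa_sequence.startswith("M")
                assert c.profile_coverage >= 0.9
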