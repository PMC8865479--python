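"""Translated search, Karlin-Altschul statistics, competitive filter, profiles."""

import math

import numpy as np
import pytest

from viromine import synthetic_data as sd
from viromine import homology_triage as ht
from viromine.homology_triage import (
    QueryItem,
    bit_score,
    e_value,
    profile_fallback,
    scan_profile,
    six_frame_translate,
    tabulate,
    triage_queries,
)

# independent codon table for the translation oracle (standard code)
CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
COMP = str.maketrans("ACGT", "TGCA")


def oracle_translate(seq, offset):
    out = []
    for i in range(offset, len(seq) - 2, 3):
        out.append(CODONS.get(seq[i : i + 3], "X"))
    return "".join(out)


class TestSixFrameTranslate:
    def test_simple_codons(self):
        assert six_frame_translate("ATGGCC")[0] == "MA"

    def test_empty_input_gives_six_empty_strings(self):
        assert six_frame_translate("") == [""] * 6

    def test_reverse_frame_recovers_coding_sequence(self):
        rng = np.random.default_rng(0)
        prot = sd.random_protein(rng, 30)
        nt = sd.back_translate(prot, rng)
        rc = nt.translate(COMP)[::-1]
        frames = six_frame_translate(rc)
        assert any("M" + prot in f for f in frames[3:])

    def test_agrees_with_independent_codon_table(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), 300))
            frames = six_frame_translate(seq)
            rcseq = seq.translate(COMP)[::-1]
            for off in range(3):
                assert frames[off] == oracle_translate(seq, off)
                assert frames[3 + off] == oracle_translate(rcseq, off)


class TestKarlinAltschul:
    def test_bits_and_e_match_direct_formula(self):
        S, m, n = 100, 100, 10_000
        bits = bit_score(S)
        assert bits == pytest.approx((0.267 * 100 - math.log(0.041)) / math.log(2))
        assert e_value(bits, m, n) == pytest.approx(1e6 * 2.0 ** (-bits))

    def test_e_value_strictly_increases_with_database_size(self):
        bits = bit_score(80)
        es = [e_value(bits, 100, n) for n in (10**3, 10**4, 10**5, 10**6)]
        assert all(a < b for a, b in zip(es, es[1:]))


class TestTranslatedSearch:
    def test_self_hit_has_full_identity_and_span(self, community, viral_searcher):
        entry = next(e for e in community.dbs["viral_db"] if len(e.aa_sequence) >= 100)
        rng = np.random.default_rng(2)
        nt = sd.back_translate(entry.aa_sequence, rng)
        hits = viral_searcher.search_translated("q", nt)
        assert hits
        top = hits[0]
        assert top.subject_id == entry.id
        assert top.identity == pytest.approx(1.0)
        assert top.subject_span == (0, len(entry.aa_sequence))

    def test_reported_hits_satisfy_e_cutoff_and_formula(self, community, viral_searcher):
        r = community.libraries["PE-NQ"][0]
        for h in viral_searcher.search_translated(r.id, r.sequence):
            assert h.e_value < 1e-5
            assert h.bit_score > 0

    def test_empty_database_returns_no_hits(self):
        s = ht.ProteinSearcher([])
        assert s.search_translated("q", "ACGT" * 30) == []

    def test_protein_search_of_db_member_finds_itself(self, community):
        arg = ht.ProteinSearcher(community.dbs["arg_db"])
        e = community.dbs["arg_db"][0]
        hits = arg.search_protein("q", e.aa_sequence)
        assert hits and hits[0].subject_id == e.id and hits[0].frame == 0


class TestCompetitiveFilter:
    def test_bacterial_decoy_read_removed(self, community, viral_searcher, nvnr_searcher):
        # a read from the bacterial chromosomal copy of a phage-borne ARG
        # hits the phage copy in the viral db but its own copy outcompetes it
        g = next(g for g in community.genomes if g.species_label == "bacterial sp1")
        f = next(f for f in g.features if f.name.endswith("_chrom"))
        read_nt = g.sequence[f.start : f.start + 250]
        vh = viral_searcher.search_translated("q", read_nt)
        assert vh, "decoy read should raw-hit the viral database"
        retained, blocker = ht.competitive_filter(vh, read_nt, nvnr_searcher, query_id="q")
        assert retained == [] and blocker is not None

    def test_genuine_phage_read_retained(self, community, viral_searcher, nvnr_searcher):
        viral_ids = community.manifest.viral_read_ids()
        read = next(
            r
            for r in community.libraries["PE-NQ"]
            if r.id in viral_ids
            and community.manifest.per_read[r.id]["family"] == "Siphoviridae"
        )
        vh = viral_searcher.search_translated(read.id, read.sequence)
        assert vh
        retained, _ = ht.competitive_filter(vh, read.sequence, nvnr_searcher, query_id=read.id)
        assert retained

    def test_tie_favours_viral(self, viral_searcher):
        hit = ht.AlignmentHit(
            "q", "s", 1, 50.0, 1e-9, 1.0, (0, 10), (0, 10), ("", "", "f", "sp"), "viral"
        )

        class FakeSearcher:
            def batch_search_translated(self, q, e_cutoff=1e-5):
                return {qid: [ht.AlignmentHit(qid, "n", 1, 50.0, 1e-9, 1.0, (0, 10), (0, 10), ("", "", "b", "x"), "nvnr")] for qid, _ in q}

            def search_translated(self, qid, seq, e_cutoff=1e-5):
                return self.batch_search_translated([(qid, seq)])[qid]

        retained, blocker = ht.competitive_filter([hit], "ACGT" * 30, FakeSearcher(), query_id="q")
        assert retained == [hit] and blocker is None


class TestProfileFallback:
    def test_remote_homolog_caught_by_profile_after_pairwise_misses(self, community):
        rng = np.random.default_rng(9)
        g = next(g for g in community.genomes if g.family_label == "Siphoviridae")
        hall = next(f for f in g.features if f.role == "hallmark").protein
        mut = sd.mutate_protein(hall, 0.65, rng)
        nt = sd.back_translate(mut, rng)
        fb = profile_fallback(
            [QueryItem(id="q", sequence=nt, library="L", is_contig=True)],
            community.dbs["profiles"],
        )
        assert fb and fb[0].subject_id == "profile:TerL"
        assert fb[0].subject_lineage[2] == "unclassified Caudovirales"

    def test_random_sequences_below_threshold(self, community):
        rng = np.random.default_rng(10)
        items = [
            QueryItem(id=f"r{i}", sequence=sd.random_dna(rng, 700), library="L", is_contig=True)
            for i in range(100)
        ]
        fps = profile_fallback(items, community.dbs["profiles"])
        assert len(fps) / 100 <= 0.05

    def test_exact_hallmark_scores_its_own_column_sum(self, community):
        prof = next(p for p in community.dbs["profiles"] if p.name == "TerL")
        g = next(g for g in community.genomes if g.family_label == "Myoviridae")
        hall = next(f for f in g.features if f.role == "hallmark").protein
        score, cov, start = scan_profile(prof, hall)
        expected = sd.score_profile_sequence(prof, hall)
        assert cov == 1.0 and start == 0
        assert score == pytest.approx(expected)


class TestTriageAndTabulate:
    def test_no_query_is_both_assigned_and_removed(self, community, viral_searcher, nvnr_searcher):
        reads = community.libraries["PT-SZZ"][:200]
        items = [QueryItem(id=r.id, sequence=r.sequence, library=r.library) for r in reads]
        assignments, best, removed = triage_queries(
            items, viral_searcher, nvnr_searcher, community.dbs["profiles"]
        )
        assigned = {a.query_id for a in assignments}
        assert assigned.isdisjoint(removed)

    def test_tabulate_counts_member_reads(self):
        a = ht.TaxonomyAssignment("c1", "L1", "Siphoviridae", "Siphoviridae sp1", 7, "primary_search")
        b = ht.TaxonomyAssignment("c2", "L1", "Siphoviridae", "Siphoviridae sp2", 2, "primary_search")
        m = tabulate([a, b], level="family")
        assert m.loc["L1", "Siphoviridae"] == 9

    def test_tabulate_empty_and_normalised(self):
        assert tabulate([]).empty
        a = ht.TaxonomyAssignment("c1", "L1", "Siphoviridae", "s", 3, "primary_search")
        b = ht.TaxonomyAssignment("c2", "L1", "Microviridae", "s", 1, "primary_search")
        m = tabulate([a, b], level="family", normalize=True)
        assert m.loc["L1"].sum() == pytest.approx(1.0)
        assert m.loc["L1", "Siphoviridae"] == pytest.approx(0.75)

    def test_unknown_taxon_rejected(self):
        a = ht.TaxonomyAssignment("c1", "L1", "Madeupviridae", "s", 1, "primary_search")
        with pytest.raises(ValueError):
            tabulate([a], level="family")
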