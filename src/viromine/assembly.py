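"""Greedy overlap-layout assembly of cleaned reads, per library.

The assembler repeatedly merges the pair of sequences with the best
suffix-prefix overlap (>= ``min_overlap`` nt at >= ``min_identity``),
considering both orientations, until no qualifying merge remains; unmerged
reads become singlets. A post-hoc chimera pass flags contigs whose two
halves hit subjects from different viral families.

Overlap detection is seeded with an exact k-mer from each sequence's prefix,
so overlaps whose first ``SEED_LEN`` bases are error-free are found; this is
the standard index shortcut and is exact for error-free overlaps.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional, Sequence

from .homology_triage import AlignmentHit
from .read_processing import Read, reverse_complement

__all__ = ["Contig", "greedy_assemble", "flag_chimeras", "contigs_to_fasta"]

SEED_LEN = 16


@dataclass
class Contig:
    id: str
    sequence: str
    library: str
    member_reads: list[str]
    is_singlet: bool = False
    chimera_flag: bool = False


class _Seq:
    __slots__ = ("sid", "seq", "rc", "members", "alive")

    def __init__(self, sid: str, seq: str, members: list[str]):
        self.sid = sid
        self.seq = seq
        self.rc = reverse_complement(seq)
        self.members = members
        self.alive = True


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> tuple[int, int]:
    """Best suffix(a)-prefix(b) overlap: returns (score=matches, length).

    Candidate overlap lengths come from exact occurrences of b's leading
    ``SEED_LEN``-mer within a's suffix region; each candidate is verified
    base-by-base against the identity floor over the full overlap.
    """
    if len(b) < min_overlap or len(a) < min_overlap:
        return (0, 0)
    seed = b[:SEED_LEN]
    best = (0, 0)
    start = max(0, len(a) - len(b))
    pos = a.find(seed, start)
    while pos != -1:
        ov = len(a) - pos
        if ov >= min_overlap and ov <= len(b):
            matches = sum(1 for x, y in zip(a[pos:], b[:ov]) if x == y)
            if matches >= min_identity * ov and matches > best[0]:
                best = (matches, ov)
        pos = a.find(seed, pos + 1)
    return best


def greedy_assemble(
    reads: Sequence[Read], min_overlap: int = 35, min_identity: float = 0.98
) -> list[Contig]:
    """Greedy overlap assembly of one library's reads.

    Deterministic for a given input: merge candidates are kept in a heap
    keyed by (-score, id pair), so the highest-scoring overlap merges first
    and ties break lexicographically by sequence id. Every input read ends up
    in exactly one contig's member list. In an overlap the leading sequence's
    bases are kept (two-sequence majority vote degenerates to that).
    """
    seqs: dict[str, _Seq] = {}
    for r in reads:
        seqs[r.id] = _Seq(r.id, r.sequence, [r.id])
    library = reads[0].library if reads else ""

    heap: list[tuple[int, str, str, int, int]] = []  # (-score, a_id, b_id, orient, ov)
    # global k-mer index over every sequence ever added (lazy deletion):
    # kmer -> sids whose sequence contains it. Used to find, for a sequence
    # b, the partners a whose body contains b's prefix seed.
    kmer_index: dict[str, set[str]] = {}

    def index_seq(s: _Seq) -> None:
        for p in range(len(s.seq) - SEED_LEN + 1):
            kmer_index.setdefault(s.seq[p : p + SEED_LEN], set()).add(s.sid)

    def push_pair(a: _Seq, b: _Seq) -> None:
        if a.sid == b.sid:
            return
        # orientations: 0 a+b, 1 a+rc(b); suffix(a)/prefix(b) only -- the
        # reverse direction is covered by the (b, a) pair
        for orient, bseq in ((0, b.seq), (1, b.rc)):
            sc, ov = _best_overlap(a.seq, bseq, min_overlap, min_identity)
            if sc > 0:
                heapq.heappush(heap, (-sc, a.sid, b.sid, orient, ov))

    def push_candidates(b: _Seq) -> None:
        """Find left partners for b via its prefix seeds (both strands)."""
        cands: set[str] = set()
        for bseq in (b.seq, b.rc):
            if len(bseq) >= SEED_LEN:
                cands |= kmer_index.get(bseq[:SEED_LEN], set())
        for aid in sorted(cands):
            a = seqs.get(aid)
            if a is not None and a.alive:
                push_pair(a, b)

    for s in seqs.values():
        index_seq(s)
    for s in sorted(seqs.values(), key=lambda x: x.sid):
        push_candidates(s)

    counter = 0
    while heap:
        negsc, aid, bid, orient, ov = heapq.heappop(heap)
        a = seqs.get(aid)
        b = seqs.get(bid)
        if a is None or b is None or not a.alive or not b.alive:
            continue
        bseq = b.seq if orient == 0 else b.rc
        sc, ov2 = _best_overlap(a.seq, bseq, min_overlap, min_identity)
        if sc != -negsc or ov2 != ov:  # stale entry
            if sc > 0:
                heapq.heappush(heap, (-sc, aid, bid, orient, ov2))
            continue
        merged = a.seq + bseq[ov:]
        a.alive = False
        b.alive = False
        del seqs[aid], seqs[bid]
        counter += 1
        m = _Seq(f"m{counter:06d}", merged, a.members + b.members)
        seqs[m.sid] = m
        index_seq(m)
        # m as right partner (others' suffixes contain m's prefix)
        push_candidates(m)
        # m as left partner: any alive seq whose prefix seed occurs in m
        for other in list(seqs.values()):
            if other.sid == m.sid or not other.alive:
                continue
            for oseq in (other.seq, other.rc):
                if len(oseq) >= SEED_LEN and oseq[:SEED_LEN] in m.seq:
                    push_pair(m, other)
                    break

    out = []
    for i, s in enumerate(sorted(seqs.values(), key=lambda s: (-len(s.members), s.sid))):
        out.append(
            Contig(
                id=f"{library or 'lib'}_c{i + 1:05d}",
                sequence=s.seq,
                library=library,
                member_reads=sorted(s.members),
                is_singlet=len(s.members) == 1,
            )
        )
    return out


def flag_chimeras(
    contigs: Sequence[Contig],
    hits_by_contig: dict[str, list[AlignmentHit]],
    e_cutoff: float = 1e-5,
) -> list[Contig]:
    """Flag contigs whose two halves best-hit different viral families.

    A contig is chimeric when the best hit over its 5' half and the best hit
    over its 3' half target subjects from different families, both at
    E < cutoff, with non-overlapping query spans. Query spans are converted
    from frame amino-acid coordinates to contig nucleotide coordinates.
    """
    for c in contigs:
        hits = hits_by_contig.get(c.id, [])
        half = len(c.sequence) / 2
        best5: Optional[AlignmentHit] = None
        best3: Optional[AlignmentHit] = None
        spans = {}
        for h in hits:
            if h.e_value >= e_cutoff:
                continue
            qs, qe = h.query_span
            if h.frame >= 0:
                off = abs(h.frame) - 1 if h.frame else 0
                nt_span = (off + 3 * qs, off + 3 * qe)
            else:
                off = abs(h.frame) - 1
                nt_span = (len(c.sequence) - (off + 3 * qe), len(c.sequence) - (off + 3 * qs))
            spans[id(h)] = nt_span
            mid = (nt_span[0] + nt_span[1]) / 2
            if mid < half and (best5 is None or h.bit_score > best5.bit_score):
                best5 = h
            if mid >= half and (best3 is None or h.bit_score > best3.bit_score):
                best3 = h
        if best5 is not None and best3 is not None:
            fam5, fam3 = best5.subject_lineage[2], best3.subject_lineage[2]
            s5, s3 = spans[id(best5)], spans[id(best3)]
            disjoint = s5[1] <= s3[0] or s3[1] <= s5[0]
            if fam5 != fam3 and disjoint:
                c.chimera_flag = True
    return list(contigs)


def contigs_to_fasta(contigs: Sequence[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(
                f">{c.id} lib={c.library} reads={len(c.member_reads)}"
                f"{' chimera' if c.chimera_flag else ''}\n{c.sequence}\n"
            )
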