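"""Viral sequence extension and annotation.

Covers the post-discovery steps applied to viral contigs: merging
non-overlapping contigs that hit the same subject, mapping reads back to
references, ORF prediction (ATG start, standard code, minimum size 300 nt
including the stop codon), hallmark-gene detection against the five
hallmark profiles, and complete-CDS selection for phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assembly import Contig
from .homology_triage import AlignmentHit, scan_profile
from .read_processing import Read, reverse_complement
from .synthetic_data import ProfileMatrix

__all__ = [
    "ORF",
    "HallmarkCall",
    "merge_contigs",
    "map_reads",
    "predict_orfs",
    "call_hallmarks",
    "orfs_to_tsv",
]


@dataclass
class ORF:
    """Predicted open reading frame in contig forward-strand coordinates."""

    id: str
    contig_id: str
    frame: int
    start: int  # 0-based half-open on the forward strand
    end: int
    strand: str
    aa_sequence: str
    has_start: bool = True
    has_stop: bool = True

    @property
    def nt_length(self) -> int:
        return self.end - self.start


@dataclass
class HallmarkCall:
    orf_id: str
    hallmark: str
    profile_score: float
    profile_coverage: float
    complete_cds: bool


# ---------------------------------------------------------------------------
# contig merging


def merge_contigs(
    contigs: Sequence[Contig], best_hits: dict[str, AlignmentHit], spacer: int = 10
) -> list[Contig]:
    """Join non-overlapping contigs that hit the same subject, in subject order.

    Contigs whose best viral hits target the same subject with
    non-overlapping, order-consistent subject spans are concatenated in
    subject-coordinate order with a ``spacer``-N spacer; each contig is first
    oriented by its hit's frame sign so all joined pieces read forward along
    the subject. Groups whose spans overlap (orientation or order cannot be
    reconciled) are left unmerged with a warning.
    """
    import logging

    by_subject: dict[str, list[Contig]] = {}
    for c in contigs:
        h = best_hits.get(c.id)
        if h is not None and not h.subject_id.startswith("profile:"):
            by_subject.setdefault(h.subject_id, []).append(c)
    merged: list[Contig] = []
    consumed: set[str] = set()
    n = 0
    for subject in sorted(by_subject):
        group = by_subject[subject]
        if len(group) < 2:
            continue
        group = sorted(group, key=lambda c: best_hits[c.id].subject_span[0])
        spans = [best_hits[c.id].subject_span for c in group]
        ok = all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))
        if not ok:
            logging.getLogger(__name__).debug(
                "overlapping subject spans for %s; not merged", subject
            )
            continue
        n += 1
        seqs = [c.sequence if best_hits[c.id].frame >= 0 else reverse_complement(c.sequence) for c in group]
        merged.append(
            Contig(
                id=f"merged_{n:04d}",
                sequence=("N" * spacer).join(seqs),
                library=group[0].library,
                member_reads=sorted(set(sum((c.member_reads for c in group), []))),
            )
        )
        consumed.update(c.id for c in group)
    out = [c for c in contigs if c.id not in consumed]
    return out + merged


# ---------------------------------------------------------------------------
# read mapping (31-mer anchored, edlib-verified)


def map_reads(
    reads: Sequence[Read],
    references: Sequence[Contig],
    min_seed: int = 31,
    min_identity: float = 0.95,
    min_aligned_frac: float = 0.90,
) -> tuple[dict[str, int], dict[str, np.ndarray], dict[str, str]]:
    """Map reads to references; each read counts once, to its best reference.

    A read is anchored to candidate references by exact ``min_seed``-mer
    match (either strand), then verified by infix alignment (edlib): the
    read maps when at least ``min_aligned_frac`` of its bases align at
    >= ``min_identity`` identity, tested on the full read and on the read
    with up to 10% trimmed from either end. Ties go to the first reference
    in input order. Returns (per-reference mapped counts, per-reference
    coverage vectors, read -> reference assignment).
    """
    import edlib

    index: dict[str, list[int]] = {}
    for ri, ref in enumerate(references):
        s = ref.sequence
        for p in range(0, max(0, len(s) - min_seed + 1)):
            index.setdefault(s[p : p + min_seed], []).append(ri)

    counts = {r.id: 0 for r in references}
    coverage = {r.id: np.zeros(len(r.sequence), dtype=np.int64) for r in references}
    assignment: dict[str, str] = {}
    ref_order = {r.id: i for i, r in enumerate(references)}

    for read in reads:
        cands: set[int] = set()
        for seq in (read.sequence, reverse_complement(read.sequence)):
            for p in range(0, max(0, len(seq) - min_seed + 1), min_seed):
                cands.update(index.get(seq[p : p + min_seed], ()))
        if not cands:
            continue
        # key: (distance fraction, -aligned bases, input order); longer
        # alignments win identity ties, earlier references win exact ties
        best: Optional[tuple[float, int, int, int, tuple[int, int]]] = None
        for ri in sorted(cands):
            ref = references[ri]
            for seq in (read.sequence, reverse_complement(read.sequence)):
                for trim in (0.0, 0.10):
                    t = int(len(seq) * trim)
                    for sub in ([seq] if t == 0 else [seq[t:], seq[:-t]]):
                        k = int(np.floor((1 - min_identity) * len(sub)))
                        res = edlib.align(sub, ref.sequence, mode="HW", task="locations", k=k)
                        if res["editDistance"] < 0:
                            continue
                        if len(sub) < min_aligned_frac * len(read.sequence):
                            continue
                        frac = res["editDistance"] / len(sub)
                        loc = res["locations"][0]
                        cand = (frac, -len(sub), ref_order[ref.id], ri, (loc[0], loc[1] + 1))
                        if best is None or cand < best:
                            best = cand
        if best is not None:
            ri = best[3]
            ref = references[ri]
            counts[ref.id] += 1
            a, b = best[4]
            coverage[ref.id][a:b] += 1
            assignment[read.id] = ref.id
    return counts, coverage, assignment


# ---------------------------------------------------------------------------
# ORF prediction


def predict_orfs(contig: Contig, min_size: int = 300) -> list[ORF]:
    """Predict ATG-initiated ORFs (standard code) of >= ``min_size`` nt.

    The length includes the stop codon. In each of the six frames, each
    stop-to-stop segment contributes at most one ORF, from its first ATG
    (nested later starts are suppressed). ORFs running off the contig's end
    without a stop are reported with ``has_stop=False`` (their length is the
    ATG-to-edge span, codon-truncated).
    """
    seq = contig.sequence.upper()
    L = len(seq)
    orfs: list[ORF] = []
    n = 0
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(3):
            frame = off + 1 if strand == "+" else -(off + 1)
            first_atg: Optional[int] = None  # codon-start position in s
            p = off
            while p + 3 <= len(s):
                codon = s[p : p + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if first_atg is not None:
                        nt_len = p + 3 - first_atg
                        if nt_len >= min_size:
                            n += 1
                            orfs.append(
                                _make_orf(contig, s, strand, frame, first_atg, p + 3, True, n)
                            )
                    first_atg = None
                elif codon == "ATG" and first_atg is None:
                    first_atg = p
                p += 3
            if first_atg is not None:
                end = off + 3 * ((len(s) - off) // 3)
                if end - first_atg >= min_size:
                    n += 1
                    orfs.append(_make_orf(contig, s, strand, frame, first_atg, end, False, n))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    for i, o in enumerate(orfs, 1):
        o.id = f"{contig.id}_orf{i:03d}"
    return orfs


def _make_orf(contig: Contig, s: str, strand: str, frame: int, a: int, b: int, has_stop: bool, n: int) -> ORF:
    from Bio.Seq import Seq

    nt = s[a:b]
    aa = str(Seq(nt).translate())
    if has_stop and aa.endswith("*"):
        aa = aa[:-1]
    if strand == "+":
        start, end = a, b
    else:
        start, end = len(s) - b, len(s) - a
    return ORF(
        id=f"{contig.id}_tmp{n}",
        contig_id=contig.id,
        frame=frame,
        start=start,
        end=end,
        strand=strand,
        aa_sequence=aa,
        has_start=True,
        has_stop=has_stop,
    )


# ---------------------------------------------------------------------------
# hallmark calls


def call_hallmarks(
    orfs: Sequence[ORF],
    profiles: Sequence[ProfileMatrix],
    min_coverage: float = 0.5,
    complete_coverage: float = 0.9,
) -> list[HallmarkCall]:
    """Scan ORFs against the hallmark profiles; best qualifying profile wins.

    A call requires the placement score to reach the profile's calibrated
    threshold pro-rated by coverage. ``complete_cds`` additionally requires
    the ORF to have both start and stop and profile coverage >= 0.9.
    """
    calls = []
    for orf in orfs:
        best: Optional[tuple[float, float, str]] = None
        for prof in profiles:
            score, cov, _ = scan_profile(prof, orf.aa_sequence, min_coverage)
            if cov <= 0 or score < prof.score_threshold * cov:
                continue
            if best is None or score > best[0]:
                best = (score, cov, prof.name)
        if best is not None:
            score, cov, name = best
            calls.append(
                HallmarkCall(
                    orf_id=orf.id,
                    hallmark=name,
                    profile_score=score,
                    profile_coverage=cov,
                    complete_cds=bool(orf.has_start and orf.has_stop and cov >= complete_coverage),
                )
            )
    return calls


def orfs_to_tsv(orfs: Sequence[ORF], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "orf": o.id, "contig": o.contig_id, "start": o.start, "end": o.end,
                "strand": o.strand, "frame": o.frame, "has_start": o.has_start,
                "has_stop": o.has_stop, "aa_length": len(o.aa_sequence),
            }
            for o in orfs
        ]
    ).to_csv(path, sep="\t", index=False)
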