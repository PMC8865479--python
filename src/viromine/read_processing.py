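"""Cleaning of raw sequencing reads.

Four steps, run in order per library: positional deduplication (reads whose
bases 5-55 are identical collapse to one randomly chosen survivor), 3' quality
trimming at a Phred threshold, adapter trimming with an ungapped local scan,
and a minimum-length filter.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "Read",
    "CleaningReport",
    "deduplicate",
    "trim_quality",
    "trim_adapters",
    "length_filter",
    "clean_library",
    "read_fastq",
    "write_fastq",
]

# 1-based inclusive window used for duplicate detection.
DEDUP_WINDOW = (5, 55)


@dataclass
class Read:
    """One sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int]
    library: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CleaningReport:
    """Per-library accounting of what cleaning removed."""

    library: str = ""
    input: int = 0
    duplicates_removed: int = 0
    bases_trimmed_quality: int = 0
    reads_adapter_trimmed: int = 0
    reads_dropped_short: int = 0
    output: int = 0

    def check(self) -> None:
        if self.input - self.duplicates_removed - self.reads_dropped_short != self.output:
            raise AssertionError("cleaning report counts do not reconcile")


def _dedup_key(seq: str) -> str:
    """Duplicate key: 1-based inclusive positions 5-55 (51 nt).

    Reads shorter than 55 nt are keyed on whatever exists from position 5 on,
    which groups conservatively instead of crashing.
    """
    lo, hi = DEDUP_WINDOW
    return seq[lo - 1 : hi]


def deduplicate(reads: Sequence[Read], seed: int) -> tuple[list[Read], CleaningReport]:
    """Collapse positional duplicates, keeping one random survivor per group.

    Groups are formed by transitive identity of the bases 5-55 key; the
    survivor is drawn uniformly with ``seed``. Output order is stable by the
    first occurrence of each group.
    """
    rng = random.Random(seed)
    groups: dict[str, list[Read]] = {}
    order: list[str] = []
    for r in reads:
        k = _dedup_key(r.sequence)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(r)
    survivors = [rng.choice(groups[k]) for k in order]
    report = CleaningReport(
        input=len(reads),
        duplicates_removed=len(reads) - len(survivors),
        output=len(survivors),
    )
    return survivors, report


def trim_quality(read: Read, threshold: int = 10) -> Read:
    """Trim the 3' tail that maximises the suffix sum of (threshold - q).

    The standard BWA-style rule: cut at the position whose suffix score
    sum(threshold - q_i) is maximal and positive; if no suffix scores
    positive the read is returned unchanged; ties resolve toward the
    shorter trim. An all-low-quality read trims to length zero (caller
    drops it via the length filter).
    """
    best_score = 0
    best_cut = len(read)
    score = 0
    for i in range(len(read) - 1, -1, -1):
        score += threshold - read.qualities[i]
        if score > best_score:
            best_score = score
            best_cut = i
    if best_cut == len(read):
        return read
    return replace(read, sequence=read.sequence[:best_cut], qualities=read.qualities[:best_cut])


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _best_adapter_match(seq: str, adapter: str) -> tuple[int, int, int]:
    """Best ungapped local match of ``adapter`` in ``seq`` (either strand).

    Scoring +1 per match, -3 per mismatch, no gaps: for every diagonal
    offset the best-scoring contiguous segment is found (vectorised Kadane
    via running minima of prefix sums). Returns (score, start, end) of the
    matched span on the read, half-open.
    """
    import numpy as np

    n, m = len(seq), len(adapter)
    if n == 0 or m == 0:
        return (0, 0, 0)
    s_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    best = (0, 0, 0)
    for adap in (adapter, reverse_complement(adapter)):
        a_arr = np.frombuffer(adap.encode(), dtype=np.uint8)
        # pad the read so every offset is a full-width comparison; padded
        # positions never match (0 is not a base)
        pad = np.zeros(n + 2 * (m - 1) + 2, dtype=np.uint8)
        pad[m - 1 : m - 1 + n] = s_arr
        win = np.lib.stride_tricks.sliding_window_view(pad, m)[: n + m - 1]
        scores = np.where(win == a_arr[None, :], 1, -3)
        scores[win == 0] = 0  # outside the read: no contribution
        prefix = np.cumsum(scores, axis=1)
        runmin = np.minimum.accumulate(np.hstack([np.zeros((prefix.shape[0], 1)), prefix]), axis=1)
        seg = prefix - runmin[:, :-1]
        row_best = seg.max(axis=1)
        r = int(np.argmax(row_best))
        if row_best[r] > best[0]:
            jend = int(np.argmax(seg[r]))  # inclusive end within adapter coords
            jstart = int(np.argmin(np.hstack([[0.0], prefix[r]])[: jend + 1]))
            off = r - (m - 1)  # read position of adapter's first column
            start = max(0, off + jstart)
            end = min(n, off + jend + 1)
            best = (int(row_best[r]), start, end)
    return best


def trim_adapters(read: Read, adapters: Sequence[str], min_match: int = 16) -> Read:
    """Remove or mask adapter carry-over.

    The highest-scoring ungapped local match of any adapter (either strand)
    with score >= ``min_match`` is acted on: a match lying in the 3' half
    truncates the read at the match start; a match elsewhere is masked with N.
    """
    best = (0, 0, 0)
    for a in adapters:
        cand = _best_adapter_match(read.sequence, a)
        if cand[0] > best[0]:
            best = cand
    score, start, end = best
    if score < min_match:
        return read
    if start >= len(read) // 2:
        return replace(read, sequence=read.sequence[:start], qualities=read.qualities[:start])
    masked = read.sequence[:start] + "N" * (end - start) + read.sequence[end:]
    return replace(read, sequence=masked)


def length_filter(reads: Iterable[Read], min_len: int = 50) -> list[Read]:
    """Drop reads shorter than ``min_len`` (boundary inclusive: 50 nt is kept)."""
    return [r for r in reads if len(r) >= min_len]


def clean_library(
    reads: Sequence[Read],
    seed: int,
    phred_threshold: int = 10,
    adapters: Sequence[str] = (),
    min_match: int = 16,
    min_len: int = 50,
) -> tuple[list[Read], CleaningReport]:
    """Full cleaning pass: dedup -> quality trim -> adapter trim -> length filter."""
    survivors, report = deduplicate(reads, seed)
    report.library = reads[0].library if reads else ""
    out: list[Read] = []
    for r in survivors:
        t = trim_quality(r, phred_threshold)
        report.bases_trimmed_quality += len(r) - len(t)
        if adapters:
            a = trim_adapters(t, adapters, min_match)
            if len(a) != len(t) or a.sequence != t.sequence:
                report.reads_adapter_trimmed += 1
            t = a
        out.append(t)
    kept = length_filter(out, min_len)
    report.reads_dropped_short = len(out) - len(kept)
    report.output = len(kept)
    report.check()
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33) via Biopython


def write_fastq(reads: Iterable[Read], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    write(records, str(path), "fastq")


def read_fastq(path, library: str = "") -> list[Read]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
                library=library,
            )
        )
    return out
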