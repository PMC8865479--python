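"""Phage functional-gene and ARG profiling.

Restricts to sequences classified as bacteriophage, annotates their
predicted ORFs against the ARG and functional catalogues (BLASTp-style,
E < 1e-5), quantifies each gene by mapping reads back to its ORF, and
normalises to ppm (per million library reads) and FPKM (additionally per
kilobase of coding sequence). Aggregations by drug class, resistance
mechanism, or functional category, and group-exclusive / core gene calls
complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import ORF, map_reads
from .assembly import Contig
from .homology_triage import AlignmentHit, ProteinSearcher, TaxonomyAssignment
from .read_processing import Read
from .synthetic_data import PHAGE_FAMILIES

__all__ = [
    "GeneAbundance",
    "select_phage_sequences",
    "annotate_genes",
    "quantify",
    "aggregate",
    "exclusive_genes",
]


@dataclass
class GeneAbundance:
    gene: str
    library: str
    read_hits: int
    ppm: float
    fpkm: float
    drug_class: str = ""
    mechanism: str = ""
    category: str = ""


def select_phage_sequences(
    assignments: Sequence[TaxonomyAssignment], phage_families: frozenset = frozenset(PHAGE_FAMILIES)
) -> set[str]:
    """Ids of contigs/singlets whose surviving lineage is a bacteriophage."""
    return {a.query_id for a in assignments if a.family in phage_families}


def annotate_genes(
    orfs: Sequence[ORF], searcher: ProteinSearcher, e_cutoff: float = 1e-5
) -> dict[str, AlignmentHit]:
    """Best catalogue hit per ORF at E < cutoff (protein-protein search)."""
    res = searcher.batch_search_protein([(o.id, o.aa_sequence) for o in orfs], e_cutoff)
    return {oid: hits[0] for oid, hits in res.items() if hits}


def quantify(
    gene_calls: Mapping[str, AlignmentHit],
    orfs: Sequence[ORF],
    reads_by_library: Mapping[str, Sequence[Read]],
    library_sizes: Mapping[str, int],
    orf_sequences: Mapping[str, str],
    gene_metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> list[GeneAbundance]:
    """Per-gene, per-library abundances from read-to-ORF mapping.

    ``read_hits`` counts reads whose best mapping is to an ORF annotated as
    the gene (each read counted once); ppm = hits * 1e6 / N and
    fpkm = hits * 1e9 / (L_nt * N), with N the library's raw read count and
    L_nt the ORF's coding length.
    """
    called_orfs = [o for o in orfs if o.id in gene_calls]
    if not called_orfs:
        return []
    refs = [
        Contig(id=o.id, sequence=orf_sequences[o.id], library="", member_reads=[o.id])
        for o in called_orfs
    ]
    gene_of = {o.id: gene_calls[o.id].subject_id for o in called_orfs}
    gene_metadata = gene_metadata or {}
    length_of = {o.id: o.nt_length for o in called_orfs}
    out: list[GeneAbundance] = []
    for lib, reads in reads_by_library.items():
        N = library_sizes[lib]
        if N == 0:
            raise ValueError(f"library {lib}: zero library size")
        counts, _, _ = map_reads(list(reads), refs)
        per_gene: dict[str, dict] = {}
        for oid, c in counts.items():
            g = gene_of[oid]
            rec = per_gene.setdefault(g, {"hits": 0, "len": 0, "oid": oid})
            rec["hits"] += c
            rec["len"] = max(rec["len"], length_of[oid])
        for g, rec in sorted(per_gene.items()):
            md = dict(gene_metadata.get(g, {}))
            out.append(
                GeneAbundance(
                    gene=g,
                    library=lib,
                    read_hits=rec["hits"],
                    ppm=rec["hits"] * 1e6 / N,
                    fpkm=rec["hits"] * 1e9 / (rec["len"] * N),
                    drug_class=md.get("drug_class", ""),
                    mechanism=md.get("mechanism", ""),
                    category=md.get("category", ""),
                )
            )
    return out


def abundances_to_frame(abundances: Sequence[GeneAbundance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": a.gene, "library": a.library, "read_hits": a.read_hits,
                "ppm": a.ppm, "fpkm": a.fpkm, "drug_class": a.drug_class,
                "mechanism": a.mechanism, "category": a.category,
            }
            for a in abundances
        ]
    )


def aggregate(abundances: Sequence[GeneAbundance], by: str = "drug_class") -> pd.DataFrame:
    """Per-library class totals (ppm) and within-library proportions.

    ``by`` is one of drug_class, mechanism, category. Returns a tidy frame
    with columns library, <by>, ppm, proportion; proportions sum to 1 per
    library whenever any class is nonzero.
    """
    if by not in ("drug_class", "mechanism", "category"):
        raise ValueError(f"cannot aggregate by {by!r}")
    df = abundances_to_frame(abundances)
    if df.empty:
        return pd.DataFrame(columns=["library", by, "ppm", "proportion"])
    g = df.groupby(["library", by], as_index=False)["ppm"].sum()
    totals = g.groupby("library")["ppm"].transform("sum")
    g["proportion"] = np.where(totals > 0, g["ppm"] / totals, 0.0)
    return g


def exclusive_genes(
    abundances: Sequence[GeneAbundance], group_labels: Mapping[str, str]
) -> tuple[dict[str, set], set]:
    """Group-exclusive and core genes from per-library abundances.

    A gene is exclusive to group G when it has ppm > 0 in at least one
    G-library and ppm = 0 (or absent) everywhere else; a gene is core when
    present (ppm > 0) in every library of ``group_labels``.
    """
    libs = sorted(group_labels)
    if len(set(group_labels.values())) < 2:
        raise ValueError("need at least two groups")
    present: dict[str, set] = {}
    for a in abundances:
        if a.ppm > 0 and a.library in group_labels:
            present.setdefault(a.gene, set()).add(a.library)
    exclusives: dict[str, set] = {}
    for grp in sorted(set(group_labels.values())):
        glibs = {l for l in libs if group_labels[l] == grp}
        exclusives[grp] = {g for g, s in present.items() if s and s <= glibs}
    core = {g for g, s in present.items() if s == set(libs)}
    return exclusives, core
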