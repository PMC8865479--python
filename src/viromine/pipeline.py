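"""End-to-end orchestration: simulate -> clean -> assemble -> triage ->
ecology -> annotate -> phylogenetics -> quantify, with one global seed
fanned out to per-stage seeds and a JSON run report reconciling counts."""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import annotation, assembly, ecology, homology_triage as ht, phylogenetics as phylo
from . import quantification as quant
from . import read_processing as rp
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "PipelineResult", "stage_seed", "run_pipeline"]

log = logging.getLogger("viromine")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "viromine_run"
    reads_per_library: int = 2000
    phred_threshold: int = 10
    min_len: int = 50
    min_overlap: int = 35
    min_identity: float = 0.98
    e_cutoff: float = 1e-5
    min_orf: int = 300
    max_gap_fraction: float = 0.5
    n_permutations: int = 999
    nvnr_mode: str = "best_score"
    run_assembly: bool = True
    run_phylogenetics: bool = True
    run_quantification: bool = True
    sim: Optional[sd.SimConfig] = None

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = sd.SimConfig(
                seed=stage_seed(self.seed, "simulate"),
                reads_per_library=self.reads_per_library,
            )


@dataclass
class PipelineResult:
    report: dict
    assignments: list
    family_matrix: pd.DataFrame
    species_matrix: pd.DataFrame
    manifest: sd.GroundTruthManifest
    cleaned: dict
    contigs: dict
    abundances: list = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # -- simulate ----------------------------------------------------------
    genomes = sd.generate_genomes(config.sim)
    dbs = sd.build_databases(genomes, seed=stage_seed(config.seed, "databases"))
    libraries, manifest = sd.simulate_reads(genomes, config.sim)
    report["stages"]["simulate"] = {
        "genomes": len(genomes),
        "libraries": {k: len(v) for k, v in libraries.items()},
        "viral_db": len(dbs["viral_db"]),
        "nvnr_db": len(dbs["nvnr_db"]),
    }
    sd.write_genomes_fasta(genomes, os.path.join(config.out_dir, "genomes.fasta"))
    manifest.to_json(os.path.join(config.out_dir, "manifest.json"))

    # -- clean -------------------------------------------------------------
    cleaned: dict[str, list[rp.Read]] = {}
    clean_reports = {}
    for lib, reads in sorted(libraries.items()):
        out, rep = rp.clean_library(
            reads,
            seed=stage_seed(config.seed, f"dedup:{lib}"),
            phred_threshold=config.phred_threshold,
            adapters=[config.sim.adapter_seq] if config.sim.adapter_seq else [],
            min_len=config.min_len,
        )
        cleaned[lib] = out
        clean_reports[lib] = rep
    report["stages"]["clean"] = {
        lib: {
            "input": r.input,
            "duplicates_removed": r.duplicates_removed,
            "reads_dropped_short": r.reads_dropped_short,
            "output": r.output,
        }
        for lib, r in clean_reports.items()
    }

    # -- assemble ----------------------------------------------------------
    contigs: dict[str, list[assembly.Contig]] = {}
    for lib, reads in sorted(cleaned.items()):
        if config.run_assembly:
            contigs[lib] = assembly.greedy_assemble(reads, config.min_overlap, config.min_identity)
        else:
            contigs[lib] = [
                assembly.Contig(id=r.id, sequence=r.sequence, library=lib, member_reads=[r.id], is_singlet=True)
                for r in reads
            ]
    report["stages"]["assemble"] = {
        lib: {
            "contigs": sum(1 for c in cs if not c.is_singlet),
            "singlets": sum(1 for c in cs if c.is_singlet),
        }
        for lib, cs in contigs.items()
    }

    # -- triage ------------------------------------------------------------
    viral_searcher = ht.ProteinSearcher(dbs["viral_db"])
    nvnr_searcher = ht.ProteinSearcher(dbs["nvnr_db"])
    items = [
        ht.QueryItem(
            id=c.id,
            sequence=c.sequence,
            library=lib,
            n_reads=len(c.member_reads),
            is_contig=not c.is_singlet,
        )
        for lib, cs in sorted(contigs.items())
        for c in cs
    ]
    assignments, best_hits, removed = ht.triage_queries(
        items, viral_searcher, nvnr_searcher, dbs["profiles"], config.e_cutoff, config.nvnr_mode
    )
    # chimera flags need per-contig hits; use best hits per contig
    for lib, cs in contigs.items():
        assembly.flag_chimeras(cs, {k: [v] for k, v in best_hits.items()}, config.e_cutoff)
    report["stages"]["triage"] = {
        "queries": len(items),
        "assigned": len(assignments),
        "nvnr_removed": len(removed),
        "profile_fallback": sum(1 for a in assignments if a.route == "profile_fallback"),
        "control_viral_assignments": sum(1 for a in assignments if a.library == "control"),
    }

    # -- ecology -----------------------------------------------------------
    eco_assign = [a for a in assignments if a.library != "control"]
    fam = ht.tabulate(eco_assign, level="family")
    spec_m = ht.tabulate(eco_assign, level="species")
    eco_report: dict = {}
    if not fam.empty and fam.shape[0] >= 3:
        dm = ecology.bray_curtis(fam)
        tree = ecology.upgma(dm)
        coords, eigvals = ecology.pcoa(dm)
        groups = {lib: config.sim.group_labels.get(lib, "NA") for lib in fam.index}
        anores = None
        counts = pd.Series(list(groups.values())).value_counts()
        if len(counts) >= 2 and (counts >= 2).all():
            anores = ecology.anosim(
                dm, groups, n_perm=config.n_permutations, seed=stage_seed(config.seed, "anosim")
            )
        sets = ecology.shared_sets(spec_m, group_labels=groups)
        with open(os.path.join(config.out_dir, "upgma.nwk"), "w") as fh:
            fh.write(tree + "\n")
        coords.to_csv(os.path.join(config.out_dir, "pcoa_coordinates.tsv"), sep="\t")
        fam.to_csv(os.path.join(config.out_dir, "family_counts.tsv"), sep="\t")
        spec_m.to_csv(os.path.join(config.out_dir, "species_counts.tsv"), sep="\t")
        eco_report = {
            "anosim_R": None if anores is None else anores.R,
            "anosim_p": None if anores is None else anores.p_value,
            "core_species": len(sets.core),
            "exclusive_species": {g: len(s) for g, s in sets.exclusives.items()},
        }
    report["stages"]["ecology"] = eco_report

    # -- annotation + phylogenetics ---------------------------------------
    assigned_ids = {a.query_id for a in assignments}
    viral_contigs = [c for cs in contigs.values() for c in cs if c.id in assigned_ids]
    merged = annotation.merge_contigs(viral_contigs, best_hits)
    orfs = [o for c in merged for o in annotation.predict_orfs(c, config.min_orf)]
    calls = annotation.call_hallmarks(orfs, dbs["profiles"])
    complete = [c for c in calls if c.complete_cds]
    report["stages"]["annotate"] = {
        "viral_contigs": len(viral_contigs),
        "orfs": len(orfs),
        "hallmark_calls": len(calls),
        "complete_cds": len(complete),
    }
    if config.run_phylogenetics:
        orf_by_id = {o.id: o for o in orfs}
        trees = {}
        for hallmark in sorted({c.hallmark for c in complete}):
            seqs = {
                c.orf_id: orf_by_id[c.orf_id].aa_sequence
                for c in complete
                if c.hallmark == hallmark
            }
            if len(seqs) < 3:
                continue
            msa = phylo.progressive_align(seqs)
            msa = phylo.filter_gap_columns(msa, config.max_gap_fraction)
            dmat = phylo.protein_distance(msa)
            trees[hallmark] = phylo.nj_tree(dmat)
            with open(os.path.join(config.out_dir, f"tree_{hallmark}.nwk"), "w") as fh:
                fh.write(trees[hallmark] + "\n")
        report["stages"]["phylogenetics"] = {"trees": sorted(trees)}

    # -- quantification ----------------------------------------------------
    abundances: list[quant.GeneAbundance] = []
    if config.run_quantification and dbs["arg_db"]:
        phage_ids = quant.select_phage_sequences(assignments)
        phage_contigs = [c for c in merged if set(c.member_reads) and c.id in phage_ids]
        # merged contigs may have new ids; also accept merged contigs built
        # from phage members
        phage_contigs = [c for c in merged if c.id in phage_ids] or [
            c for cs in contigs.values() for c in cs if c.id in phage_ids
        ]
        phage_orfs = [o for c in phage_contigs for o in annotation.predict_orfs(c, config.min_orf)]
        arg_searcher = ht.ProteinSearcher(dbs["arg_db"])
        arg_calls = quant.annotate_genes(phage_orfs, arg_searcher, config.e_cutoff)
        orf_seqs = {}
        contig_by_id = {c.id: c for c in phage_contigs}
        for o in phage_orfs:
            c = contig_by_id[o.contig_id]
            orf_seqs[o.id] = (
                c.sequence[o.start : o.end]
                if o.strand == "+"
                else rp.reverse_complement(c.sequence[o.start : o.end])
            )
        raw_sizes = {lib: len(reads) for lib, reads in libraries.items() if lib != "control"}
        reads_by_lib = {lib: cleaned[lib] for lib in raw_sizes}
        meta = {e.id: e.metadata for e in dbs["arg_db"]}
        abundances = quant.quantify(arg_calls, phage_orfs, reads_by_lib, raw_sizes, orf_seqs, meta)
        if abundances:
            quant.abundances_to_frame(abundances).to_csv(
                os.path.join(config.out_dir, "arg_abundance.tsv"), sep="\t", index=False
            )
            classes = quant.aggregate(abundances, by="drug_class")
            classes.to_csv(os.path.join(config.out_dir, "arg_drug_classes.tsv"), sep="\t", index=False)
            mech = quant.aggregate(abundances, by="mechanism")
            mech.to_csv(os.path.join(config.out_dir, "arg_mechanisms.tsv"), sep="\t", index=False)
            exclusives, core = quant.exclusive_genes(
                abundances, {l: g for l, g in config.sim.group_labels.items() if l in raw_sizes}
            )
            report["stages"]["quantify"] = {
                "arg_genes": sorted({a.gene for a in abundances}),
                "exclusive": {g: sorted(s) for g, s in exclusives.items()},
                "core": sorted(core),
            }

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return PipelineResult(
        report=report,
        assignments=assignments,
        family_matrix=fam,
        species_matrix=spec_m,
        manifest=manifest,
        cleaned=cleaned,
        contigs=contigs,
        abundances=abundances,
    )
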