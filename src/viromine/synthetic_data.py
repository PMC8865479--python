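"""Synthetic gut-virome community generator with known ground truth.

Emulates a pooled fecal virome sequencing study of two lizard species
(PE = *Phrynocephalus erythrurus*, PT = *P. theobaldi*) sampled at five
plateau sites: six libraries of 250-bp paired-end reads drawn from a mix of
phage, eukaryotic-virus, CRESS, bacterial, and host genomes, plus a blank
control, with PCR duplicates, 3' adapter carry-over, and positional quality
decay. Every read's true origin is recorded in a manifest so downstream
stages can be scored against ground truth.

The generator also builds the mock reference resources the discovery
pipeline needs: a viral proteome database, a non-virus non-redundant (NVNR)
decoy database, an antibiotic-resistance-gene (ARG) catalogue with
drug-class/mechanism metadata, a functional-gene catalogue, and
position-specific score matrices for the five virus hallmark genes
(TerL, MCP, Rep, NS1, RdRp).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .read_processing import Read, reverse_complement

__all__ = [
    "GenomeRecord",
    "GeneFeature",
    "SimConfig",
    "GroundTruthManifest",
    "ProteinDBEntry",
    "ProfileMatrix",
    "LINEAGES",
    "ARG_CATALOGUE",
    "HALLMARK_BY_CATEGORY",
    "PHAGE_FAMILIES",
    "generate_genomes",
    "build_databases",
    "simulate_reads",
    "mutate_protein",
    "random_protein",
    "back_translate",
    "default_config",
    "arg_study_config",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# family label -> (realm, order, category). The lineage table downstream
# modules consult; "unclassified Caudovirales" is the label profile-fallback
# assignments receive when only the hallmark (not the family) is known.
LINEAGES: dict[str, dict[str, str]] = {
    "Siphoviridae": {"realm": "Duplodnaviria", "order": "Caudovirales", "category": "phage_dsDNA"},
    "Myoviridae": {"realm": "Duplodnaviria", "order": "Caudovirales", "category": "phage_dsDNA"},
    "Podoviridae": {"realm": "Duplodnaviria", "order": "Caudovirales", "category": "phage_dsDNA"},
    "unclassified Caudovirales": {
        "realm": "Duplodnaviria",
        "order": "Caudovirales",
        "category": "phage_dsDNA",
    },
    "Microviridae": {"realm": "Monodnaviria", "order": "Petitvirales", "category": "phage_ssDNA"},
    "Parvoviridae": {"realm": "Monodnaviria", "order": "Piccovirales", "category": "euk_virus_DNA"},
    "Circoviridae": {"realm": "Monodnaviria", "order": "Cirlivirales", "category": "cress"},
    "Smacoviridae": {"realm": "Monodnaviria", "order": "Cremevirales", "category": "cress"},
    "Astroviridae": {"realm": "Riboviria", "order": "Stellavirales", "category": "euk_virus_RNA"},
    "Caliciviridae": {"realm": "Riboviria", "order": "Picornavirales", "category": "euk_virus_RNA"},
    "bacterial": {"realm": "Bacteria", "order": "Bacteria", "category": "bacterial"},
    "host": {"realm": "Eukaryota", "order": "Squamata", "category": "host"},
}

HALLMARK_BY_CATEGORY = {
    "phage_dsDNA": "TerL",
    "phage_ssDNA": "MCP",
    "cress": "Rep",
    "euk_virus_DNA": "NS1",
    "euk_virus_RNA": "RdRp",
}

# hallmark -> group label used when only the profile identifies a sequence
HALLMARK_GROUP_LABEL = {
    "TerL": "unclassified Caudovirales",
    "MCP": "Microviridae",
    "Rep": "Circoviridae",
    "NS1": "Parvoviridae",
    "RdRp": "Astroviridae",
}

PHAGE_FAMILIES = {"Siphoviridae", "Myoviridae", "Podoviridae", "unclassified Caudovirales", "Microviridae"}

# Mock ARG catalogue: gene -> (drug class, resistance mechanism). Names and
# class/mechanism pairings follow the CARD conventions for these genes.
ARG_CATALOGUE: dict[str, dict[str, str]] = {
    "cmeB": {"drug_class": "multidrug", "mechanism": "antibiotic efflux"},
    "cmeA": {"drug_class": "multidrug", "mechanism": "antibiotic efflux"},
    "oprM": {"drug_class": "multidrug", "mechanism": "antibiotic efflux"},
    "macB": {"drug_class": "macrolide", "mechanism": "antibiotic efflux"},
    "floR": {"drug_class": "phenicol", "mechanism": "antibiotic efflux"},
    "arnA": {"drug_class": "peptide", "mechanism": "antibiotic target alteration"},
    "ugd": {"drug_class": "peptide", "mechanism": "antibiotic target alteration"},
    "ileS": {"drug_class": "mupirocin", "mechanism": "antibiotic target alteration"},
    "tet36": {"drug_class": "tetracycline", "mechanism": "antibiotic target protection"},
    "dfrE": {"drug_class": "diaminopyrimidine", "mechanism": "antibiotic target replacement"},
    "vanA": {"drug_class": "glycopeptide", "mechanism": "antibiotic target alteration"},
    "tetW": {"drug_class": "tetracycline", "mechanism": "antibiotic target protection"},
    "ermB": {"drug_class": "macrolide", "mechanism": "antibiotic target alteration"},
}

FUNCTION_CATEGORIES = [
    ("Metabolism", "Energy metabolism"),
    ("Metabolism", "Carbohydrate metabolism"),
    ("Metabolism", "Amino acid metabolism"),
    ("Genetic Information Processing", "Replication and repair"),
    ("Cellular Processes", "Prokaryote cellular community"),
]

LIBRARIES = ["PE-NMC", "PE-NQ", "PT-NQ", "PT-SZZ", "PT-ZB", "PT-RT"]
GROUP_LABELS = {"PE-NMC": "PE", "PE-NQ": "PE", "PT-NQ": "PT", "PT-SZZ": "PT", "PT-ZB": "PT", "PT-RT": "PT"}


@dataclass
class GeneFeature:
    """A gene placed on a synthetic genome (forward strand, 0-based half-open)."""

    gene_id: str
    name: str
    role: str  # hallmark | cds | arg | function
    start: int
    end: int
    strand: str
    protein: str
    metadata: dict = field(default_factory=dict)


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    category: str
    family_label: str
    species_label: str
    features: list[GeneFeature] = field(default_factory=list)


@dataclass
class ProteinDBEntry:
    id: str
    aa_sequence: str
    source_genome: str
    lineage: tuple[str, str, str, str]  # realm, order, family, species
    db_role: str  # viral | nvnr | arg | function
    metadata: dict = field(default_factory=dict)


@dataclass
class ProfileMatrix:
    """Additive position-specific score matrix (log-odds vs uniform background)."""

    name: str
    scores: np.ndarray  # (length, 20) over AA20 order
    score_threshold: float

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class GroundTruthManifest:
    """Per-read true origin plus per-library and per-gene truth."""

    per_read: dict[str, dict] = field(default_factory=dict)
    per_library: dict[str, dict[str, int]] = field(default_factory=dict)
    per_gene: dict[str, list[dict]] = field(default_factory=dict)

    def viral_read_ids(self, viral_categories=frozenset(HALLMARK_BY_CATEGORY)) -> set[str]:
        return {
            rid
            for rid, rec in self.per_read.items()
            if LINEAGES[rec["family"]]["category"] in viral_categories
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"per_read": self.per_read, "per_library": self.per_library, "per_gene": self.per_gene},
                fh,
                indent=0,
            )


# default per-library family composition: phage-dominated communities over a
# bacterial/host background, with the PE-NMC (lake-site) library
# parvovirus-rich, qualitatively mirroring a lake-shore insect-prey diet.
_BASE_COMPOSITION = {
    "Siphoviridae": 0.18,
    "Myoviridae": 0.12,
    "Podoviridae": 0.06,
    "Microviridae": 0.07,
    "Parvoviridae": 0.05,
    "Circoviridae": 0.03,
    "Astroviridae": 0.06,
    "bacterial": 0.36,
    "host": 0.07,
}

_NMC_COMPOSITION = {
    "Siphoviridae": 0.14,
    "Myoviridae": 0.09,
    "Podoviridae": 0.05,
    "Microviridae": 0.04,
    "Parvoviridae": 0.21,
    "Circoviridae": 0.03,
    "Astroviridae": 0.06,
    "bacterial": 0.31,
    "host": 0.07,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated sequencing run."""

    seed: int = 0
    n_libraries: int = 6
    read_length: int = 250
    reads_per_library: int = 2000
    composition: dict[str, dict[str, float]] = field(default_factory=dict)
    duplicate_rate: float = 0.10
    adapter_seq: str = "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"
    adapter_fraction: float = 0.05
    quality_decay: tuple[float, float, float] = (36.0, 26.0, 3.0)  # mean start, mean end, sd
    group_labels: dict[str, str] = field(default_factory=lambda: dict(GROUP_LABELS))
    species_per_family: int = 2
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    control_reads: int = 50
    partial_duplicates: bool = False
    # species_label -> proportion overrides (within the library's family mass);
    # used to place particular genomes in particular libraries.
    species_composition: dict[str, dict[str, float]] = field(default_factory=dict)
    # species_label -> list of ARG gene names carried by that phage genome
    phage_arg_plan: dict[str, list[str]] = field(default_factory=dict)
    bacterial_arg_plan: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.composition:
            self.composition = {
                lib: dict(_NMC_COMPOSITION if lib == "PE-NMC" else _BASE_COMPOSITION)
                for lib in LIBRARIES[: self.n_libraries]
            }
        if not self.phage_arg_plan:
            self.phage_arg_plan = {
                "Siphoviridae sp1": ["cmeB", "macB", "oprM"],
                "Myoviridae sp2": ["cmeA", "floR"],
            }
        if not self.bacterial_arg_plan:
            self.bacterial_arg_plan = {"bacterial sp1": ["vanA", "tetW", "ermB"]}
        self.validate()

    def validate(self) -> None:
        if self.read_length <= 55:
            raise ValueError("read_length must exceed 55 so the dedup window exists")
        if not (0 <= self.duplicate_rate < 1):
            raise ValueError("duplicate_rate must be in [0, 1)")
        for lib, comp in self.composition.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"library {lib}: composition sums to {total}, not 1")
            for fam in comp:
                if fam not in LINEAGES:
                    raise ValueError(f"library {lib}: unknown family_label {fam!r}")

    def to_yaml(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        d["quality_decay"] = list(self.quality_decay)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def default_config(seed: int = 0, **kw) -> SimConfig:
    return SimConfig(seed=seed, **kw)


def arg_study_config(seed: int = 0, reads_per_library: int = 4000, **kw) -> SimConfig:
    """Study conditions for the group-exclusive ARG scenario.

    Five ARGs (arnA, ugd, ileS, tet36, dfrE) ride on 'Siphoviridae sp2',
    which is placed only in PT-group libraries; 'Siphoviridae sp1' carries
    core ARGs (cmeB, macB, oprM) and is present in every library. The
    default depth gives the ARG phage ~10x per-library coverage
    (Lander-Waterman: contiguous assembly of each ~600-nt ARG ORF in at
    least one library of its group is then near-certain).
    """
    plan = {
        "Siphoviridae sp1": ["cmeB", "macB", "oprM"],
        "Siphoviridae sp2": ["arnA", "ugd", "ileS", "tet36", "dfrE"],
    }
    species_comp: dict[str, dict[str, float]] = {}
    for lib, grp in GROUP_LABELS.items():
        if grp == "PT":
            species_comp[lib] = {"Siphoviridae sp1": 0.5, "Siphoviridae sp2": 0.5}
        else:
            species_comp[lib] = {"Siphoviridae sp1": 1.0}
    return SimConfig(
        seed=seed,
        reads_per_library=reads_per_library,
        phage_arg_plan=plan,
        species_composition=species_comp,
        **kw,
    )


# ---------------------------------------------------------------------------
# sequence-level primitives

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of residues (length preserved)."""
    n_mut = int(round(divergence * len(seq)))
    pos = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    out = list(seq)
    for p in pos:
        choices = [a for a in AA20 if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly random synonymous codons, adding a stop."""
    table = _codon_table()
    codons = [table[aa][rng.integers(len(table[aa]))] for aa in protein]
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(codons) + stop


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------------------
# genome generation


def generate_genomes(config: SimConfig) -> list[GenomeRecord]:
    """Build the community's genomes with planted hallmark/ARG/function genes.

    Deterministic given ``config.seed``. Each viral genome embeds exactly one
    hallmark ORF for its category; phage genomes may additionally carry ARG
    and functional genes per the config's plans; bacterial genomes carry NVNR
    genes, their own ARGs, and near-homologs of every phage-borne ARG (the
    horizontal-transfer decoys that exercise the competitive filter).
    """
    rng = np.random.default_rng(config.seed)
    families = sorted({fam for comp in config.composition.values() for fam in comp})
    for sp_map in config.species_composition.values():
        for sp in sp_map:
            fam = sp.rsplit(" sp", 1)[0]
            if fam not in families:
                raise ValueError(f"species_composition references unknown family {fam!r}")

    # one ancestral hallmark protein per hallmark gene (shared across the
    # families of a category, so e.g. all Caudovirales TerLs are homologous)
    hallmark_len = {"TerL": 220, "MCP": 180, "Rep": 160, "NS1": 170, "RdRp": 200}
    hallmark_anc = {h: random_protein(rng, hallmark_len[h]) for h in sorted(hallmark_len)}
    # family-level divergence from the category ancestor
    fam_hallmark: dict[str, str] = {}
    for fam in families:
        cat = LINEAGES[fam]["category"]
        if cat in HALLMARK_BY_CATEGORY:
            h = HALLMARK_BY_CATEGORY[cat]
            fam_hallmark[fam] = mutate_protein(hallmark_anc[h], 0.18, rng)

    # ARG ancestors, deterministic order
    arg_len = 210
    arg_anc = {g: random_protein(rng, arg_len) for g in sorted(ARG_CATALOGUE)}
    phage_arg_genes = sorted({g for gl in config.phage_arg_plan.values() for g in gl})

    genomes: list[GenomeRecord] = []
    gene_counter = [0]

    def _assemble(genes: list[tuple[str, str, str, dict]], gid: str) -> tuple[str, list[GeneFeature]]:
        """genes: (name, role, protein, metadata); tiled forward-strand, short intergenic gaps."""
        parts: list[str] = [random_dna(rng, int(rng.integers(12, 25)))]
        feats: list[GeneFeature] = []
        pos = len(parts[0])
        for name, role, protein, meta in genes:
            nt = back_translate(protein, rng)
            gene_counter[0] += 1
            feats.append(
                GeneFeature(
                    gene_id=f"gene{gene_counter[0]:04d}_{name}",
                    name=name,
                    role=role,
                    start=pos,
                    end=pos + len(nt),
                    strand="+",
                    protein=protein,
                    metadata=meta,
                )
            )
            parts.append(nt)
            pos += len(nt)
            gap = random_dna(rng, int(rng.integers(12, 25)))
            parts.append(gap)
            pos += len(gap)
        return "".join(parts), feats

    for fam in families:
        cat = LINEAGES[fam]["category"]
        if cat in HALLMARK_BY_CATEGORY:
            hall = HALLMARK_BY_CATEGORY[cat]
            for i in range(1, config.species_per_family + 1):
                species = f"{fam} sp{i}"
                gid = f"g_{fam}_{i}"
                genes: list[tuple[str, str, str, dict]] = []
                genes.append(
                    (hall, "hallmark", mutate_protein(fam_hallmark[fam], float(rng.uniform(0.03, 0.10)), rng), {})
                )
                n_extra = 7 if cat == "phage_dsDNA" else 3
                for j in range(n_extra):
                    genes.append((f"vp{j}", "cds", random_protein(rng, int(rng.integers(120, 260))), {}))
                for g in config.phage_arg_plan.get(species, []):
                    meta = dict(ARG_CATALOGUE[g])
                    genes.append((g, "arg", mutate_protein(arg_anc[g], 0.04, rng), meta))
                if cat in ("phage_dsDNA", "phage_ssDNA"):
                    k = int(rng.integers(1, 3))
                    for j in range(k):
                        cat2, sub = FUNCTION_CATEGORIES[int(rng.integers(len(FUNCTION_CATEGORIES)))]
                        genes.append(
                            (
                                f"fn{j}",
                                "function",
                                random_protein(rng, int(rng.integers(120, 220))),
                                {"category": cat2, "subcategory": sub},
                            )
                        )
                seq, feats = _assemble(genes, gid)
                if len(seq) < 1000:  # viral minimum; pad with a filler gene
                    seq += back_translate(random_protein(rng, (1000 - len(seq)) // 3 + 30), rng)
                genomes.append(GenomeRecord(gid, seq, cat, fam, species, feats))
        elif cat == "bacterial":
            for i in range(1, 3):
                species = f"bacterial sp{i}"
                gid = f"g_bacterial_{i}"
                genes = []
                for j in range(16):
                    genes.append((f"bp{j}", "cds", random_protein(rng, int(rng.integers(150, 300))), {}))
                for g in config.bacterial_arg_plan.get(species, []):
                    genes.append((g, "arg", mutate_protein(arg_anc[g], 0.04, rng), dict(ARG_CATALOGUE[g])))
                if i == 1:
                    # chromosomal near-homologs of every phage-borne ARG: the
                    # decoys the competitive filter must use to reject
                    # bacterial reads that also hit the phage-carried copy
                    for g in phage_arg_genes:
                        genes.append((f"{g}_chrom", "cds", mutate_protein(arg_anc[g], 0.04, rng), {}))
                seq, feats = _assemble(genes, gid)
                genomes.append(GenomeRecord(gid, seq, cat, "bacterial", species, feats))
        elif cat == "host":
            species = "host sp1"
            gid = "g_host_1"
            genes = [(f"hp{j}", "cds", random_protein(rng, int(rng.integers(150, 300))), {}) for j in range(12)]
            seq, feats = _assemble(genes, gid)
            genomes.append(GenomeRecord(gid, seq, cat, "host", species, feats))

    for g in genomes:
        minimum = 1000 if g.category in HALLMARK_BY_CATEGORY else 5000
        while len(g.sequence) < minimum:
            g.sequence += random_dna(rng, minimum - len(g.sequence))
    return genomes


# ---------------------------------------------------------------------------
# database + profile construction

AA_INDEX = {a: i for i, a in enumerate(AA20)}


def _encode_protein(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(a, -1) for a in seq], dtype=np.int64)


def score_profile_sequence(profile: ProfileMatrix, seq: str) -> float:
    """Full-length score of ``seq`` against the profile (lengths must agree)."""
    idx = _encode_protein(seq)
    ok = idx >= 0
    pos = np.arange(len(idx))
    return float(profile.scores[pos[ok], idx[ok]].sum())


def _build_profile(name: str, training: list[str], rng: np.random.Generator) -> ProfileMatrix:
    """Per-column log-odds vs uniform background from a same-length training set.

    Columns are estimated from the observed homologs broadened with mutants
    at 10-50% divergence (the profile's breadth). The score threshold is the
    1st percentile of self-scores of HELD-OUT true positives spanning
    20-65% divergence: held-out calibration avoids the self-inclusion bias
    of scoring training members against columns that contain them, so the
    threshold admits remote family members (down to roughly one-third
    identity) while random sequence stays far below it.
    """
    augmented = list(training)
    for t in training:
        for _ in range(3):
            augmented.append(mutate_protein(t, float(rng.uniform(0.10, 0.50)), rng))
    L = len(training[0])
    counts = np.full((L, 20), 0.25)
    for s in augmented:
        idx = _encode_protein(s)
        ok = idx >= 0
        counts[np.arange(L)[ok], idx[ok]] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    scores = np.log2(freqs / 0.05)
    prof = ProfileMatrix(name=name, scores=scores, score_threshold=0.0)
    held_out = [
        mutate_protein(t, float(rng.uniform(0.25, 0.70)), rng) for t in training for _ in range(6)
    ]
    self_scores = sorted(score_profile_sequence(prof, s) for s in held_out)
    prof.score_threshold = float(np.percentile(self_scores, 1))
    return prof


def build_databases(
    genomes: list[GenomeRecord], decoy_fraction: float = 0.2, seed: int = 0
) -> dict[str, object]:
    """Partition genome proteins into the pipeline's reference databases.

    viral_db: every protein on a viral genome (lineage attached);
    nvnr_db: bacterial/host proteins plus ``decoy_fraction`` diverged copies
    of random viral proteins (remote homolog decoys);
    arg_db / function_db: metadata-carrying catalogues;
    profiles: hallmark PSSMs trained on the simulated hallmark homologs.
    """
    if not genomes:
        raise ValueError("no genomes")
    rng = np.random.default_rng(seed + 977)
    viral_db: list[ProteinDBEntry] = []
    nvnr_db: list[ProteinDBEntry] = []
    arg_db: list[ProteinDBEntry] = []
    function_db: list[ProteinDBEntry] = []
    hallmark_sets: dict[str, list[str]] = {}

    for g in genomes:
        lin = LINEAGES[g.family_label]
        lineage = (lin["realm"], lin["order"], g.family_label, g.species_label)
        viral = g.category in HALLMARK_BY_CATEGORY
        for f in g.features:
            entry_id = f"{g.id}|{f.gene_id}"
            if viral:
                viral_db.append(ProteinDBEntry(entry_id, f.protein, g.id, lineage, "viral", dict(f.metadata)))
            else:
                nvnr_db.append(ProteinDBEntry(entry_id, f.protein, g.id, lineage, "nvnr", {}))
            if f.role == "arg":
                arg_db.append(
                    ProteinDBEntry(f.name, f.protein, g.id, lineage, "arg", dict(f.metadata))
                )
            if f.role == "function":
                function_db.append(
                    ProteinDBEntry(entry_id, f.protein, g.id, lineage, "function", dict(f.metadata))
                )
            if f.role == "hallmark":
                hallmark_sets.setdefault(f.name, []).append(f.protein)

    n_decoys = int(round(decoy_fraction * len(nvnr_db)))
    pool = [e for e in viral_db]
    for k in range(n_decoys):
        src = pool[int(rng.integers(len(pool)))]
        nvnr_db.append(
            ProteinDBEntry(
                f"decoy_{k:03d}",
                mutate_protein(src.aa_sequence, 0.30, rng),
                "decoy",
                ("Bacteria", "Bacteria", "bacterial", "decoy homolog"),
                "nvnr",
                {"decoy_of": src.id},
            )
        )

    profiles = [
        _build_profile(name, seqs, rng) for name, seqs in sorted(hallmark_sets.items())
    ]
    return {
        "viral_db": viral_db,
        "nvnr_db": nvnr_db,
        "arg_db": arg_db,
        "function_db": function_db,
        "profiles": profiles,
    }


# ---------------------------------------------------------------------------
# read simulation


def _quality_vector(rng: np.random.Generator, length: int, decay: tuple[float, float, float]) -> np.ndarray:
    mean = np.linspace(decay[0], decay[1], length)
    q = rng.normal(mean, decay[2])
    return np.clip(np.round(q), 2, 40).astype(int)


_DNA = np.array(list("ACGT"))


def _apply_errors(seq: str, quals: np.ndarray, rng: np.random.Generator) -> str:
    p_err = 10.0 ** (-quals / 10.0)
    hits = np.nonzero(rng.random(len(seq)) < p_err)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[rng.integers(3)]
    return "".join(out)


def simulate_reads(
    genomes: list[GenomeRecord], config: SimConfig
) -> tuple[dict[str, list[Read]], GroundTruthManifest]:
    """Draw paired-end reads per library composition; emit truth manifest.

    Mates come from opposite strands of an insert (default 400 +/- 50 nt);
    a ``duplicate_rate`` fraction of each library's reads are exact re-emitted
    copies; ``adapter_fraction`` of reads have adapter carried into their 3'
    end; substitution errors follow the per-base Phred error probability.
    A near-empty blank control library ("control") is always emitted.
    """
    rng = np.random.default_rng(config.seed + 1)
    by_family: dict[str, list[GenomeRecord]] = {}
    by_species: dict[str, GenomeRecord] = {}
    for g in genomes:
        by_family.setdefault(g.family_label, []).append(g)
        by_species[g.species_label] = g

    manifest = GroundTruthManifest()
    for g in genomes:
        for f in g.features:
            manifest.per_gene.setdefault(f.name, []).append(
                {"genome": g.id, "gene_id": f.gene_id, "start": f.start, "end": f.end, "strand": f.strand, "role": f.role}
            )

    libraries: dict[str, list[Read]] = {}
    L = config.read_length

    def _sample_genome(lib: str, comp: dict[str, float], fams: list[str], probs: np.ndarray) -> GenomeRecord:
        fam = fams[int(rng.choice(len(fams), p=probs))]
        sp_over = config.species_composition.get(lib, {})
        in_fam = {sp: w for sp, w in sp_over.items() if sp.rsplit(" sp", 1)[0] == fam}
        if in_fam:
            sps = sorted(in_fam)
            w = np.array([in_fam[s] for s in sps])
            return by_species[sps[int(rng.choice(len(sps), p=w / w.sum()))]]
        cands = by_family.get(fam)
        if not cands:
            raise ValueError(f"composition references family {fam!r} with no genome")
        return cands[int(rng.integers(len(cands)))]

    def _emit_pair(lib: str, genome: GenomeRecord, idx: int) -> list[Read]:
        glen = len(genome.sequence)
        frag_len = int(np.clip(rng.normal(config.insert_mean, config.insert_sd), L // 2, glen))
        start = int(rng.integers(0, glen - frag_len + 1))
        frag = genome.sequence[start : start + frag_len]
        fwd = rng.random() < 0.5
        if not fwd:
            frag = reverse_complement(frag)
        out = []
        for mate in (1, 2):
            sub = frag[:L] if mate == 1 else reverse_complement(frag)[:L]
            quals = _quality_vector(rng, len(sub), config.quality_decay)
            seq = _apply_errors(sub, quals, rng)
            adapter_len = 0
            if config.adapter_seq and rng.random() < config.adapter_fraction:
                adapter_len = int(rng.integers(18, min(len(config.adapter_seq), len(seq) // 3)))
                seq = seq[: len(seq) - adapter_len] + config.adapter_seq[:adapter_len]
            rid = f"{lib}_r{idx:06d}_{mate}"
            out.append(Read(rid, seq, list(quals), library=lib))
            manifest.per_read[rid] = {
                "genome": genome.id,
                "family": genome.family_label,
                "species": genome.species_label,
                "start": start,
                "strand": "+" if fwd else "-",
                "mate": mate,
                "is_duplicate_of": None,
                "adapter_len": adapter_len,
            }
        return out

    lib_names = sorted(config.composition)
    for lib in lib_names:
        comp = config.composition[lib]
        fams = sorted(comp)
        probs = np.array([comp[f] for f in fams])
        probs = probs / probs.sum()
        for fam in fams:
            if comp[fam] > 0 and fam not in by_family:
                raise ValueError(f"library {lib}: no genome for family {fam!r}")
        n = config.reads_per_library
        n_dup = int(np.floor(config.duplicate_rate * n))
        reads: list[Read] = []
        idx = 0
        while len(reads) < n - n_dup:
            genome = _sample_genome(lib, comp, fams, probs)
            pair = _emit_pair(lib, genome, idx)
            idx += 1
            for r in pair:
                if len(reads) < n - n_dup:
                    reads.append(r)
                else:
                    del manifest.per_read[r.id]
        originals = list(reads)
        for k in range(n_dup):
            src = originals[int(rng.integers(len(originals)))]
            rid = f"{lib}_dup{k:05d}"
            if config.partial_duplicates:
                # identical only in the dedup window (bases 5-55, 1-based)
                seq = list(random_dna(rng, len(src.sequence)))
                seq[4:55] = src.sequence[4:55]
                seq = "".join(seq)
            else:
                seq = src.sequence
            quals = _quality_vector(rng, len(seq), config.quality_decay)
            reads.append(Read(rid, seq, list(quals), library=lib))
            rec = dict(manifest.per_read[src.id])
            rec["is_duplicate_of"] = src.id
            manifest.per_read[rid] = rec
        libraries[lib] = reads
        fam_counts: dict[str, int] = {}
        for r in reads:
            fam_counts[manifest.per_read[r.id]["family"]] = fam_counts.get(manifest.per_read[r.id]["family"], 0) + 1
        manifest.per_library[lib] = fam_counts

    # blank control: trace carry-over of background (bacterial/host) material
    control: list[Read] = []
    background = [g for g in genomes if g.category in ("bacterial", "host")] or genomes
    idx = 0
    while len(control) < config.control_reads:
        genome = background[int(rng.integers(len(background)))]
        for r in _emit_pair("control", genome, idx):
            if len(control) < config.control_reads:
                control.append(r)
            else:
                del manifest.per_read[r.id]
        idx += 1
    libraries["control"] = control
    manifest.per_library["control"] = {}
    for r in control:
        fam = manifest.per_read[r.id]["family"]
        manifest.per_library["control"][fam] = manifest.per_library["control"].get(fam, 0) + 1
    return libraries, manifest


# ---------------------------------------------------------------------------
# text-format exports


def write_genomes_fasta(genomes: list[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id} family={g.family_label} species={g.species_label}\n{g.sequence}\n")


def write_protein_db_fasta(entries: list[ProteinDBEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.id} role={e.db_role}\n{e.aa_sequence}\n")


def save_databases(dbs: dict, outdir) -> None:
    """Write the reference databases as FASTA/JSON text files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for role in ("viral_db", "nvnr_db", "arg_db", "function_db"):
        with open(os.path.join(outdir, f"{role}.fasta"), "w") as fh:
            for e in dbs[role]:
                meta = ";".join(f"{k}={v}" for k, v in sorted(e.metadata.items()))
                lin = "|".join(e.lineage)
                fh.write(f">{e.id}\trole={e.db_role}\tlineage={lin}\tsrc={e.source_genome}\tmeta={meta}\n")
                fh.write(e.aa_sequence + "\n")
    with open(os.path.join(outdir, "profiles.json"), "w") as fh:
        json.dump(
            [
                {"name": p.name, "score_threshold": p.score_threshold, "scores": p.scores.tolist()}
                for p in dbs["profiles"]
            ],
            fh,
        )


def load_databases(outdir) -> dict:
    """Inverse of :func:`save_databases`."""
    import os

    out: dict = {}
    for role in ("viral_db", "nvnr_db", "arg_db", "function_db"):
        entries = []
        path = os.path.join(outdir, f"{role}.fasta")
        with open(path) as fh:
            header = None
            seq: list[str] = []
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if header is not None:
                        entries.append(_parse_db_header(header, "".join(seq)))
                    header, seq = line[1:], []
                else:
                    seq.append(line)
            if header is not None:
                entries.append(_parse_db_header(header, "".join(seq)))
        out[role] = entries
    with open(os.path.join(outdir, "profiles.json")) as fh:
        out["profiles"] = [
            ProfileMatrix(
                name=d["name"],
                scores=np.array(d["scores"]),
                score_threshold=d["score_threshold"],
            )
            for d in json.load(fh)
        ]
    return out


def _parse_db_header(header: str, seq: str) -> ProteinDBEntry:
    name, *fields = header.split("\t")
    kv = dict(f.split("=", 1) for f in fields if "=" in f)
    meta = {}
    if kv.get("meta"):
        meta = dict(p.split("=", 1) for p in kv["meta"].split(";") if "=" in p)
    return ProteinDBEntry(
        id=name,
        aa_sequence=seq,
        source_genome=kv.get("src", ""),
        lineage=tuple(kv.get("lineage", "|||").split("|")),  # type: ignore[arg-type]
        db_role=kv.get("role", ""),
        metadata=meta,
    )


def write_lineage_table(path) -> None:
    with open(path, "w") as fh:
        fh.write("family\trealm\torder\tcategory\n")
        for fam, lin in sorted(LINEAGES.items()):
            fh.write(f"{fam}\t{lin['realm']}\t{lin['order']}\t{lin['category']}\n")


def write_arg_metadata(path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdrug_class\tmechanism\n")
        for g, meta in sorted(ARG_CATALOGUE.items()):
            fh.write(f"{g}\t{meta['drug_class']}\t{meta['mechanism']}\n")
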