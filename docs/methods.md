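# Methods

`viromine` reimplements, at desk scale, the computational workflow of a
pooled fecal virome study: read cleaning, per-library assembly, translated
homology triage against a viral proteome with a competitive non-viral
confirmation step, community ecology across libraries, hallmark-gene
annotation and phylogenetics, and phage ARG/functional-gene quantification.
Because the original workflow runs on tens of millions of reads against
NCBI-scale databases, every stage here is exercised instead on a synthetic
community whose ground truth is known exactly. This note records the models,
parameter choices, and numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Synthetic community generator

The generator emulates six pooled libraries from two lizard species
(group labels PE and PT) across five plateau sites, plus a blank control.

**Genomes.** Each viral family in the community receives (by default) two
species-level genomes built as dense forward-strand tilings of
protein-coding genes separated by 12–25 nt intergenic gaps — a reasonable
cartoon of phage genome architecture, where coding density is ~90%+. Every
viral genome embeds exactly one hallmark gene for its group (TerL for
*Caudovirales*, MCP for *Microviridae*, Rep for CRESS viruses, NS1 for
*Parvoviridae*, RdRp for *Riboviria*). Hallmarks descend from one ancestral
protein per hallmark: families diverge ~18% from the ancestor and species a
further 3–10%, so hallmark sets are genuinely homologous across families of
a category. RNA-virus genomes are emitted as cDNA (DNA alphabet throughout),
mirroring a reverse-transcription library protocol. Bacterial genomes carry
their own genes and ARGs, plus ~96%-identity chromosomal homologs of every
phage-borne ARG — the horizontal-transfer decoys that make the competitive
filter do real work. A lizard "host" genome supplies additional background.

**Reads.** 250-nt paired-end reads are drawn per library from a family-level
composition table (phage-dominated; the PE-NMC library parvovirus-rich,
echoing the lake-site pattern). Mates come from opposite strands of a
400 ± 50 nt insert. Positional quality decays linearly from Phred ~36 to
~26 (sd 3); substitution errors follow the per-base Phred error probability.
A configurable fraction of reads (default 10%) is re-emitted as exact
duplicates (an option restricts the copied span to bases 5–55 to stress the
dedup rule); 5% of reads carry adapter sequence into their 3' end. A blank
control library of ~50 background reads models trace carry-over. The
manifest records every read's genome, coordinates, strand, duplicate parent
and adapter length; per-library family counts therefore sum exactly to the
library size. The defaults (2,000 reads/library for the pipeline smoke
scale, 10,000/library for the recovery benchmark) were chosen so that every
stage sees non-trivial input while a full run stays in the minutes range on
one core. Insert size and duplicate rate are free parameters of the
simulator, not estimates of any real library.

**Databases.** The viral proteome database holds every protein on a viral
genome; the non-virus non-redundant (NVNR) database holds bacterial and host
proteins plus diverged (~70% identity) copies of randomly chosen viral
proteins — 20% of the NVNR base count — as remote-homolog decoys. ARG
entries carry CARD-style drug class and resistance mechanism; functional
entries carry a two-level pathway category.

**Hallmark profiles.** Each hallmark gets an additive position-specific
score matrix: per-column log-odds of residue frequency versus a uniform
background, estimated from the observed hallmark homologs broadened with
mutants at 10–50% divergence. The score threshold is the 1st percentile of
self-scores of *held-out* true positives spanning 20–65% divergence.
Held-out calibration matters: scoring training members against columns that
contain them inflates their scores by several hundred points, and a
threshold set that way rejects every remote homolog. With held-out
calibration the profiles detect homologs down to ~35% identity while random
sequence scores hundreds of points below threshold (measured false-positive
rate 0 on random contigs).

## Read cleaning

Duplicates are reads identical over 1-based positions 5–55 (51 nt);
grouping is transitive on the key, one survivor per group is chosen
uniformly with the stage seed, and reads shorter than 55 nt key on whatever
exists from position 5 (conservative, never crashes). Quality trimming uses
the BWA-style suffix-maximization rule at Phred threshold 10; ties resolve
toward the shorter trim. Adapter trimming is an ungapped +1/−3 scan of both
adapter strands at every offset (vectorised Kadane); a match scoring ≥16
truncates the read when it lies in the 3' half and masks it with N
otherwise. The length filter keeps reads of ≥50 nt, boundary inclusive.

## Assembly

A greedy overlap-layout assembler merges, at each step, the pair of
sequences (either orientation) with the highest-scoring suffix–prefix
overlap of ≥35 nt at ≥98% identity, with ties broken lexicographically by
id; unmerged reads become singlets, and every read ends in exactly one
contig. Candidate overlaps are found through an exact 16-mer prefix seed,
which is exhaustive for overlaps whose first 16 bases are error-free — at
simulated error rates (≤0.3% per base) this misses essentially nothing. In
an overlap the leading sequence's bases are kept. Chimera flagging is a
split-hit test: a contig whose 5'-half and 3'-half best hits (both E<1e−5,
non-overlapping spans) belong to different families is flagged. This rule is
a stand-in for an unnamed upstream method; it targets exactly the artifact
class a greedy assembler can create.

## Translated homology triage

The discovery engine is a BLASTx-style seeded aligner:

- 3-mer seed words, database-side neighbourhood expansion at BLOSUM62
  threshold 11, so query lookup is a table probe;
- two word hits on a diagonal within 40 residues trigger an ungapped X-drop
  extension (X=16), run in a compiled kernel over whole read batches;
- extensions reaching raw score 55 (~32 bits) trigger a gapped local
  alignment (BLOSUM62, affine gaps open 11 / extend 1) via Biopython's
  PairwiseAligner, capped at the best 8 subjects per query.

Scores convert to bits with the published gapped-BLOSUM62 constants
S' = (λS − ln K)/ln 2, λ=0.267, K=0.041, and E = m·n·2^(−S') with m the
translated frame length and n the total database residues; hits are
reported at E < 1e−5. The gapped trigger is conservative by construction:
at desk-scale database sizes a reportable hit needs ≈37 bits (raw ≈87), far
above the trigger, so the heuristics cost no reportable hits; they do make
the null-query hit rate fall below the Karlin–Altschul expectation rather
than match it exactly, which is why the calibration check is one-sided.

Queries with a viral hit are searched against NVNR; the viral assignment is
discarded only when the best NVNR bit score strictly exceeds the best viral
bit score (ties favour viral; an `any_hit` mode removes on any NVNR hit
below the cutoff). Contigs — not singlet reads — with no surviving viral
hit are scanned against the hallmark profiles as a remote-homology
fallback; a qualifying window yields a group-level assignment
("unclassified Caudovirales" for TerL, etc.). Species identity for counting
is the best hit's species label, ties broken by identity then subject id.

## Ecology

Bray–Curtis dissimilarity uses the standard abundance formula. UPGMA is
average linkage with ties broken on the lexicographically smallest pair of
cluster labels; node height is half the merge distance, so trees are
ultrametric to serialization precision (10 significant digits). PCoA is
Gower double-centering plus eigendecomposition; negative eigenvalues are
reported but their axes dropped (no Cailliez/Lingoes correction — none is
described upstream), and each axis's first nonzero loading is made
positive. ANOSIM uses the rank-based statistic R = (r̄_B − r̄_W)/(M/2) over
M = n(n−1)/2 pairwise distances, with p = (1 + #{R* ≥ R})/(1 + n_perm)
under seeded label permutations; the statistic matches scikit-bio's
implementation exactly on shared inputs. A species counts as present in a
library at ≥1 assigned read. Shared-species accounting reports the disjoint
intersection cardinalities (UpSet layout), per-group exclusives, and the
all-library core. Constrained ordination (CCA) is out of scope; the
unconstrained PCoA carries the comparison.

## Annotation and phylogenetics

Viral contigs whose best hits target the same subject with non-overlapping,
order-consistent spans are joined in subject order with a 10-N spacer, each
piece oriented by its hit frame. Read mapping is exact 31-mer anchoring plus
edlib infix alignment; a read maps when ≥90% of it aligns at ≥95% identity
(tested on the full read and with 10% end-trims), counted once to its best
reference with ties to input order. ORF prediction reports, per
stop-to-stop segment in each of six frames, the ORF from the segment's
first ATG, at ≥300 nt including the stop codon ("minimum size 300" is read
as nucleotides, the convention of the upstream GUI tool; an amino-acid
reading would simply change the constant). Edge-truncated ORFs carry
`has_stop=False`. Hallmark calls take the best profile whose placement
score reaches the threshold pro-rated by coverage; a complete CDS requires
start, stop, and ≥90% profile coverage — the coverage guard keeps fragments
from being called complete.

Phylogenetics aligns hallmark proteins progressively along a 3-mer-distance
UPGMA guide tree, merging profiles by global affine DP (BLOSUM62, 11/1,
column scores are expected pair scores with gaps contributing zero).
Columns with strictly more than 50% gaps are removed (a 50%-gap column
stays). Distances are Poisson-corrected p-distances over mutually ungapped
columns, d = −ln(1−p), clamped at 10 on saturation. Trees are standard
neighbor-joining with lexicographic tie-breaks; negative branch lengths
clamp to zero with the deficit moved to the sister branch. Bayesian and
maximum-likelihood inference are deliberately out of scope — they are
published tools, not part of this workflow's own logic — so the distance
trees stand where those would run, on the same filtered alignments.

## Quantification

Sequences whose surviving lineage is a bacteriophage family (the
*Caudovirales* families, *Microviridae*, and the unclassified-Caudovirales
fallback label) enter ARG/functional profiling. Their ORFs are searched
BLASTp-style against the catalogues at E < 1e−5 (best hit per ORF); reads
are mapped back to annotated ORFs, each read counted once; and abundances
are normalised as ppm = hits·10⁶/N and FPKM = hits·10⁹/(L·N), with N the
library's **raw** (pre-cleaning) read count and L the ORF's coding length —
the two factors the upstream description couples ambiguously are split
conventionally and both reported. Aggregations sum ppm by drug class,
mechanism, or functional category and normalise to per-library proportions.
A gene is exclusive to a group when present (ppm > 0) only in that group's
libraries, and core when present in every library; whether a read mapping
to two ORFs should be double-counted is resolved as "count once, best ORF".

## Pipeline, seeding, determinism

`run_pipeline` chains simulate → clean → assemble → triage → ecology →
annotate → phylogenetics → quantify and writes a JSON report reconciling
per-stage counts. One global seed fans out to per-stage seeds via
`seed·2654435761 + crc32(stage) mod 2³¹`; all randomness flows through
injected NumPy generators, so identical configurations reproduce
byte-identical outputs. The command-line entry points (`viromine
simulate|clean|assemble|triage|run`) are thin wrappers over these library
functions.

## Validation battery and its limits

The `evaluation` module regenerates every reported number from scratch:
brute-force oracle agreement (1,000 random instances per operation),
six-library triage recovery at 10,000 reads/library (composition Spearman
ρ, viral sensitivity, background false-positive rate with decoys present),
null-query E-value calibration (10⁵ random reads, one-sided against the
Karlin–Altschul expectation — the seeded heuristics are conservative),
ANOSIM level (2,000 null datasets at 6+6) and power (400 datasets at 4+4
under a between-group shift of two within-group SDs; 3+3 admits only ten
distinct partitions, so its minimum permutation p-value is ~0.1 and no test
can reject at α=0.05 there), PCoA/UPGMA exactness, NJ topology recovery on
100 additive cases, ppm linearity for a planted 10× abundance ratio
(median over 20 seeds; a single seed carries ~20% counting noise at this
depth), exclusive/core ARG recovery on the planted two-group design, and
the blank-control zero-viral check.

What passing shows — and does not. The synthetic reads carry substitution
errors only (no indels, no real Illumina error profile, no chimeric library
artifacts beyond what assembly itself creates), genomes are coding-dense
with single-copy genes, and the databases are small and internally
consistent. Passing therefore demonstrates that the *logic* of each stage
is correct under its stated model, and that the statistical machinery holds
its nominal properties; it does not estimate the workflow's sensitivity or
error rates on real gut-virome data, where database incompleteness and
sequence artifacts dominate.
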