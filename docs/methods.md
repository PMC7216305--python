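# Methods

`phasetps` re-implements, as a tested library, the comparative annotation of
an expanded terpene-synthase (TPS) gene family on phased diploid genome
assemblies: gene-region discovery and ORF-integrity classification,
duplication/hemizygosity typing through the coverage-scaled identity
statistic I′, reference-guided chromosome grouping, UPGMA/Jukes–Cantor
phylogenies for subfamily and carbocation-mechanism prediction, greedy
protein clustering into representatives, and typed comparative networks.
This note records the models, parameter choices and numerical decisions, and
what the synthetic study design does and does not demonstrate.

## The data model

A phased (FALCON-UNZIP-style) assembly yields two sequence sets per
cultivar: *primary contigs*, pseudomolecules representing both haplotypes'
gene complement, and *haplotigs*, shorter phased sequences carrying the
alternate allele of heterozygous regions. On such assemblies a gene family
appears as: allelic pairs (one copy on a primary contig, its counterpart on
a haplotig that groups to the same chromosome), tandem duplicates (two
copies on one contig), hemizygous genes (present on one haplotype only) and
pseudogenized copies — *d-ORF* genes whose reading frame is disrupted by a
premature stop or a frameshift indel, and *partial* genes truncated to a
few exons.

## Synthetic phased assemblies

The generator emits complete study inputs with known truth so every
downstream stage is scorable without genome downloads.

**Templates.** `make_reference_panel(n_per_subfamily, seed)` builds a
labeled panel over the five plant TPS subfamilies (TPS-a/b/g/c/e). Each
subfamily has a random ancestral CDS with the class-I metal-binding motifs
stamped at fixed positions (DDxxD at ~55% of the protein, an NSE/DTE-type
motif 40 residues downstream; TPS-b templates additionally carry RRx8W near
the N terminus and RxR upstream of DDxxD). Mechanism classes (see below)
descend from the subfamily ancestor at 30% nucleotide divergence, members
from their class ancestor at 13%; motif codons, the start codon and the
terminal stop are frozen, and substitutions that would create an internal
stop are re-rolled. Two panel members of one class are therefore ~24%
divergent pairwise — close enough to group by phylogeny, far enough
(I′ ≈ 76) never to read as gene duplicates at the 80% threshold. Templates
have 7 exons (>= 5 for complete-class templates) and introns of 80–400 bp
with canonical GT..AG ends — below the 3000 bp spliced-search limit, so
noiseless recovery is structurally guaranteed; `with_oversized_intron`
provides the violation mode (5 kb) used to test the limit.

**Mechanism classes.** TPS-a: acyclic-FPP, 1,6-cyclization of the nerolidyl
cation (NPP), 1,10- and 1,11-cyclization of the farnesyl cation. TPS-b:
Type I (terpinyl cation, cyclic monoterpenes) and Type II (acyclic;
optionally also accepting FPP). TPS-g: three substrate-repertoire clades —
GPP-only (geraniol), GPP+FPP ((3S)-linalool/(E)-nerolidol) and
GPP+FPP+GGPP ((E,E)-geranyl linalool); all TPS-g products are acyclic
alcohols. No TPS-c/e member has a characterized mechanism; they carry an
unresolved placeholder class.

**Assemblies.** Reference chromosomes are i.i.d. uniform DNA at GC 0.45
(avoiding accidental homology between unrelated implants); contig backbones
are carved as windows of these chromosomes, so chromosome grouping has
exact truth; genes replace backbone windows at designed offsets
(overlapping windows are a design error), making truth exon coordinates
exact final contig coordinates. The truth table records realized classes:
with a nonzero background SNP rate the generator re-derives completeness
and ORF class from the final sequence, since background substitutions can
create genuine premature stops. Designed disruptions (injected stops,
1 bp frameshift indels) are placed at least 21 bp away from splice
boundaries: a disruption inside the boundary ambiguity zone cannot be
distinguished from intron sequence by any spliced aligner, which would
make the designed class unrecoverable even without noise.

**The standard design** (per cultivar, 60 implants): 30 fl-ORF (6 allelic
pairs, 3 tandem groups of four — two primary copies plus two haplotig
copies, so tandem genes also have allelic partners — and 6 hemizygous
loners), 15 d-ORF (5 allelic pairs and 5 hemizygous, mixing premature
stops and frameshifts), 15 partial (middle 4 exons, so both the exon-count
and terminal-codon conditions fail), across 6 primary contigs and 8
haplotigs on 6 chromosomes, intergenic spacing 4 kb. The same template
fills the same slot in every cultivar, so cross-cultivar homologs exist by
construction. With 45 complete genes and allelic partners arriving in
pairs, the hemizygous count is necessarily odd; the design has 11.

**What the generator does not emulate:** repeat/transposon landscapes,
recombination, read-level error profiles, real codon usage or GC structure,
assembly artifacts (chimeras, collapsed repeats). Passing tests therefore
demonstrate the correctness of the algorithms under clean phased-assembly
semantics, not robustness to real assembly pathology.

## Gene-region discovery and classification

The spliced search is an internal seed-and-chain aligner (the external
est2genome-style tool it replaces is a pipeline dependency, not a
contribution): exact 15-mer seeds against a per-contig index, collapsed
into same-diagonal segments (seed gaps <= 60 bp bridge SNP interruptions),
chained colinearly with query gaps in [-15, 200] bp and target gaps at most
`max_intron` (default 3000) beyond the query gap; both strands are
searched and chains are extracted iteratively so tandem copies yield
separate hits. Within a chain, a target gap exceeding the query gap by
more than 30 bp opens an intron; smaller offsets are treated as exonic
indels.

Exon boundaries are refined by distributing each unanchored query chunk
between the flanking exons to maximize matching bases. Two safeguards
matter: (1) the ungapped (substitution-only) split is preferred, and a
gapped (edlib prefix-fit) split is accepted only when strictly better
after an indel penalty of 3 per shifted base — otherwise a SNP adjacent to
a splice site gets re-explained as an indel pair and silently shifts the
reading frame; (2) exact ties are broken toward canonical splice signals
(GT..AG on the plus strand, reading CT..AC in forward-text coordinates on
the minus strand). Terminal extensions are kept only when they consume the
query to its end (within an x-drop of 12), so truncated genes never bleed
into flanking background.

Hits are scored as matched bases per anchored query base, with the 0.90
floor retained and a minimum anchored span of 300 bp. Normalizing over the
anchored span rather than the full query is a deliberate choice: with
full-length queries a hard fraction-of-query-maximum floor would make
sub-span partial genes (4 of 7 exons) undiscoverable. Verbatim implants
still score exactly 1.0.

Curation merges overlapping same-strand hits per contig; the hit with the
greatest exon coverage, then the highest score, then the leftmost position,
then the lexicographically smallest query id defines the locus. Accessions
are the two-letter cultivar code + "TPS" + a sequential number in
(contig id, position) order. Classification: a region is *partial* iff it
has <= 4 exons **or** lacks a terminal start/stop codon (the complete
definition requires all conditions, so either failure suffices); complete
regions with a CDS length not divisible by three are *d-ORF frameshift*,
with an internal stop in a preserved frame *d-ORF premature stop*,
otherwise *fl-ORF* with the translated protein attached. Translation uses
the standard code, ATG-initiated only.

Motif patterns are configurable regular expressions with defaults
`RRx8W = RR.{8}W`, `DDxxD = DD..[DE]`, `NSE/DTE = [ND]D..[ST]...E`, and
`RxR = R.R` reported only within 40 residues upstream of a DDxxD hit.

## Duplication typing and I′

Complete genes (fl-ORF + d-ORF) are compared all-against-all per cultivar.
The published description of I′ ("*I* the number of identities and gaps,
*n* the aligned length, *L* the total length of the query and subject") is
ambiguous about gap counting and the normalizing length; the package fixes

    I′ = 100 · I / max(L_q, L_s)

with I the identity count of the best local alignment — symmetric under
swap, and penalizing partial coverage so a perfect but short overlap is
not called a duplication (a perfect half-length match scores exactly 50).
The choice lives in one replaceable function (`identity_prime`);
alternatives would normalize by the alignment length n or by L_q + L_s.
Local alignments use match +2 / mismatch −3 / gap open 5 / extend 2 with a
Karlin–Altschul E-value screen (default floor 1e-5); I and n come from the
single optimal local alignment (the best colinear chain of one — for
full-length gene homologs the optimal local alignment *is* the chain).

Two screens keep all-vs-all inside the runtime budget without affecting
results: pairs must share >= 8 canonical 15-mers (a borderline pair at 80%
identity over >= 1 kb shares on the order of a hundred), and a unit-cost
global edit-distance estimate must reach threshold − 10 (for near-threshold
full-length homologs the estimate tracks I′ closely; dissimilar pairs score
tens of points below). Only surviving pairs get the exact local alignment.

Edge typing at I′ > 80: same contig → tandem; primary↔haplotig whose
contigs group to the same chromosome → haplotype (allelic); anything else →
tentative (pairs with missing chromosome assignments are typed on contig
identity alone and logged). A complete gene with no haplotype-type edge is
hemizygous. The composition summary reports edge-type percentages and the
duplicated/hemizygous shares among complete genes.

## Chromosome grouping

Each contig is assigned to the reference chromosome sharing the most
*chromosome-unique* canonical 21-mers with it; the grouping score is the
winner's share of all uniquely-matching k-mers (ties go to "unplaced" with
a warning). Restricting the vote to k-mers occurring in exactly one
chromosome guards against repeat-driven misassignment without an external
aligner. Ordering/orienting contigs within chromosomes, chimera breaking
and structural-variant calling are out of scope; only the grouping decision
and its confidence are reproduced.

## Phylogenies and functional prediction

**Progressive MSA.** A deterministic internal aligner: UPGMA guide tree on
k-mer distances (k = 6 nucleotide, k = 3 protein; d = 1 − shared/min),
then profile–profile global alignment with linear gap costs (match +2,
mismatch −1, gap 2 per row) via a vectorized prefix-max dynamic program.
Degapping any row recovers the input sequence. External aligners are
deliberately not called: downstream contracts depend only on MSA validity
and determinism.

**Distances.** Nucleotide: Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p) with p
the mismatch proportion over sites where both rows are residues; p >= 0.75
saturates the correction and is capped at 10 (logged); zero comparable
sites is an error. Protein: p-distance without multiple-hit correction
(the correction is a nucleotide-model concept), computed over columns where
*either* row is a residue, one-sided gaps counting as differences — short
active-site regions from different classes overlap mainly at the frozen
motifs, and excluding gapped columns would make them look spuriously close.

**UPGMA.** Arithmetic-average agglomeration; heights are half the merge
distance (ultrametric output); ties break toward the pair whose
lexicographically smallest member id is smallest. Bootstrap support is
column resampling with replacement (default 100 replicates, seeded); the
support of an internal bipartition is the percentage of replicate trees
containing it. Supports are reported but never veto assignments.

**Active sites.** The region runs from the start of the last DDxxD hit
through the end of the first NSE/DTE hit downstream of it, both anchors
included; a missing anchor yields an empty region, and such proteins are
excluded from mechanism phylogenies and reported. Anchor-inclusive spanning
is the package's documented reading of the active-site definition.

**Subfamily assignment** aligns query spliced CDS jointly with the labeled
panel mRNAs at the nucleotide level (intron turnover adds noise without
adding signal), builds the UPGMA tree on JC distances and assigns each
query the subfamily of its nearest labeled leaf by patristic (cophenetic)
distance; exact ties across subfamilies give "unresolved". Queries are
processed in batches of 25 against the full panel; nearest-labeled-leaf
assignment is unaffected by which other queries share the tree.

**Mechanism assignment** is stricter (mirroring the refusal to over-assign
cyclization groups): per subfamily, queries (active-site sequences for
TPS-a/b, full-length proteins for TPS-g) join the labeled panel in a
protein UPGMA tree, and a query takes the label of its smallest enclosing
clade containing labeled leaves only if those labels are unanimous;
conflicts yield cyclization "unresolved" with the substrate union. The
NPP-clade convention (non-acyclic NPP enzymes proceed through
1,6-cyclization of the nerolidyl cation) is encoded in the class catalog.
In recovery simulations, query copies are mutated outside the motif spans:
the metal-binding motifs are under strong purifying selection, and ablating
an anchor tests anchor loss, not mechanism assignment.

## Protein clustering

Centroid-style greedy set cover: proteins ordered by (length descending,
id ascending); the first unassigned protein becomes a representative and
absorbs every unassigned protein passing bidirectional thresholds against
it (coverage >= 0.85 in both directions, identity >= 0.75, E-value floor
1e-5). Pairwise identity and coverage come from a unit-cost global
alignment: identity = matching columns / alignment columns, coverage of
each sequence = residue-to-residue aligned columns / its length. The
ordering rule makes the output independent of input order; singletons are
their own representatives (an unconnected representative marks a unique
sequence).

## Networks and summaries

A typed multigraph: gene nodes (partial genes flagged with a lighter-shade
attribute), chromosome nodes (gray mapping edges), protein nodes for
fl-ORFs with mechanism metadata (blue association edges), homology edges
carrying I′ and the duplication type (green; cross-cultivar homolog edges
permitted), cluster-membership edges to representative nodes, and
characterized-enzyme nodes for panel proteins appearing in clusters.
Color/shade semantics are stored as attributes, never rendered. GraphML
and CX exports round-trip losslessly; SIF carries topology only. Summary
tables report per-cultivar ORF composition, duplicated vs hemizygous
shares among complete genes, homology edge-type composition and
subfamily-by-chromosome counts; percentage columns sum to 100. With a
truth table supplied, per-classifier confusion matrices are added.

## Problem sizes and determinism

The standard end-to-end study uses two cultivars with 60 implants each
(~60 s on one CPU); robustness screens use a compact 30-implant
single-cultivar design per seed over 20 seeds at 2% nucleotide divergence;
mechanism recovery uses 50 replicates at 5% amino-acid divergence over a
6-per-subfamily panel. All randomness flows from one seeded generator per
invocation; identical seeds and designs reproduce outputs byte-for-byte.

## Known limitations

- The spliced aligner assumes exact seed survival; above ~10% nucleotide
  divergence recovery degrades (by design — the family analysis operates
  well below that).
- Exon boundaries adjacent to a substitution are recoverable only up to the
  genuine ambiguity of the alignment; canonical-splice tie-breaking
  resolves the common case but non-canonical boundaries may shift by a few
  bases without changing the frame.
- The E-value models (Karlin–Altschul with fixed ungapped parameters) are
  hit/no-hit screens, not calibrated significance estimates.
- UPGMA assumes rate constancy; it is retained because clade assignment
  must mirror the published procedure, not because it is the best
  phylogenetic estimator.
- Hemizygosity is an assembly-level call: a gene on a primary contig with
  no haplotig counterpart may be truly hemizygous or simply collapsed
  (homozygous) — the two are indistinguishable from the assembly alone.
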