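"""Gene-duplication typing via the coverage-scaled identity statistic I'.

Complete gene regions (fl-ORF and d-ORF) are compared all-against-all with a
Smith-Waterman-style local alignment; a pair with I' above the threshold
(default 80%) is called duplicated. Same-contig pairs are tandem duplicates;
primary<->haplotig pairs whose contigs group to one chromosome are haplotype
(allelic) duplications; everything else above threshold is a tentative
duplication. A complete gene on one haplotype with no haplotype-type partner
on the other is hemizygous.

I' = 100 * I / max(L_q, L_s): the identity count of the best local alignment
scaled by the length of the longer sequence, so a perfect but short partial
overlap is not called a duplication. (The source description of I' is
ambiguous about gap counting and the normalizing length; this choice is
symmetric and coverage-penalizing, and lives in one replaceable function —
alternatives would normalize by n, the alignment length, or by L_q + L_s.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from ._seq import kmer_set, revcomp

DEFAULT_THRESHOLD = 80.0
DEFAULT_E_FLOOR = 1e-5
#: Karlin-Altschul parameters for the +2/-3 DNA scoring used here (ungapped
#: estimates; adequate for the hit/no-hit decision at e_floor)
_KA_LAMBDA = 1.28
_KA_K = 0.46
#: pairs sharing fewer canonical 15-mers than this are skipped in all-vs-all
#: screening; a pair at >=70% identity over >=1 kb shares hundreds
PREFILTER_MIN_SHARED_KMERS = 8
PREFILTER_K = 15


@dataclass
class PairwiseAlignmentStats:
    """Best-local-alignment bookkeeping for one ordered sequence pair."""

    I: int  # identical aligned positions
    n: int  # alignment length including gaps
    L_q: int
    L_s: int
    e_value: float
    strand: str = "+"

    def __post_init__(self):
        if self.I > self.n:
            raise ValueError(f"I={self.I} exceeds alignment length n={self.n}")

    @property
    def I_prime(self) -> float:
        return identity_prime(self)


@dataclass
class DuplicationEdge:
    gene_a: str
    gene_b: str
    I_prime: float
    dup_type: str  # tandem | haplotype | tentative


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def best_local_alignment(query: str, subject: str, e_floor: float = DEFAULT_E_FLOOR,
                         max_hsps: int = 5, max_targets: int = 10,
                         strands: str = "+-") -> list[PairwiseAlignmentStats]:
    """Best local alignments of query vs subject, both strands by default.

    Returns up to ``max_hsps`` HSPs (here: the single optimal local alignment
    per strand — the best colinear chain of one) that pass the E-value floor,
    best first. ``max_targets`` is accepted for interface parity with
    multi-subject searches; a single subject is a single target.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    aligner = _aligner()
    out = []
    for strand in strands:
        sub = subject if strand == "+" else revcomp(subject)
        alns = aligner.align(query, sub)
        try:  # never len(alns): the count of co-optimal paths can overflow
            aln = next(iter(alns))
        except StopIteration:
            continue
        counts = aln.counts()
        ident = counts.identities
        e = _evalue(aln.score, len(query), len(subject))
        if e > e_floor:
            continue
        out.append(PairwiseAlignmentStats(
            I=ident, n=aln.length, L_q=len(query), L_s=len(subject),
            e_value=e, strand=strand))
    out.sort(key=lambda s: (-s.I, s.e_value))
    return out[:max_hsps]


def identity_prime(stats: PairwiseAlignmentStats | None) -> float:
    """I' = 100 * I / max(L_q, L_s); 0 when no alignment exists."""
    if stats is None:
        return 0.0
    if stats.L_q <= 0 or stats.L_s <= 0:
        raise ValueError("sequence lengths must be positive")
    return 100.0 * stats.I / max(stats.L_q, stats.L_s)


def pair_identity_prime(seq_a: str, seq_b: str, e_floor: float = DEFAULT_E_FLOOR,
                        strands: str = "+-") -> float:
    """I' of the best local alignment between two sequences."""
    stats = best_local_alignment(seq_a, seq_b, e_floor=e_floor, strands=strands)
    return identity_prime(stats[0]) if stats else 0.0


def screen_identity_estimate(seq_a: str, seq_b: str) -> tuple[float, str]:
    """Cheap I' estimate from unit-cost global edit distance, per strand;
    returns (estimate, best strand). Dissimilar pairs score far below the
    duplication threshold here (for near-threshold, full-length homologs the
    estimate tracks I' closely), so pairs falling under threshold minus a
    10-point margin skip the exact local alignment."""
    import edlib

    lmax = max(len(seq_a), len(seq_b))
    d_f = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    d_r = edlib.align(seq_a, revcomp(seq_b), mode="NW", task="distance")["editDistance"]
    if d_f <= d_r:
        return 100.0 * (lmax - d_f) / lmax, "+"
    return 100.0 * (lmax - d_r) / lmax, "-"


def _shares_kmers(ka: set, kb: set) -> bool:
    if len(ka) > len(kb):
        ka, kb = kb, ka
    hits = 0
    for km in ka:
        if km in kb:
            hits += 1
            if hits >= PREFILTER_MIN_SHARED_KMERS:
                return True
    return False


def classify_duplication_edges(genes, sequences: dict[str, str], chrom: dict[str, str],
                               threshold: float = DEFAULT_THRESHOLD,
                               e_floor: float = DEFAULT_E_FLOOR,
                               warnings: list | None = None):
    """All-vs-all duplication typing for one cultivar's complete genes.

    ``genes``: GeneRegion list (complete only — fl-ORF and d-ORF; others are
    ignored). ``sequences``: accession -> genomic (unspliced) region sequence.
    ``chrom``: contig_id -> chromosome (missing contigs are classified on
    contig identity alone and logged to ``warnings``).

    Returns (edges, hemizygous set, composition summary). The summary carries
    the percentage of edges per type and the percentage of complete genes
    duplicated vs hemizygous.
    """
    complete = [g for g in genes if g.completeness == "complete"]
    complete.sort(key=lambda g: g.accession)
    ksets = {g.accession: kmer_set(sequences[g.accession], PREFILTER_K, canonical=True)
             for g in complete}

    edges: list[DuplicationEdge] = []
    for i in range(len(complete)):
        for j in range(i + 1, len(complete)):
            a, b = complete[i], complete[j]
            if not _shares_kmers(ksets[a.accession], ksets[b.accession]):
                continue
            est, strand = screen_identity_estimate(sequences[a.accession],
                                                   sequences[b.accession])
            if est < threshold - 10.0:
                continue
            ip = pair_identity_prime(sequences[a.accession], sequences[b.accession],
                                     e_floor=e_floor, strands=strand)
            if ip <= threshold:
                continue
            if a.contig_id == b.contig_id:
                dup_type = "tandem"
            else:
                ca, cb = chrom.get(a.contig_id), chrom.get(b.contig_id)
                if ca is None or cb is None:
                    if warnings is not None:
                        warnings.append(
                            f"{a.accession}/{b.accession}: missing chromosome assignment, "
                            f"typed on contig identity only")
                    dup_type = "tentative"
                elif a.contig_role != b.contig_role and ca == cb and ca != "unplaced":
                    dup_type = "haplotype"
                else:
                    dup_type = "tentative"
            edges.append(DuplicationEdge(a.accession, b.accession, round(ip, 3), dup_type))

    partnered = set()
    for e in edges:
        if e.dup_type == "haplotype":
            partnered.add(e.gene_a)
            partnered.add(e.gene_b)
    hemizygous = {g.accession for g in complete if g.accession not in partnered}

    duplicated = {x for e in edges for x in (e.gene_a, e.gene_b)}
    n_edges = len(edges)
    n_complete = len(complete)
    summary = {
        "n_complete_genes": n_complete,
        "n_edges": n_edges,
        "pct_edges_tandem": _pct(sum(e.dup_type == "tandem" for e in edges), n_edges),
        "pct_edges_haplotype": _pct(sum(e.dup_type == "haplotype" for e in edges), n_edges),
        "pct_edges_tentative": _pct(sum(e.dup_type == "tentative" for e in edges), n_edges),
        "pct_genes_duplicated": _pct(len(duplicated), n_complete),
        "pct_genes_hemizygous": _pct(len(hemizygous), n_complete),
    }
    return edges, hemizygous, summary


def _pct(k: int, n: int) -> float:
    return round(100.0 * k / n, 3) if n else 0.0
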