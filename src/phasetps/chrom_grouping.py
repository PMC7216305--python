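"""Reference-guided chromosome grouping of contigs.

A desk-scale analog of reference-guided contig grouping: each contig is
assigned to the reference chromosome sharing the most chromosome-unique
canonical k-mers with it, with a grouping-confidence score (the winner's
share of all uniquely-matching k-mers). K-mers occurring in more than one
reference chromosome are ignored, which guards against repeat-driven
misassignment. Location and orientation within a chromosome are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import canonical_kmer

DEFAULT_K = 21


@dataclass
class ChromosomeAssignment:
    contig_id: str
    chromosome: str  # chromosome id or "unplaced"
    grouping_score: float  # in [0, 1]; 0.0 when unplaced
    kmer_counts: dict[str, int] = field(default_factory=dict)


class ReferenceKmerIndex:
    """Canonical k-mer -> chromosome map, keeping only chromosome-unique
    k-mers. Any unplaced pseudo-molecule (e.g. "chr00") must be excluded from
    the reference before indexing."""

    def __init__(self, reference: dict[str, str], k: int = DEFAULT_K):
        self.k = k
        index: dict[str, str] = {}
        ambiguous: set[str] = set()
        for chrom, seq in reference.items():
            seen: set[str] = set()
            for i in range(len(seq) - k + 1):
                km = canonical_kmer(seq[i : i + k])
                if km in seen:
                    continue
                seen.add(km)
                if km in ambiguous:
                    continue
                if km in index and index[km] != chrom:
                    ambiguous.add(km)
                    del index[km]
                else:
                    index[km] = chrom
        self._index = index

    def chromosome_of(self, kmer: str) -> str | None:
        return self._index.get(kmer)


def assign_contig_chromosome(contig, reference: dict[str, str] | ReferenceKmerIndex,
                             k: int = DEFAULT_K,
                             warnings: list | None = None) -> ChromosomeAssignment:
    """Assign one contig to its best-supported reference chromosome.

    Counts the contig's distinct canonical k-mers that occur in exactly one
    reference chromosome; the argmax chromosome wins with score = its share.
    No matching k-mer, or a tie for the maximum, yields "unplaced" (ties are
    logged to ``warnings``). Strand-insensitive by canonicalization.
    """
    index = reference if isinstance(reference, ReferenceKmerIndex) else \
        ReferenceKmerIndex(reference, k)
    seq = contig.seq
    if index.k > len(seq):
        raise ValueError(f"k={index.k} larger than contig {contig.id} ({len(seq)} bp)")
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for i in range(len(seq) - index.k + 1):
        km = canonical_kmer(seq[i : i + index.k])
        if km in seen:
            continue
        seen.add(km)
        chrom = index.chromosome_of(km)
        if chrom is not None:
            counts[chrom] = counts.get(chrom, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return ChromosomeAssignment(contig.id, "unplaced", 0.0, counts)
    top = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == top)
    if len(winners) > 1:
        if warnings is not None:
            warnings.append(f"{contig.id}: grouping tie between {winners}, left unplaced")
        return ChromosomeAssignment(contig.id, "unplaced", 0.0, counts)
    return ChromosomeAssignment(contig.id, winners[0], top / total, counts)


def group_contigs(contigs, reference: dict[str, str], k: int = DEFAULT_K,
                  warnings: list | None = None) -> dict[str, ChromosomeAssignment]:
    """Assign every contig; the reference index is built once."""
    index = ReferenceKmerIndex(reference, k)
    return {c.id: assign_contig_chromosome(c, index, k, warnings) for c in contigs}
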