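"""The I' identity statistic and duplication-edge typing."""

import numpy as np
import pytest

from phasetps._seq import random_dna, revcomp
from phasetps.duplication import (DuplicationEdge, PairwiseAlignmentStats,
                                  best_local_alignment, classify_duplication_edges,
                                  identity_prime, pair_identity_prime)
from phasetps.gene_models import GeneRegion
from phasetps.synthetic_data import mutate_sequence


@pytest.fixture(scope="module")
def seq1k():
    return random_dna(np.random.default_rng(0), 1000)


class TestBestLocalAlignment:
    def test_identical_sequences(self, seq1k):
        stats = best_local_alignment(seq1k, seq1k)
        assert stats[0].I == 1000 and stats[0].n == 1000

    def test_reverse_complement_found_on_minus_strand(self, seq1k):
        stats = best_local_alignment(seq1k, revcomp(seq1k))
        assert stats[0].strand == "-" and stats[0].I == 1000

    def test_divergent_pair_identity_band(self, seq1k):
        """A pair at 5% divergence aligns with I/n in [0.93, 0.97]."""
        ok = 0
        for s in range(100):
            mut, _ = mutate_sequence(seq1k, 0.05, [], False, seed=s)
            st = best_local_alignment(seq1k, mut, strands="+")[0]
            ok += 0.93 <= st.I / st.n <= 0.97
        assert ok >= 95

    def test_empty_sequence_rejected(self, seq1k):
        with pytest.raises(ValueError):
            best_local_alignment("", seq1k)


class TestIdentityPrime:
    def test_perfect_duplicate(self):
        st = PairwiseAlignmentStats(I=1000, n=1000, L_q=1000, L_s=1000, e_value=0)
        assert identity_prime(st) == 100.0

    def test_partial_coverage_penalized(self):
        st = PairwiseAlignmentStats(I=100, n=100, L_q=100, L_s=200, e_value=0)
        assert identity_prime(st) == 50.0

    def test_no_alignment_is_zero(self):
        assert identity_prime(None) == 0.0

    def test_invariant_violation(self):
        with pytest.raises(ValueError):
            PairwiseAlignmentStats(I=101, n=100, L_q=100, L_s=100, e_value=0)

    def test_symmetric_under_swap(self, seq1k):
        mut, _ = mutate_sequence(seq1k, 0.03, [], False, seed=4)
        assert pair_identity_prime(seq1k, mut) == pytest.approx(
            pair_identity_prime(mut, seq1k), abs=0.2)


def _regions_and_seqs(rng):
    """Two tandem copies on one contig, an allelic primary/haplotig pair on one
    chromosome, and one unrelated singleton."""
    dup = random_dna(rng, 1200)
    other = random_dna(rng, 1200)
    regions = [
        GeneRegion("G1", "P1", "S1", "primary", "+", [(0, 1200)], "complete", "fl-ORF"),
        GeneRegion("G2", "P1", "S1", "primary", "+", [(5000, 6200)], "complete", "fl-ORF"),
        GeneRegion("G3", "P2", "S1", "primary", "+", [(0, 1200)], "complete", "fl-ORF"),
        GeneRegion("G4", "H1", "S1", "haplotig", "+", [(0, 1200)], "complete", "fl-ORF"),
        GeneRegion("G5", "P3", "S1", "primary", "+", [(0, 1200)], "complete", "fl-ORF"),
        GeneRegion("G6", "P3", "S1", "primary", "+", [(0, 900)], "partial",
                   "not_applicable"),
    ]
    seqs = {"G1": dup, "G2": dup, "G3": other,
            "G4": mutate_sequence(other, 0.01, [], False, seed=1)[0],
            "G5": random_dna(rng, 1200), "G6": random_dna(rng, 900)}
    chrom = {"P1": "chr13", "P2": "chr18", "H1": "chr18", "P3": "chr19"}
    return regions, seqs, chrom


class TestClassifyDuplicationEdges:
    def test_edge_types_and_hemizygosity(self):
        regions, seqs, chrom = _regions_and_seqs(np.random.default_rng(7))
        edges, hemi, summary = classify_duplication_edges(regions, seqs, chrom)
        types = {tuple(sorted((e.gene_a, e.gene_b))): e.dup_type for e in edges}
        assert types == {("G1", "G2"): "tandem", ("G3", "G4"): "haplotype"}
        # G3/G4 are allelic partners; everything else lacks one
        assert hemi == {"G1", "G2", "G5"}
        assert summary["pct_edges_tandem"] + summary["pct_edges_haplotype"] \
            + summary["pct_edges_tentative"] == pytest.approx(100.0, abs=0.1)
        # partial gene G6 never participates
        assert not any("G6" in (e.gene_a, e.gene_b) for e in edges)

    def test_missing_chromosome_assignment_logged(self):
        regions, seqs, chrom = _regions_and_seqs(np.random.default_rng(7))
        del chrom["H1"]
        warnings = []
        edges, _, _ = classify_duplication_edges(regions, seqs, chrom,
                                                 warnings=warnings)
        types = {tuple(sorted((e.gene_a, e.gene_b))): e.dup_type for e in edges}
        assert types[("G3", "G4")] == "tentative"
        assert any("missing chromosome" in w for w in warnings)

    def test_threshold_monotonicity_and_symmetry(self):
        regions, seqs, chrom = _regions_and_seqs(np.random.default_rng(7))
        counts = []
        for thr in (70.0, 80.0, 90.0, 99.9):
            edges, _, _ = classify_duplication_edges(regions, seqs, chrom,
                                                     threshold=thr)
            pairs = {tuple(sorted((e.gene_a, e.gene_b))) for e in edges}
            assert len(pairs) == len(edges)  # no duplicate or self edges
            assert all(a != b for a, b in pairs)
            counts.append(len(edges))
        assert counts == sorted(counts, reverse=True)

    def test_edge_set_invariant_under_input_order(self):
        regions, seqs, chrom = _regions_and_seqs(np.random.default_rng(7))
        fwd, _, _ = classify_duplication_edges(regions, seqs, chrom)
        rev, _, _ = classify_duplication_edges(list(reversed(regions)), seqs, chrom)
        as_set = lambda es: {(tuple(sorted((e.gene_a, e.gene_b))), e.dup_type)
                             for e in es}
        assert as_set(fwd) == as_set(rev)
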