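"""Spliced search, curation, ORF classification and motif scanning."""

import numpy as np
import pytest

from phasetps._seq import random_dna, revcomp
from phasetps.gene_models import (Contig, GeneRegion, annotate_cultivar,
                                  classify_gene_region, curate_hits, scan_motifs,
                                  spliced_align)
from phasetps.synthetic_data import (make_reference_panel, mutate_sequence,
                                     with_oversized_intron)


def _implant_contig(gdna, seed=0, flank=3000):
    rng = np.random.default_rng(seed)
    left = random_dna(rng, flank)
    right = random_dna(rng, flank)
    return Contig("c1", "S1", "primary", left + gdna + right), flank


class TestSplicedAlign:
    def test_verbatim_implant_recovered_exactly(self, panel2):
        tpl = panel2[0]
        contig, off = _implant_contig(tpl.gdna, seed=1)
        hits = spliced_align(tpl.cds, contig, query_id=tpl.id)
        assert len(hits) == 1
        h = hits[0]
        assert h.score == 1.0 and h.strand == "+"
        expect, pos = [], off
        for i, ln in enumerate(tpl.exon_lengths):
            expect.append((pos, pos + ln))
            pos += ln + (tpl.intron_lengths[i] if i < len(tpl.intron_lengths) else 0)
        assert h.exons == expect

    def test_oversized_intron_splits_chain(self, panel2):
        """An intron beyond the 3000 bp search limit is never bridged: the
        locus surfaces as split (or sub-threshold) chains."""
        tpl = with_oversized_intron(panel2[1], seed=3, intron_index=2, length=5000)
        contig, _ = _implant_contig(tpl.gdna, seed=4)
        hits = spliced_align(tpl.cds, contig, query_id=tpl.id)
        for h in hits:
            assert len(h.exons) < len(tpl.exon_lengths)
            gaps = [b[0] - a[1] for a, b in zip(h.exons, h.exons[1:])]
            assert all(g <= 3000 for g in gaps)

    def test_snp_mutated_implant_recovered(self, panel2):
        """At 5% nucleotide divergence the implant is recovered with identity
        >= 0.93 in at least 95% of seeded replicates."""
        tpl = panel2[2]
        ok = 0
        n = 100
        for s in range(n):
            rng = np.random.default_rng(5000 + s)
            ex = [mutate_sequence(e, 0.05, [], False, int(rng.integers(2**31)))[0]
                  for e in tpl.exons]
            iv = [mutate_sequence(i, 0.05, [], False, int(rng.integers(2**31)))[0]
                  for i in tpl.introns]
            g = "".join(x for pair in zip(ex, iv + [""]) for x in pair)
            contig, _ = _implant_contig(g, seed=6000 + s)
            hits = spliced_align(tpl.cds, contig, query_id=tpl.id)
            if hits and hits[0].identity >= 0.93:
                ok += 1
        assert ok / n >= 0.95

    def test_empty_inputs_rejected(self, panel2):
        contig, _ = _implant_contig(panel2[0].gdna)
        with pytest.raises(ValueError):
            spliced_align("", contig)


class TestCurateAndClassify:
    def test_best_coverage_hit_defines_locus_and_order(self, panel2):
        """Overlapping hits merge into one locus defined by the best hit;
        accessions follow (contig, position) order."""
        tpl_a, tpl_b = panel2[0], panel2[1]
        rng = np.random.default_rng(1)
        gap = random_dna(rng, 4000)
        seq = random_dna(rng, 2000) + tpl_a.gdna + gap + tpl_b.gdna + random_dna(rng, 2000)
        contig = Contig("c1", "S1", "primary", seq)
        regions = annotate_cultivar([contig], {t.id: t.cds for t in panel2[:2]})
        assert [r.accession for r in regions] == ["S1TPS001", "S1TPS002"]
        assert regions[0].query_id == tpl_a.id and regions[1].query_id == tpl_b.id
        assert regions[0].start < regions[1].start

    def test_tandem_pair_never_merged(self, panel2):
        tpl = panel2[3]
        rng = np.random.default_rng(2)
        seq = (random_dna(rng, 2000) + tpl.gdna + random_dna(rng, 4000)
               + tpl.gdna + random_dna(rng, 2000))
        contig = Contig("c1", "S1", "primary", seq)
        regions = annotate_cultivar([contig], {tpl.id: tpl.cds})
        assert len(regions) == 2

    @pytest.mark.parametrize("edit,expected", [
        ("none", ("complete", "fl-ORF")),
        ("stop", ("complete", "d-ORF_premature_stop")),
        ("frameshift", ("complete", "d-ORF_frameshift")),
        ("truncate", ("partial", "not_applicable")),
    ])
    def test_orf_classification_rules(self, panel2, edit, expected):
        """7-exon clean frame -> fl-ORF; in-frame TAA -> premature stop; 1 bp
        deletion -> frameshift; <=4 exons without terminal codons -> partial."""
        tpl = panel2[4]
        exons = list(tpl.exons)
        introns = list(tpl.introns)
        if edit == "stop":
            cds, _ = mutate_sequence(tpl.cds, 0.0, [], True, seed=9)
            exons, pos = [], 0
            for ln in tpl.exon_lengths:
                exons.append(cds[pos:pos + ln])
                pos += ln
        elif edit == "frameshift":
            exons[2] = exons[2][:50] + exons[2][51:]
        elif edit == "truncate":
            exons, introns = exons[1:5], introns[1:4]
        g = "".join(x for pair in zip(exons, introns + [""]) for x in pair)
        contig, off = _implant_contig(g, seed=10)
        iv, pos = [], off
        for i, e in enumerate(exons):
            iv.append((pos, pos + len(e)))
            pos += len(e) + (len(introns[i]) if i < len(introns) else 0)
        region = GeneRegion("S1TPS001", "c1", "S1", "primary", "+", iv)
        out = classify_gene_region(region, contig.seq)
        assert (out.completeness, out.orf_class) == expected
        if expected[1] == "fl-ORF":
            assert out.protein == tpl.protein

    def test_classification_idempotent(self, panel2):
        tpl = panel2[5]
        contig, off = _implant_contig(tpl.gdna, seed=11)
        regions = annotate_cultivar([contig], {tpl.id: tpl.cds})
        once = regions[0]
        twice = classify_gene_region(once, contig.seq)
        assert (once.completeness, once.orf_class, once.protein, once.cds) == \
               (twice.completeness, twice.orf_class, twice.protein, twice.cds)

    def test_exon_out_of_bounds_rejected(self):
        region = GeneRegion("x", "c1", "S1", "primary", "+", [(0, 50)])
        with pytest.raises(ValueError, match="bounds"):
            classify_gene_region(region, "ACGT")

    def test_strand_symmetry(self, panel2):
        """Reverse-complementing the contig yields the same loci with flipped
        strand and mirrored coordinates."""
        tpl = panel2[6]
        contig, _ = _implant_contig(tpl.gdna, seed=12)
        fwd = annotate_cultivar([contig], {tpl.id: tpl.cds})
        rc = Contig("c1", "S1", "primary", revcomp(contig.seq))
        rev = annotate_cultivar([rc], {tpl.id: tpl.cds})
        L = len(contig.seq)

        def key(regions, mirror):
            out = []
            for r in regions:
                ex = sorted((L - e, L - s) for s, e in r.exons) if mirror else r.exons
                st = {"+": "-", "-": "+"}[r.strand] if mirror else r.strand
                out.append((tuple(ex), st, r.completeness, r.orf_class, r.cds))
            return sorted(out)

        assert key(fwd, False) == key(rev, True)


class TestScanMotifs:
    def test_ddxxd_reported_at_offset(self):
        prot = "A" * 40 + "DDTYD" + "A" * 40
        hits = scan_motifs(prot)
        assert hits.hits["DDxxD"] == [(40, 45)]

    def test_no_match_on_polyalanine(self):
        assert all(not v for v in scan_motifs("A" * 100).hits.values())

    def test_rxr_only_reported_upstream_of_ddxxd(self):
        with_context = "A" * 10 + "RVR" + "A" * 20 + "DDTYD" + "A" * 20
        assert scan_motifs(with_context).hits["RxR"] == [(10, 13)]
        without = "A" * 10 + "RVR" + "A" * 80 + "DDTYD"
        assert scan_motifs(without).hits["RxR"] == []

    def test_all_panel_proteins_carry_both_anchors(self, panel4):
        for tpl in panel4:
            hits = scan_motifs(tpl.protein, tpl.id)
            assert hits.has("DDxxD") and hits.has("NSE/DTE")

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs("ACDB1")
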