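"""Generator contracts: panel validity, mutation bookkeeping, assembly truth."""

import re

import numpy as np
import pytest
from scipy.stats import binom

from phasetps.io import read_fasta, read_gff3, spliced_sequence
from phasetps.synthetic_data import (build_phased_assembly, make_reference_panel,
                                     mutate_sequence, standard_design)
from phasetps._seq import translate


class TestReferencePanel:
    def test_counts_and_orf_validity(self, panel2):
        assert len(panel2) == 10  # 5 subfamilies x 2
        for tpl in panel2:
            prot = translate(tpl.cds)
            assert prot[-1] == "*" and "*" not in prot[:-1]
            assert tpl.cds.startswith("ATG")

    def test_determinism_byte_identical(self):
        a = make_reference_panel(2, seed=1)
        b = make_reference_panel(2, seed=1)
        assert [(t.id, t.cds, t.introns) for t in a] == \
               [(t.id, t.cds, t.introns) for t in b]

    def test_motifs_present_in_all_proteins(self, panel4):
        for tpl in panel4:
            assert re.search(r"DD..[DE]", tpl.protein), tpl.id
            assert re.search(r"[ND]D..[ST]...E", tpl.protein), tpl.id
            if tpl.subfamily == "TPS-b":
                assert re.search(r"RR.{8}W", tpl.protein), tpl.id

    def test_mechanism_classes_all_covered(self, panel4):
        classes = {t.mechanism_class for t in panel4}
        assert {"a_acyclic_FPP", "a_16_NPP", "a_110_FPP", "a_111_FPP",
                "b_typeI", "b_typeII", "g_GPP", "g_dual", "g_tri"} <= classes

    def test_complete_templates_have_at_least_five_exons(self, panel2):
        assert all(len(t.exon_lengths) >= 5 for t in panel2)


class TestMutateSequence:
    def test_zero_rate_identity(self):
        seq = "ACGT" * 100
        out, log = mutate_sequence(seq, 0.0, [], False, seed=3)
        assert out == seq and log == []

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", 0.5, [], False, seed=0)

    def test_stop_injection_truncates_translation(self, panel2):
        cds = panel2[0].cds
        out, log = mutate_sequence(cds, 0.0, [], True, seed=5)
        assert len(out) == len(cds)
        stops = [e for e in log if e["op"] == "stop"]
        assert len(stops) == 1
        assert len(translate(out, to_stop=True)) < len(translate(cds, to_stop=True))

    def test_indel_log_is_exact(self):
        seq = "ACGT" * 50
        out, log = mutate_sequence(seq, 0.0, [("del", 10, 2)], False, seed=0)
        assert len(out) == len(seq) - 2
        assert log == [{"op": "del", "pos": 10, "ref": seq[10:12]}]

    def test_snp_count_within_binomial_interval(self):
        """Hamming distance to the input follows Binomial(n, rate): over many
        seeds, ~99% of draws fall inside the central 99% binomial interval."""
        n, rate, seeds = 1000, 0.05, 400
        seq = "ACGT" * (n // 4)
        lo, hi = binom.ppf([0.005, 0.995], n, rate)
        inside = 0
        for s in range(seeds):
            out, log = mutate_sequence(seq, rate, [], False, seed=s)
            ham = sum(a != b for a, b in zip(seq, out))
            assert ham == len(log)  # every logged SNP changes the base
            inside += lo <= ham <= hi
        assert inside / seeds >= 0.97


class TestBuildPhasedAssembly:
    def test_standard_design_truth_counts(self, panel4):
        panel = make_reference_panel(8, seed=2)
        design = standard_design(panel, cultivars=("S1",), seed=3)
        asm = build_phased_assembly(panel, design, seed=4)
        truth = asm.truth
        assert len(truth) == 60
        assert (truth.orf_class == "fl-ORF").sum() == 30
        assert truth.orf_class.str.startswith("d-ORF").sum() == 15
        assert (truth.completeness == "partial").sum() == 15

    def test_empty_design_gives_background_only(self, panel2):
        from phasetps.synthetic_data import ContigPlan, Design

        design = Design(contigs=[ContigPlan("S1", "S1_P01", "primary", "chr13")],
                        implants=[])
        asm = build_phased_assembly(panel2, design, seed=1)
        assert len(asm.truth) == 0
        assert len(asm.primary["S1"]["S1_P01"]) > 0

    def test_truth_gff_roundtrips_cds(self, panel2, tmp_path):
        design = standard_design(make_reference_panel(8, seed=5),
                                 cultivars=("S1",), seed=6)
        asm = build_phased_assembly(make_reference_panel(8, seed=5), design, seed=7)
        asm.write(tmp_path)
        contigs = {**read_fasta(tmp_path / "S1_primary.fasta"),
                   **read_fasta(tmp_path / "S1_haplotigs.fasta")}
        genes = read_gff3(tmp_path / "truth.gff3")
        assert len(genes) == len(asm.truth)
        for g in genes:
            cds = spliced_sequence(contigs[g.seqid], g.exons, g.strand)
            assert cds == asm.cds_by_gene[g.gene_id]

    def test_determinism(self):
        panel = make_reference_panel(3, seed=9)
        design = standard_design(panel, cultivars=("S1",), seed=10,
                                 n_fl_pairs=1, n_tandem_groups=1, n_fl_hemi=1,
                                 n_dorf_pairs=1, n_dorf_hemi=1, n_partial=2)
        a = build_phased_assembly(panel, design, seed=11)
        b = build_phased_assembly(panel, design, seed=11)
        assert a.primary == b.primary and a.haplotigs == b.haplotigs
        assert a.truth.equals(b.truth)

    def test_overlapping_implants_rejected(self, panel2):
        from phasetps.synthetic_data import ContigPlan, Design, ImplantSpec

        tpl = panel2[0]
        mk = lambda off, gid: ImplantSpec(
            template_id=tpl.id, cultivar="S1", contig_role="primary",
            contig_id="S1_P01", offset=off, strand="+", gene_id=gid)
        design = Design(contigs=[ContigPlan("S1", "S1_P01", "primary", "chr13")],
                        implants=[mk(1000, "g1"), mk(1200, "g2")])
        with pytest.raises(ValueError, match="overlap"):
            build_phased_assembly(panel2, design, seed=0)

    def test_hemizygosity_rule(self, tiny_run):
        """A complete gene is hemizygous iff no complete copy of its template
        sits on the opposite haplotype of the same cultivar."""
        truth = tiny_run.assembly.truth
        complete = truth[truth.completeness == "complete"]
        for _, row in complete.iterrows():
            partner = complete[(complete.template_id == row.template_id)
                               & (complete.cultivar == row.cultivar)
                               & (complete.role != row.role)]
            assert bool(row.hemizygous) == (len(partner) == 0)
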