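"""Distance phylogenies: JC, progressive MSA, UPGMA, bootstrap, active sites,
subfamily and mechanism assignment."""

import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from phasetps.gene_models import scan_motifs
from phasetps.phylo import (MSA, assign_mechanism, assign_subfamily,
                            bootstrap_support, extract_active_site,
                            jukes_cantor_distance, msa_distance_matrix,
                            progressive_msa, upgma_tree)
from phasetps.mechanisms import MechanismLabel
from phasetps.pipeline import mechanism_recovery


class TestJukesCantor:
    def test_identical_rows_are_zero(self):
        assert jukes_cantor_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_to_1e12(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        expect = -0.75 * math.log(1 - 4 / 3 * 0.10)
        assert abs(jukes_cantor_distance(a, b) - expect) < 1e-12

    def test_gap_sites_excluded(self):
        assert jukes_cantor_distance("AC-T", "ACG-") == 0.0

    def test_saturation_capped_and_logged(self):
        warnings = []
        d = jukes_cantor_distance("AAAA", "CCCC", warnings=warnings)
        assert d == 10.0 and any("saturated" in w for w in warnings)

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor_distance("A---", "-CCC")


class TestProgressiveMSA:
    def test_identical_pair_gap_free(self):
        msa = progressive_msa({"a": "ACGTACGT", "b": "ACGTACGT"}, "DNA")
        assert msa.rows == ["ACGTACGT", "ACGTACGT"]

    def test_single_gap_column_case(self):
        """{ACGT, ACGGT}: one gap column, four matched columns (verified by an
        exhaustive tiny-case dynamic-programming oracle)."""
        msa = progressive_msa({"a": "ACGT", "b": "ACGGT"}, "DNA")
        assert msa.n_columns == 5
        assert sum(x == y for x, y in zip(*msa.rows)) == 4
        assert msa.degapped(0) == "ACGT" and msa.degapped(1) == "ACGGT"

    def test_degapping_recovers_inputs(self, panel2):
        seqs = {t.id: t.cds[:300] for t in panel2[:6]}
        msa = progressive_msa(seqs, "DNA")
        for i, sid in enumerate(msa.ids):
            assert msa.degapped(i) == seqs[sid]
        assert msa.n_columns >= max(len(s) for s in seqs.values())

    def test_deterministic(self, panel2):
        seqs = {t.id: t.protein[:200] for t in panel2[:5]}
        assert progressive_msa(seqs, "protein").rows == \
            progressive_msa(seqs, "protein").rows

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa({}, "DNA")


class TestUPGMA:
    def test_hand_example(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma_tree(d, ["A", "B", "C"])
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        coph = tree.cophenetic_matrix()
        assert coph[0, 1] == 2.0 and coph[0, 2] == 4.0
        assert tree.root.height == 2.0

    def test_two_taxon_cherry(self):
        tree = upgma_tree(np.array([[0.0, 3.0], [3.0, 0.0]]), ["x", "y"])
        assert tree.root.height == 1.5

    def test_matches_independent_average_linkage_on_random_matrices(self):
        """Cophenetic matrices agree with scipy's average-linkage hierarchical
        clustering on 200 random matrices of up to 8 taxa."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            ids = [f"t{i}" for i in range(n)]
            mine = upgma_tree(m, ids).cophenetic_matrix()
            ref = squareform(cophenet(linkage(squareform(m), method="average")))
            assert np.allclose(mine, ref, atol=1e-9)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(5)
        m = rng.random((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = upgma_tree(m, [f"t{i}" for i in range(7)])

        def depths(node, acc, h0):
            if node.is_leaf:
                acc.append(h0)
            for c in node.children:
                depths(c, acc, h0)
            return acc

        # every leaf sits at height 0; root-to-leaf path length = root height
        assert all(l.height == 0 for l in tree.root.leaves())

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            upgma_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            upgma_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])


class TestBootstrap:
    def _separated_msa(self):
        seqs = {f"x{i}": "ACGTACGTACGTACGTACGT" for i in range(4)}
        seqs.update({f"y{i}": "TGCATGCATGCATGCATGCA" for i in range(4)})
        return progressive_msa(seqs, "DNA")

    def test_separated_clusters_get_full_support(self):
        tree = bootstrap_support(self._separated_msa(), replicates=100, seed=1)
        sup = {}

        def walk(n):
            if n.children and n.support is not None:
                sup[n.leaf_names()] = n.support
            for c in n.children:
                walk(c)

        walk(tree.root)
        assert sup[frozenset({"x0", "x1", "x2", "x3"})] == 100.0
        assert sup[frozenset({"y0", "y1", "y2", "y3"})] == 100.0

    def test_seeded_reproducibility(self):
        msa = self._separated_msa()
        assert bootstrap_support(msa, 50, seed=9).newick() == \
            bootstrap_support(msa, 50, seed=9).newick()

    def test_identical_sequences_no_crash(self):
        msa = progressive_msa({f"s{i}": "ACGTACGT" for i in range(5)}, "DNA")
        tree = bootstrap_support(msa, replicates=20, seed=0)
        assert set(tree.ids) == {f"s{i}" for i in range(5)}


class TestActiveSite:
    def test_region_spans_anchor_to_anchor(self):
        prot = "A" * 300 + "DDTYD" + "A" * 135 + "NDTASALAE" + "A" * 50
        region = extract_active_site(prot, scan_motifs(prot))
        assert (region.start, region.end) == (300, 449)
        assert region.seq == prot[300:449]
        assert region.anchors_found == (True, True)

    def test_missing_downstream_anchor_gives_empty_region(self):
        prot = "A" * 50 + "DDTYD" + "A" * 50
        region = extract_active_site(prot, scan_motifs(prot))
        assert region.is_empty and region.anchors_found == (True, False)

    def test_all_panel_proteins_have_regions(self, panel4):
        for tpl in panel4:
            region = extract_active_site(tpl.protein,
                                         scan_motifs(tpl.protein, tpl.id))
            assert not region.is_empty, tpl.id


class TestAssignment:
    def test_query_identical_to_reference(self, panel2):
        refs = {t.id: (t.cds, t.subfamily) for t in panel2}
        queries = {"q1": panel2[3].cds}
        out = assign_subfamily(queries, refs)
        assert out["q1"] == panel2[3].subfamily

    def test_equidistant_query_unresolved(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGT"
        refs = {"r1": (seq, "TPS-a"), "r2": (seq, "TPS-b")}
        warnings = []
        out = assign_subfamily({"q": seq}, refs, warnings=warnings)
        assert out["q"] == "unresolved" and warnings

    def test_no_references_rejected(self):
        with pytest.raises(ValueError):
            assign_subfamily({"q": "ACGT"}, {})

    def test_exact_panel_copies_recover_all_labels(self, panel4):
        assert mechanism_recovery(panel4, aa_divergence=0.0, seed=0) == 1.0

    def test_query_without_active_site_reported(self, panel4):
        sf = "TPS-a"
        panel_map = {}
        for t in panel4:
            if t.subfamily != sf:
                continue
            hits = scan_motifs(t.protein, t.id)
            panel_map[t.id] = (extract_active_site(t.protein, hits).seq, t.mechanism)
        report = []
        out = assign_mechanism({"q_empty": ""}, panel_map, sf, report=report)
        assert out == {} and any("q_empty" in r for r in report)

    def test_conflicting_clade_yields_unresolved(self):
        lab_a = MechanismLabel("TPS-a", frozenset({"FPP"}), "cyc_1_10")
        lab_b = MechanismLabel("TPS-a", frozenset({"NPP"}), "cyc_1_6")
        seq = "MKLFDDTYDAAAPLWNDTASALAEKRV" * 3
        panel_map = {"p1": (seq, lab_a), "p2": (seq, lab_b)}
        out = assign_mechanism({"q": seq}, panel_map, "TPS-a")
        assert out["q"].cyclization == "unresolved"
        assert out["q"].substrates == frozenset({"FPP", "NPP"})
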