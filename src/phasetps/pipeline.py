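"""End-to-end orchestration: simulate -> annotate -> duplicates -> group ->
phylo -> cluster -> network, plus truth-recovery scoring.

Every stage is also usable on its own; this module wires the standard run
used by the CLI (`phasetps run-all`) and the reproduction script, and scores
a run against the generator's truth table (classification accuracy,
duplication edge recall, hemizygosity and chromosome-assignment recovery,
subfamily and mechanism label recovery).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from . import chrom_grouping, clustering, duplication, gene_models, network, phylo
from ._seq import kmer_set, revcomp
from .io import write_fasta, write_tsv
from .synthetic_data import (Assembly, build_phased_assembly, expected_duplication_edges,
                             make_reference_panel, standard_design)


@dataclass
class PipelineResult:
    seed: int
    panel: list
    assembly: Assembly
    regions: dict[str, list]  # cultivar -> GeneRegion list
    assignments: dict  # contig_id -> ChromosomeAssignment
    dup_edges: dict[str, list]  # cultivar -> DuplicationEdge list
    hemizygous: dict[str, set]
    dup_summary: dict[str, dict]
    cross_edges: list
    subfamilies: dict[str, str]  # accession -> subfamily
    mech_labels: dict[str, tuple]  # accession -> (subfamily, MechanismLabel)
    proteins: dict[str, str]
    clusters: list
    graph: object
    summaries: dict
    warnings: list = field(default_factory=list)

    @property
    def all_regions(self) -> list:
        return [r for regs in self.regions.values() for r in regs]

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.assembly.write(os.path.join(outdir, "assembly"))
        rows = [{
            "accession": r.accession, "cultivar": r.cultivar, "contig": r.contig_id,
            "role": r.contig_role, "strand": r.strand, "start": r.start, "end": r.end,
            "n_exons": len(r.exons), "completeness": r.completeness,
            "orf_class": r.orf_class, "subfamily": self.subfamilies.get(r.accession, ""),
            "chromosome": getattr(self.assignments.get(r.contig_id), "chromosome", ""),
        } for r in self.all_regions]
        write_tsv(os.path.join(outdir, "regions.tsv"), pd.DataFrame(rows))
        write_fasta(os.path.join(outdir, "proteins.fasta"), self.proteins)
        reps = {c.representative_id: self.proteins.get(c.representative_id, "")
                for c in self.clusters}
        write_fasta(os.path.join(outdir, "representatives.fasta"),
                    {k: v for k, v in reps.items() if v})
        for fmt, name in (("graphml", "network.graphml"), ("cx", "network.cx"),
                          ("sif", "network.sif")):
            network.export_network(self.graph, os.path.join(outdir, name), fmt)
        for name, df in self.summaries.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(os.path.join(outdir, f"summary_{name}.tsv"), sep="\t")


def _oriented_span(contig_seq: str, region) -> str:
    seq = contig_seq[region.start : region.end]
    return revcomp(seq) if region.strand == "-" else seq


def run_pipeline(seed: int, cultivars: tuple[str, ...] = ("S1", "S2"),
                 snp_rate: float = 0.0, n_per_subfamily: int = 8,
                 dup_threshold: float = 80.0, bootstrap_replicates: int = 0,
                 subfamily_query_batch: int = 25, design_kwargs: dict | None = None,
                 stages: tuple[str, ...] = ("phylo", "cluster", "network")) -> PipelineResult:
    """Run the standard synthetic study end to end.

    ``stages`` controls the optional tail stages (annotation, grouping and
    duplication always run); robustness screens that only score gene classes
    and duplication edges can drop "phylo"/"cluster"/"network" for speed.
    """
    warnings: list = []
    panel = make_reference_panel(n_per_subfamily, seed=seed)
    design = standard_design(panel, cultivars=cultivars, snp_rate=snp_rate,
                             seed=seed + 1, **(design_kwargs or {}))
    assembly = build_phased_assembly(panel, design, seed=seed + 2)
    templates = {t.id: t for t in panel}
    queries = {t.id: t.cds for t in panel}

    # --- discovery + classification -------------------------------------
    regions: dict[str, list] = {}
    contig_objs: dict[str, gene_models.Contig] = {}
    for cv in assembly.cultivars:
        contigs = [gene_models.Contig(cid, cv, "primary", seq)
                   for cid, seq in assembly.primary.get(cv, {}).items()]
        contigs += [gene_models.Contig(cid, cv, "haplotig", seq)
                    for cid, seq in assembly.haplotigs.get(cv, {}).items()]
        for c in contigs:
            contig_objs[c.id] = c
        regions[cv] = gene_models.annotate_cultivar(contigs, queries)

    # --- chromosome grouping --------------------------------------------
    assignments = chrom_grouping.group_contigs(
        list(contig_objs.values()), assembly.reference, warnings=warnings)
    chrom_map = {cid: a.chromosome for cid, a in assignments.items()
                 if a.chromosome != "unplaced"}

    # --- duplication typing ----------------------------------------------
    dup_edges, hemizygous, dup_summary = {}, {}, {}
    region_seqs: dict[str, str] = {}
    for cv in assembly.cultivars:
        seqs = {r.accession: _oriented_span(contig_objs[r.contig_id].seq, r)
                for r in regions[cv]}
        region_seqs.update(seqs)
        e, h, s = duplication.classify_duplication_edges(
            regions[cv], seqs, chrom_map, threshold=dup_threshold, warnings=warnings)
        dup_edges[cv], hemizygous[cv], dup_summary[cv] = e, h, s

    # --- cross-cultivar homology ------------------------------------------
    cross_edges = []
    complete = [r for cv in assembly.cultivars for r in regions[cv]
                if r.completeness == "complete"]
    ksets = {r.accession: kmer_set(region_seqs[r.accession],
                                   duplication.PREFILTER_K, canonical=True)
             for r in complete}
    for i in range(len(complete)):
        for j in range(i + 1, len(complete)):
            a, b = complete[i], complete[j]
            if a.cultivar == b.cultivar:
                continue
            if not duplication._shares_kmers(ksets[a.accession], ksets[b.accession]):
                continue
            est, strand = duplication.screen_identity_estimate(
                region_seqs[a.accession], region_seqs[b.accession])
            if est < dup_threshold - 10.0:
                continue
            ip = duplication.pair_identity_prime(region_seqs[a.accession],
                                                 region_seqs[b.accession],
                                                 strands=strand)
            if ip > dup_threshold:
                cross_edges.append((a.accession, b.accession, round(ip, 3)))

    # --- subfamily + mechanism -------------------------------------------
    subfamilies: dict[str, str] = {}
    mech_labels: dict[str, tuple] = {}
    proteins: dict[str, str] = {}
    clusters: list = []
    graph = None
    summaries: dict = {}
    if "phylo" in stages:
        # nucleotide-level placement against the labeled panel mRNAs (spliced
        # query sequences; intron turnover adds noise without adding signal)
        refs = {t.id: (t.cds, t.subfamily) for t in panel}
        all_regs = [r for cv in assembly.cultivars for r in regions[cv]]
        for start in range(0, len(all_regs), subfamily_query_batch):
            batch = all_regs[start : start + subfamily_query_batch]
            qseqs = {r.accession: r.cds for r in batch}
            subfamilies.update(phylo.assign_subfamily(qseqs, refs, warnings=warnings))

        proteins = {r.accession: r.protein for r in all_regs
                    if r.orf_class == "fl-ORF" and r.protein}
        mech_report: list = []
        for sf in ("TPS-a", "TPS-b", "TPS-g"):
            sf_accs = [acc for acc, s in subfamilies.items()
                       if s == sf and acc in proteins]
            if not sf_accs:
                continue
            use_active_site = sf in ("TPS-a", "TPS-b")
            qmap = {}
            for acc in sf_accs:
                prot = proteins[acc]
                if use_active_site:
                    hits = gene_models.scan_motifs(prot, acc)
                    qmap[acc] = phylo.extract_active_site(prot, hits).seq
                else:
                    qmap[acc] = prot
            panel_map = {}
            for t in panel:
                if t.subfamily != sf:
                    continue
                if use_active_site:
                    hits = gene_models.scan_motifs(t.protein, t.id)
                    seq = phylo.extract_active_site(t.protein, hits).seq
                else:
                    seq = t.protein
                panel_map[t.id] = (seq, t.mechanism)
            labels = phylo.assign_mechanism(qmap, panel_map, sf, report=mech_report)
            for acc, label in labels.items():
                mech_labels[acc] = (sf, label)
        warnings.extend(mech_report)
        for acc, sf in subfamilies.items():
            if acc in proteins and acc not in mech_labels:
                mech_labels.setdefault(acc, (sf, None))

    if "cluster" in stages and proteins:
        pool = dict(proteins)
        pool.update({t.id: t.protein for t in panel})
        clusters = clustering.greedy_cluster(pool)

    if "network" in stages:
        mech_clean = {acc: (sf, lab) for acc, (sf, lab) in mech_labels.items()
                      if lab is not None}
        characterized = {t.id: (t.subfamily, t.mechanism) for t in panel}
        graph = network.build_network(
            [r for cv in assembly.cultivars for r in regions[cv]],
            [e for cv in assembly.cultivars for e in dup_edges[cv]],
            assignments, proteins, mech_clean, clusters,
            hemizygous=frozenset().union(*hemizygous.values()) if hemizygous else frozenset(),
            cross_edges=cross_edges, characterized=characterized)
        summaries = network.summarize_family(graph, truth=assembly.truth)

    return PipelineResult(
        seed=seed, panel=panel, assembly=assembly, regions=regions,
        assignments=assignments, dup_edges=dup_edges, hemizygous=hemizygous,
        dup_summary=dup_summary, cross_edges=cross_edges, subfamilies=subfamilies,
        mech_labels=mech_labels, proteins=proteins, clusters=clusters,
        graph=graph, summaries=summaries, warnings=warnings)


# ---------------------------------------------------------------------------
# mechanism-recovery experiment


def _mutate_protein(protein: str, rate: float, protected: set[int], rng) -> str:
    """Substitute amino acids at the given rate outside protected positions
    (the metal-binding motifs, which are under strong purifying selection and
    anchor the active-site extraction)."""
    import numpy as np  # noqa: F401 (rng comes in seeded)

    aas = phylo.PROTEIN_CODE
    out = list(protein)
    hits = (rng.random(len(out)) < rate).nonzero()[0]
    for pos in hits:
        if int(pos) in protected:
            continue
        choices = [a for a in aas if a != out[pos]]
        out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def mechanism_recovery(panel, aa_divergence: float = 0.05, seed: int = 0) -> float:
    """One replicate of the label-recovery experiment: every panel member of
    the TPS-a/b/g subfamilies is copied at the given amino-acid divergence
    (motifs preserved) and re-assigned against the full panel; returns the
    fraction of copies recovering their true mechanism label."""
    import numpy as np

    rng = np.random.default_rng(seed)
    total = correct = 0
    for sf in ("TPS-a", "TPS-b", "TPS-g"):
        members = [t for t in panel if t.subfamily == sf]
        use_active_site = sf in ("TPS-a", "TPS-b")
        panel_map, queries, truth = {}, {}, {}
        for t in members:
            hits = gene_models.scan_motifs(t.protein, t.id)
            protected = {p for spans in hits.hits.values() for s, e in spans
                         for p in range(s, e)}
            mut = _mutate_protein(t.protein, aa_divergence, protected, rng)
            if use_active_site:
                panel_map[t.id] = (phylo.extract_active_site(t.protein, hits).seq,
                                   t.mechanism)
                qh = gene_models.scan_motifs(mut, f"q_{t.id}")
                queries[f"q_{t.id}"] = phylo.extract_active_site(mut, qh).seq
            else:
                panel_map[t.id] = (t.protein, t.mechanism)
                queries[f"q_{t.id}"] = mut
            truth[f"q_{t.id}"] = t.mechanism.key()
        got = phylo.assign_mechanism(queries, panel_map, sf)
        for qid, key in truth.items():
            total += 1
            lab = got.get(qid)
            correct += bool(lab is not None and lab.key() == key)
    return correct / total if total else 1.0


# ---------------------------------------------------------------------------
# truth-recovery scoring


def match_regions_to_truth(result: PipelineResult) -> pd.DataFrame:
    """One row per truth gene with the overlapping predicted region (if any)."""
    truth = result.assembly.truth
    rows = []
    for _, t in truth.iterrows():
        match = None
        for r in result.regions.get(t.cultivar, []):
            if (r.contig_id == t.contig_id and r.strand == t.strand
                    and r.start < t.end and t.start < r.end):
                match = r
                break
        rows.append({
            "gene_id": t.gene_id, "cultivar": t.cultivar,
            "true_completeness": t.completeness, "true_orf": t.orf_class,
            "true_subfamily": t.subfamily, "mechanism_class": t.mechanism_class,
            "template_id": t.template_id, "chromosome": t.chromosome,
            "contig_id": t.contig_id, "hemizygous": bool(t.hemizygous),
            "accession": match.accession if match else None,
            "pred_completeness": match.completeness if match else None,
            "pred_orf": match.orf_class if match else None,
        })
    return pd.DataFrame(rows)


def evaluate_run(result: PipelineResult) -> dict:
    """Recovery metrics of a run against its own truth table."""
    matched = match_regions_to_truth(result)
    found = matched[matched.accession.notna()]
    n_truth = len(matched)
    class_ok = ((found.pred_completeness == found.true_completeness)
                & (found.pred_orf == found.true_orf)).sum()
    acc_of = dict(zip(matched.gene_id, matched.accession))
    gene_of = {v: k for k, v in acc_of.items() if v is not None}

    edge_recall_num = edge_recall_den = 0
    edge_type_ok = True
    pred_minus_truth = 0
    hemi_exact = True
    for cv in result.assembly.cultivars:
        truth_edges = {(a, b): kind for a, b, kind
                       in expected_duplication_edges(result.assembly.truth, cv)}
        pred_edges = {}
        for e in result.dup_edges[cv]:
            ga, gb = gene_of.get(e.gene_a), gene_of.get(e.gene_b)
            if ga is None or gb is None:
                continue
            pred_edges[tuple(sorted((ga, gb)))] = e.dup_type
        edge_recall_den += len(truth_edges)
        for pair, kind in truth_edges.items():
            if pair in pred_edges:
                edge_recall_num += 1
                if pred_edges[pair] != kind:
                    edge_type_ok = False
        pred_minus_truth += len(set(pred_edges) - set(truth_edges))
        truth_hemi = set(result.assembly.truth[
            (result.assembly.truth.cultivar == cv)
            & result.assembly.truth.hemizygous].gene_id)
        pred_hemi = {gene_of.get(a) for a in result.hemizygous[cv]}
        if pred_hemi != truth_hemi:
            hemi_exact = False

    truth = result.assembly.truth
    bearing = truth[["contig_id", "chromosome"]].drop_duplicates()
    chrom_ok = sum(
        getattr(result.assignments.get(r.contig_id), "chromosome", None) == r.chromosome
        for r in bearing.itertuples())

    sf_num = sf_den = 0
    mech_num = mech_den = 0
    if result.subfamilies:
        for r in matched.itertuples():
            if r.accession is None:
                continue
            sf_den += 1
            sf_num += result.subfamilies.get(r.accession) == r.true_subfamily
            if (r.true_orf == "fl-ORF" and r.pred_orf == "fl-ORF"
                    and r.true_subfamily in ("TPS-a", "TPS-b", "TPS-g")):
                got = result.mech_labels.get(r.accession)
                if got and got[1] is not None:
                    mech_den += 1
                    truth_label = next(t.mechanism for t in result.panel
                                       if t.id == r.template_id)
                    mech_num += got[1].key() == truth_label.key()

    return {
        "n_truth_genes": n_truth,
        "n_detected": int(len(found)),
        "classification_accuracy": class_ok / n_truth if n_truth else 1.0,
        "duplication_edge_recall": (edge_recall_num / edge_recall_den
                                    if edge_recall_den else 1.0),
        "duplication_extra_edges": pred_minus_truth,
        "duplication_types_consistent": edge_type_ok,
        "hemizygous_exact": hemi_exact,
        "chromosome_accuracy": chrom_ok / len(bearing) if len(bearing) else 1.0,
        "subfamily_accuracy": sf_num / sf_den if sf_den else None,
        "mechanism_accuracy": mech_num / mech_den if mech_den else None,
    }
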