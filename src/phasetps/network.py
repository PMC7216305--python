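"""Typed comparative networks over genes, chromosomes, proteins and clusters.

Nodes: gene (complete or partial; partial flagged with a lighter shade
attribute), chromosome, protein (fl-ORF products with mechanism metadata)
and cluster representative. Edges: chromosome_mapping (gray), homology
(green; carries I' and the duplication type), protein_association (blue) and
cluster_membership. Presentation semantics (colors/shades) are stored as
attributes, not rendered. Exports: GraphML and CX (lossless round-trip),
SIF (topology only) and node/edge TSV.
"""

from __future__ import annotations

import json
import os

import networkx as nx
import pandas as pd

EDGE_TYPES = ("chromosome_mapping", "homology", "protein_association", "cluster_membership")
NODE_TYPES = ("gene", "chromosome", "protein", "representative", "characterized_enzyme")

_NODE_COLOR = {"gene": "cultivar", "chromosome": "pink", "protein": "blue",
               "representative": "triangle"}
_EDGE_COLOR = {"chromosome_mapping": "gray", "homology": "green",
               "protein_association": "blue", "cluster_membership": "black"}


def build_network(regions, dup_edges, assignments, proteins, mech_labels,
                  clusters, hemizygous=frozenset(), cross_edges=(),
                  characterized=None) -> nx.MultiGraph:
    """Assemble one pipeline run into a typed multigraph.

    regions: GeneRegion list (all cultivars). dup_edges: DuplicationEdge list
    (within-cultivar). assignments: contig_id -> ChromosomeAssignment.
    proteins: gene accession -> protein sequence (fl-ORF only). mech_labels:
    accession -> (subfamily, MechanismLabel). clusters: Cluster list over
    protein accessions. cross_edges: (gene_a, gene_b, I') cross-cultivar
    homolog pairs. characterized: id -> (subfamily, MechanismLabel) for
    reference enzymes that may appear as cluster members.
    """
    characterized = characterized or {}
    G = nx.MultiGraph()
    subfam = {acc: sf for acc, (sf, _) in mech_labels.items()}
    for r in regions:
        G.add_node(r.accession, node_type="gene", cultivar=r.cultivar,
                   contig=r.contig_id, contig_role=r.contig_role,
                   start=int(r.start), end=int(r.end), strand=r.strand,
                   completeness=r.completeness, orf_class=r.orf_class,
                   subfamily=subfam.get(r.accession, ""),
                   shade="light" if r.completeness == "partial" else "full",
                   hemizygous=bool(r.accession in hemizygous))
        asn = assignments.get(r.contig_id)
        if asn is not None and asn.chromosome != "unplaced":
            if not G.has_node(asn.chromosome):
                G.add_node(asn.chromosome, node_type="chromosome", color="pink")
            G.add_edge(r.accession, asn.chromosome, key="chromosome_mapping",
                       edge_type="chromosome_mapping", color="gray",
                       grouping_score=float(asn.grouping_score))
    for e in dup_edges:
        G.add_edge(e.gene_a, e.gene_b, key="homology", edge_type="homology",
                   color="green", I_prime=float(e.I_prime), dup_type=e.dup_type)
    for a, b, ip in cross_edges:
        G.add_edge(a, b, key="homology", edge_type="homology", color="green",
                   I_prime=float(ip), dup_type="cross_cultivar")
    for acc, seq in proteins.items():
        pid = f"{acc}.p"
        sf, label = mech_labels.get(acc, ("", None))
        G.add_node(pid, node_type="protein", color="blue", gene=acc,
                   length=len(seq), subfamily=sf,
                   substrates="+".join(sorted(label.substrates)) if label else "",
                   cyclization=label.cyclization if label else "",
                   product_note=label.product_note if label else "")
        G.add_edge(acc, pid, key="protein_association",
                   edge_type="protein_association", color="blue")
    for cl in clusters:
        rid = f"rep.{cl.representative_id}"
        G.add_node(rid, node_type="representative", shape="triangle",
                   representative=cl.representative_id, size=len(cl.member_ids),
                   mean_identity=float(cl.mean_identity))
        for m in cl.member_ids:
            if m in characterized:
                if not G.has_node(m):
                    sf, label = characterized[m]
                    G.add_node(m, node_type="characterized_enzyme", subfamily=sf,
                               substrates="+".join(sorted(label.substrates)),
                               cyclization=label.cyclization,
                               product_note=label.product_note, shade="enlarged")
                G.add_edge(m, rid, key="cluster_membership",
                           edge_type="cluster_membership", color="black")
                continue
            pid = f"{m}.p"
            if G.has_node(pid):
                G.add_edge(pid, rid, key="cluster_membership",
                           edge_type="cluster_membership", color="black")
    validate_network(G)
    return G


def validate_network(G: nx.MultiGraph) -> None:
    """Referential integrity + closed type sets."""
    for n, data in G.nodes(data=True):
        if data.get("node_type") not in NODE_TYPES:
            raise ValueError(f"node {n!r} has unknown type {data.get('node_type')!r}")
    for u, v, data in G.edges(data=True):
        if data.get("edge_type") not in EDGE_TYPES:
            raise ValueError(f"edge {u}-{v} has unknown type {data.get('edge_type')!r}")
        if not (G.has_node(u) and G.has_node(v)):
            raise ValueError(f"dangling edge {u}-{v}")


# ---------------------------------------------------------------------------
# summaries


def summarize_family(G: nx.MultiGraph, truth: pd.DataFrame | None = None) -> dict:
    """Summary tables: per-cultivar ORF composition, duplication/hemizygosity
    among complete genes, homology edge-type composition, and subfamily-by-
    chromosome counts. With a truth table, adds classification confusion
    matrices (predicted vs truth) for completeness and ORF class."""
    genes = [(n, d) for n, d in G.nodes(data=True) if d.get("node_type") == "gene"]
    rows = []
    cultivars = sorted({d["cultivar"] for _, d in genes})
    for cv in cultivars:
        sub = [d for _, d in genes if d["cultivar"] == cv]
        n = len(sub)
        n_fl = sum(d["orf_class"] == "fl-ORF" for d in sub)
        n_d = sum(d["orf_class"].startswith("d-ORF") for d in sub)
        n_part = sum(d["completeness"] == "partial" for d in sub)
        rows.append({
            "cultivar": cv, "total_regions": n, "n_fl_orf": n_fl, "n_d_orf": n_d,
            "n_partial": n_part,
            "pct_fl_orf": _pct(n_fl, n), "pct_d_orf": _pct(n_d, n),
            "pct_partial": _pct(n_part, n)})
    orf_table = pd.DataFrame(rows)

    dup_rows, edge_rows = [], []
    for cv in cultivars:
        accs = {n for n, d in genes if d["cultivar"] == cv}
        complete = {n for n, d in genes
                    if d["cultivar"] == cv and d["completeness"] == "complete"}
        dup_edges = [(u, v, d) for u, v, d in G.edges(data=True)
                     if d.get("edge_type") == "homology"
                     and u in accs and v in accs
                     and d.get("dup_type") != "cross_cultivar"]
        duplicated = {x for u, v, _ in dup_edges for x in (u, v)}
        hemi = {n for n, d in genes if d["cultivar"] == cv and d.get("hemizygous")}
        nc = len(complete)
        dup_rows.append({
            "cultivar": cv, "n_complete": nc,
            "pct_duplicated": _pct(len(duplicated & complete), nc),
            "pct_hemizygous": _pct(len(hemi & complete), nc)})
        ne = len(dup_edges)
        edge_rows.append({
            "cultivar": cv, "n_edges": ne,
            "pct_tandem": _pct(sum(d["dup_type"] == "tandem" for *_, d in dup_edges), ne),
            "pct_haplotype": _pct(sum(d["dup_type"] == "haplotype" for *_, d in dup_edges), ne),
            "pct_tentative": _pct(sum(d["dup_type"] == "tentative" for *_, d in dup_edges), ne)})
    dup_table = pd.DataFrame(dup_rows)
    edge_table = pd.DataFrame(edge_rows)

    chrom_of = {}
    for u, v, d in G.edges(data=True):
        if d.get("edge_type") == "chromosome_mapping":
            gene, chrom = (u, v) if G.nodes[u].get("node_type") == "gene" else (v, u)
            chrom_of[gene] = chrom
    sc_rows = []
    for acc, d in genes:
        sc_rows.append({"cultivar": d["cultivar"],
                        "subfamily": d.get("subfamily") or "unassigned",
                        "chromosome": chrom_of.get(acc, "unplaced")})
    subfam_by_chrom = (pd.DataFrame(sc_rows)
                       .value_counts().rename("n_genes").reset_index()
                       .sort_values(["cultivar", "chromosome", "subfamily"])
                       .reset_index(drop=True)
                       if sc_rows else pd.DataFrame(
                           columns=["cultivar", "subfamily", "chromosome", "n_genes"]))

    out = {"orf_classes": orf_table, "duplication": dup_table,
           "edge_composition": edge_table, "subfamily_by_chromosome": subfam_by_chrom}

    if truth is not None and len(genes):
        pred = []
        for acc, d in genes:
            hit = truth[(truth.contig_id == d["contig"]) & (truth.strand == d["strand"])
                        & (truth.start < d["end"]) & (d["start"] < truth.end)]
            if len(hit) == 1:
                row = hit.iloc[0]
                pred.append({"accession": acc,
                             "pred_completeness": d["completeness"],
                             "true_completeness": row.completeness,
                             "pred_orf": d["orf_class"], "true_orf": row.orf_class})
        pred = pd.DataFrame(pred)
        if len(pred):
            out["confusion_completeness"] = pd.crosstab(
                pred.true_completeness, pred.pred_completeness)
            out["confusion_orf"] = pd.crosstab(pred.true_orf, pred.pred_orf)
    return out


def _pct(k: int, n: int) -> float:
    return round(100.0 * k / n, 3) if n else 0.0


# ---------------------------------------------------------------------------
# export / import


def export_network(G: nx.MultiGraph, path: str | os.PathLike, fmt: str) -> None:
    fmt = fmt.lower()
    if fmt == "graphml":
        H = nx.MultiGraph()
        H.add_nodes_from((n, _clean(d)) for n, d in G.nodes(data=True))
        for u, v, k, d in G.edges(keys=True, data=True):
            H.add_edge(u, v, key=k, **_clean(d))
        nx.write_graphml(H, str(path))
    elif fmt == "cx":
        with open(path, "w") as fh:
            json.dump(to_cx(G), fh)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in G.edges(data=True):
                fh.write(f"{u}\t{d.get('edge_type', 'link')}\t{v}\n")
    elif fmt == "tsv":
        base = str(path)
        stem = base[:-4] if base.endswith(".tsv") else base
        nodes = pd.DataFrame([{"id": n, **_clean(d)} for n, d in G.nodes(data=True)])
        edges = pd.DataFrame([{"source": u, "target": v, **_clean(d)}
                              for u, v, d in G.edges(data=True)])
        nodes.to_csv(stem + ".nodes.tsv", sep="\t", index=False)
        edges.to_csv(stem + ".edges.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r} (GraphML, CX, SIF, TSV)")


def _clean(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if v is None:
            continue
        out[k] = v if isinstance(v, (str, int, float, bool)) else str(v)
    return out


def import_graphml(path: str | os.PathLike) -> nx.MultiGraph:
    return nx.read_graphml(str(path), force_multigraph=True)


def to_cx(G: nx.MultiGraph) -> list[dict]:
    """CX aspect list: nodes, edges, nodeAttributes, edgeAttributes."""
    node_ids = {n: i for i, n in enumerate(G.nodes())}
    nodes = [{"@id": i, "n": str(n)} for n, i in node_ids.items()]
    edges, node_attrs, edge_attrs = [], [], []
    for n, d in G.nodes(data=True):
        for k, v in _clean(d).items():
            node_attrs.append({"po": node_ids[n], "n": k, "v": v})
    for eid, (u, v, d) in enumerate(G.edges(data=True)):
        edges.append({"@id": eid, "s": node_ids[u], "t": node_ids[v],
                      "i": d.get("edge_type", "link")})
        for k, val in _clean(d).items():
            edge_attrs.append({"po": eid, "n": k, "v": val})
    return [
        {"metaData": [{"name": "nodes", "elementCount": len(nodes)},
                      {"name": "edges", "elementCount": len(edges)},
                      {"name": "nodeAttributes", "elementCount": len(node_attrs)},
                      {"name": "edgeAttributes", "elementCount": len(edge_attrs)}]},
        {"nodes": nodes},
        {"edges": edges},
        {"nodeAttributes": node_attrs},
        {"edgeAttributes": edge_attrs},
        {"status": [{"error": "", "success": True}]},
    ]


def from_cx(aspects: list[dict]) -> nx.MultiGraph:
    nodes = edges = node_attrs = edge_attrs = None
    for aspect in aspects:
        nodes = aspect.get("nodes", nodes)
        edges = aspect.get("edges", edges)
        node_attrs = aspect.get("nodeAttributes", node_attrs)
        edge_attrs = aspect.get("edgeAttributes", edge_attrs)
    G = nx.MultiGraph()
    id_to_name = {}
    for n in nodes or []:
        id_to_name[n["@id"]] = n["n"]
        G.add_node(n["n"])
    for a in node_attrs or []:
        G.nodes[id_to_name[a["po"]]][a["n"]] = a["v"]
    edge_attr_map: dict[int, dict] = {}
    for a in edge_attrs or []:
        edge_attr_map.setdefault(a["po"], {})[a["n"]] = a["v"]
    for e in edges or []:
        attrs = edge_attr_map.get(e["@id"], {})
        G.add_edge(id_to_name[e["s"]], id_to_name[e["t"]],
                   key=attrs.get("edge_type", e.get("i", "link")), **attrs)
    return G


def import_cx(path: str | os.PathLike) -> nx.MultiGraph:
    with open(path) as fh:
        return from_cx(json.load(fh))


# ---------------------------------------------------------------------------
# representative lookup


def query_representatives(query: str, representatives: dict[str, str],
                          clusters, mech_labels) -> dict:
    """Find the best-matching cluster representative for a protein: the
    package's analog of the BLAST lookup against the representative set.
    Returns representative id, identity, cluster members and mechanism
    metadata of the representative (when it has any)."""
    from .clustering import pair_identity_coverage

    if not representatives:
        raise ValueError("no representative sequences supplied")
    best = None
    for rid in sorted(representatives):
        ident, cov_q, cov_r, _ = pair_identity_coverage(query, representatives[rid])
        if best is None or ident > best[0]:
            best = (ident, rid)
    ident, rid = best
    cluster = next((c for c in clusters if c.representative_id == rid), None)
    sf, label = mech_labels.get(rid, ("", None))
    return {
        "representative": rid,
        "identity": round(ident, 4),
        "members": list(cluster.member_ids) if cluster else [rid],
        "subfamily": sf,
        "substrates": sorted(label.substrates) if label else [],
        "cyclization": label.cyclization if label else "",
        "product_note": label.product_note if label else "",
    }
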