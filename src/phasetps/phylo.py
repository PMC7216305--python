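"""Phylogeny-based subfamily and mechanism prediction.

Distance phylogenies exactly as the annotation procedure prescribes: a
deterministic progressive multiple alignment (UPGMA guide tree on k-mer
distances, vectorized profile-profile dynamic programming with linear gap
costs), Jukes-Cantor distances for nucleotide alignments (p-distance for
proteins), UPGMA agglomeration with lexicographic tie-breaking, and
nonparametric bootstrap (column resampling) for branch support. Subfamilies
are inherited from the nearest labeled leaf by patristic distance; the
carbocation-mechanism label of a query is the unanimous label of its
smallest enclosing clade that contains labeled references — conflicting
clades yield an unresolved cyclization, never an over-assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanisms import MechanismLabel

DNA_CODE = "ACGT"
PROTEIN_CODE = "ACDEFGHIKLMNPQRSTVWY"
JC_CAP = 10.0  # saturated-distance cap (p >= 0.75), logged when applied


# ---------------------------------------------------------------------------
# alignment containers


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def row_of(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def _encode(rows: list[str], alphabet: str) -> np.ndarray:
    lut = np.full(256, len(alphabet), dtype=np.uint8)  # gap/unknown -> A
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    return np.vstack([lut[np.frombuffer(r.encode(), dtype=np.uint8)] for r in rows])


# ---------------------------------------------------------------------------
# distances


def jukes_cantor_distance(a: str, b: str, cap: float = JC_CAP,
                          warnings: list | None = None) -> float:
    """Jukes-Cantor distance between two aligned nucleotide rows.

    Sites where either row is a gap are excluded. d = -(3/4) ln(1 - (4/3) p)
    over the comparable sites; p >= 0.75 saturates the correction and is
    capped at ``cap`` (logged).
    """
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    comparable = diff = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        diff += x != y
    if comparable == 0:
        raise ValueError("no comparable (gap-free) sites between rows")
    p = diff / comparable
    if p >= 0.75:
        if warnings is not None:
            warnings.append(f"saturated JC distance (p={p:.3f}), capped at {cap}")
        return cap
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def msa_distance_matrix(msa: MSA, model: str = "jc", cap: float = JC_CAP) -> np.ndarray:
    """Pairwise distance matrix from an alignment.

    "jc": nucleotide Jukes-Cantor over sites where both rows are residues.
    "p": protein p-distance (no multiple-hit correction) over columns where
    either row is a residue, with one-sided gap columns counted as
    differences — short regions that overlap only at conserved motifs would
    otherwise look spuriously close.
    """
    alphabet = DNA_CODE if model == "jc" else PROTEIN_CODE
    enc = _encode(msa.rows, alphabet)
    gap = len(alphabet)
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i in range(n):
        ri = enc[i]
        if model == "jc":
            valid = (ri != gap) & (enc[i + 1:] != gap)
        else:
            valid = (ri != gap) | (enc[i + 1:] != gap)
        diff = valid & (ri != enc[i + 1:])
        comp = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(comp > 0, diff.sum(axis=1) / np.maximum(comp, 1), 0.0)
        if model == "jc":
            row = np.where(p >= 0.75, cap, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.7499) / 3.0))
        else:
            row = p
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return d


def kmer_distance(seq_a: str, seq_b: str, k: int) -> float:
    sa = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    sb = {seq_b[i : i + k] for i in range(len(seq_b) - k + 1)}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None  # leaf name; None for internal nodes
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0  # ultrametric height above the leaves
    support: float | None = None  # bootstrap %, internal nodes only
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())


@dataclass
class Tree:
    root: TreeNode
    ids: list[str]

    def __post_init__(self):
        self._leaf_map = {l.name: l for l in self.root.leaves()}

    def leaf(self, name: str) -> TreeNode:
        return self._leaf_map[name]

    def newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = max(0.0, parent_height - node.height)
            if node.is_leaf:
                return f"{node.name}:{bl:.6f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            sup = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){sup}:{bl:.6f}"

        return fmt(self.root, self.root.height) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Leaf sets of internal (non-root, non-leaf) nodes."""
        out = set()

        def walk(node: TreeNode):
            if node.is_leaf:
                return
            if node is not self.root:
                out.add(node.leaf_names())
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def cophenetic_matrix(self) -> np.ndarray:
        """Patristic distances between leaves (for an ultrametric tree,
        twice the height of the most recent common ancestor)."""
        idx = {name: i for i, name in enumerate(self.ids)}
        n = len(self.ids)
        d = np.zeros((n, n))

        def walk(node: TreeNode):
            if node.is_leaf:
                return [node.name]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
            return [x for g in groups for x in g]

        walk(self.root)
        return d


def upgma_tree(dist: np.ndarray, ids: list[str]) -> Tree:
    """UPGMA agglomeration of a symmetric distance matrix.

    Cluster heights are half the merge distance (ultrametric output);
    arithmetic-average linkage; ties are broken toward the pair whose
    lexicographically smallest member id is smallest (then the next).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(ids):
        raise ValueError("distance matrix must be square and match ids")
    if n == 0:
        raise ValueError("empty distance matrix")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(dist < 0):
        raise ValueError("negative distances are invalid")

    nodes = {i: TreeNode(name=ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    mins = {i: ids[i] for i in range(n)}  # lexicographically smallest member
    D = {frozenset((i, j)): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        best = None
        for pair, d in D.items():
            i, j = sorted(pair)
            key = (d, *sorted((mins[i], mins[j])))
            if best is None or key < best[0]:
                best = (key, i, j, d)
        _, i, j, d = best
        new = TreeNode(children=[nodes[i], nodes[j]], height=d / 2.0)
        nodes[i].parent = nodes[j].parent = new
        size_new = sizes[i] + sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = D.pop(frozenset((i, k)))
            djk = D.pop(frozenset((j, k)))
            D[frozenset((next_id, k))] = (sizes[i] * dik + sizes[j] * djk) / size_new
        del D[frozenset((i, j))]
        del nodes[i], nodes[j], sizes[i], sizes[j]
        nodes[next_id] = new
        sizes[next_id] = size_new
        mins[next_id] = min(mins.pop(i), mins.pop(j))
        next_id += 1
    return Tree(root=nodes.popitem()[1], ids=list(ids))


# ---------------------------------------------------------------------------
# progressive alignment


def _profile_counts(enc: np.ndarray, n_symbols: int) -> np.ndarray:
    L = enc.shape[1]
    counts = np.zeros((L, n_symbols), dtype=np.int32)
    for s in range(n_symbols):
        counts[:, s] = (enc == s).sum(axis=0)
    return counts


def _align_profiles(rows_a: list[str], rows_b: list[str], alphabet: str,
                    match: int = 2, mismatch: int = -1, gap: int = 2):
    """Global profile-profile alignment (linear gap costs); returns the two
    row groups re-expanded to the merged alignment."""
    A = len(alphabet)
    ea = _encode(rows_a, alphabet)
    eb = _encode(rows_b, alphabet)
    # float64 throughout: counts and scores are small integers, represented
    # exactly, and float matmul uses BLAS (integer matmul does not)
    ca = _profile_counts(ea, A).astype(np.float64)
    cb = _profile_counts(eb, A).astype(np.float64)
    # column score: sum over residue pairs, gaps contributing zero =
    # (match-mismatch) * ca cb^T + mismatch * sa sb^T, folded into one matmul
    # via an augmented residue-count column
    ca_aug = np.hstack([ca * (match - mismatch), ca.sum(axis=1, keepdims=True)])
    cb_aug = np.hstack([cb, cb.sum(axis=1, keepdims=True) * mismatch])
    S = ca_aug @ cb_aug.T
    g1 = float(gap * len(rows_b))  # advancing in A against gaps in B
    g2 = float(gap * len(rows_a))
    L1, L2 = ca.shape[0], cb.shape[0]
    H = np.empty((L1 + 1, L2 + 1), dtype=np.float64)
    H[0, :] = -g2 * np.arange(L2 + 1)
    ramp = g2 * np.arange(L2 + 1, dtype=np.float64)
    base = np.empty(L2 + 1, dtype=np.float64)
    scratch = np.empty(L2, dtype=np.float64)
    for i in range(1, L1 + 1):
        prev = H[i - 1]
        base[0] = prev[0] - g1
        np.add(prev[:-1], S[i - 1], out=base[1:])
        np.subtract(prev[1:], g1, out=scratch)
        np.maximum(base[1:], scratch, out=base[1:])
        # H[i, j] = max_{k<=j} base[k] - g2*(j-k)
        base += ramp
        np.maximum.accumulate(base, out=H[i])
        H[i] -= ramp
    # traceback (diag > up > left on ties)
    i, j = L1, L2
    path = []
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + S[i - 1, j - 1]:
            path.append("D")
            i -= 1
            j -= 1
        elif i > 0 and h == H[i - 1, j] - g1:
            path.append("U")
            i -= 1
        else:
            path.append("L")
            j -= 1
    path.reverse()
    path = np.array(path)
    out_a = _expand(rows_a, path, "U")
    out_b = _expand(rows_b, path, "L")
    return out_a, out_b


def _expand(rows: list[str], path: np.ndarray, own_gapless: str) -> list[str]:
    """Insert gap columns where the path advances only the other profile."""
    mask = (path == "D") | (path == own_gapless)
    n, L = len(rows), len(path)
    out = np.full((n, L), ord("-"), dtype=np.uint8)
    src = np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    out[:, mask] = src
    return [row.tobytes().decode() for row in out]


def progressive_msa(seqs: dict[str, str], alphabet: str = "DNA",
                    guide_k: int | None = None) -> MSA:
    """Deterministic progressive multiple alignment.

    Pairwise profile merges follow a UPGMA guide tree built on k-mer
    distances (k=6 for DNA, k=3 for proteins by default). Degapping any row
    recovers the corresponding input sequence.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    ids = list(seqs.keys())
    if len(ids) == 1:
        return MSA(ids=ids, rows=[seqs[ids[0]]])
    code = DNA_CODE if alphabet == "DNA" else PROTEIN_CODE
    k = guide_k or (6 if alphabet == "DNA" else 3)
    n = len(ids)
    ksets = {i: {seqs[ids[i]][p : p + k] for p in range(len(seqs[ids[i]]) - k + 1)}
             for i in range(n)}
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = ksets[i], ksets[j]
            d = 1.0 if not sa or not sb else 1.0 - len(sa & sb) / min(len(sa), len(sb))
            dist[i, j] = dist[j, i] = d
    guide = upgma_tree(dist, ids)

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [seqs[node.name]]
        (ids_a, rows_a) = merge(node.children[0])
        (ids_b, rows_b) = merge(node.children[1])
        rows_a, rows_b = _align_profiles(rows_a, rows_b, code)
        return ids_a + ids_b, rows_a + rows_b

    out_ids, out_rows = merge(guide.root)
    order = {name: i for i, name in enumerate(out_ids)}
    rows = [out_rows[order[name]] for name in ids]
    return MSA(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(msa: MSA, replicates: int = 100, seed: int = 0,
                      model: str = "jc") -> Tree:
    """UPGMA tree from the alignment with bootstrap supports.

    Columns are resampled with replacement ``replicates`` times; the support
    of each internal bipartition of the original tree is the percentage of
    replicate trees containing it. Seeded and bit-reproducible.
    """
    base = upgma_tree(msa_distance_matrix(msa, model=model), msa.ids)
    if replicates <= 0:
        return base
    rng = np.random.default_rng(seed)
    L = msa.n_columns
    counts: dict[frozenset, int] = {bp: 0 for bp in base.bipartitions()}
    enc_rows = np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows])
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep_rows = [row.tobytes().decode("latin1") for row in enc_rows[:, cols]]
        rep = MSA(ids=list(msa.ids), rows=rep_rows)
        rep_tree = upgma_tree(msa_distance_matrix(rep, model=model), rep.ids)
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    def annotate(node: TreeNode):
        if node.is_leaf:
            return
        if node is not base.root:
            bp = node.leaf_names()
            node.support = round(100.0 * counts.get(bp, 0) / replicates, 3)
        for c in node.children:
            annotate(c)

    annotate(base.root)
    return base


# ---------------------------------------------------------------------------
# active sites and label assignment


@dataclass
class ActiveSiteRegion:
    protein_id: str
    start: int = 0
    end: int = 0  # 0-based half-open on the unaligned protein
    seq: str = ""
    anchors_found: tuple[bool, bool] = (False, False)  # (DDxxD, NSE/DTE)

    @property
    def is_empty(self) -> bool:
        return not self.seq


def extract_active_site(protein: str, motif_hits) -> ActiveSiteRegion:
    """Active-site region between the C-terminal metal-binding motifs: from
    the start of the last DDxxD hit through the end of the first NSE/DTE hit
    downstream of it, both anchors included. Either anchor missing yields an
    empty region with the flags set accordingly."""
    dd = motif_hits.hits.get("DDxxD", [])
    nse = motif_hits.hits.get("NSE/DTE", [])
    if not dd:
        return ActiveSiteRegion(motif_hits.protein_id,
                                anchors_found=(False, bool(nse)))
    dd_start = dd[-1][0]
    downstream = [(s, e) for s, e in nse if s > dd_start]
    if not downstream:
        return ActiveSiteRegion(motif_hits.protein_id, anchors_found=(True, False))
    end = downstream[0][1]
    return ActiveSiteRegion(motif_hits.protein_id, start=dd_start, end=end,
                            seq=protein[dd_start:end], anchors_found=(True, True))


def nearest_labeled_leaf(tree: Tree, labels: dict[str, str]):
    """Map each unlabeled leaf to the label of its nearest labeled leaf by
    patristic distance; exact ties between different labels -> None."""
    coph = tree.cophenetic_matrix()
    idx = {name: i for i, name in enumerate(tree.ids)}
    labeled = [name for name in tree.ids if name in labels]
    out = {}
    for name in tree.ids:
        if name in labels:
            continue
        dists = sorted((coph[idx[name], idx[r]], labels[r], r) for r in labeled)
        best_d = dists[0][0]
        best_labels = {lab for d, lab, _ in dists if d == best_d}
        out[name] = dists[0][1] if len(best_labels) == 1 else None
    return out


def assign_subfamily(query_seqs: dict[str, str], reference: dict[str, tuple[str, str]],
                     warnings: list | None = None) -> dict[str, str]:
    """Subfamily of each query gDNA by phylogenetic position.

    Joint MSA of queries and labeled references, UPGMA on Jukes-Cantor
    distances; each query inherits the subfamily of its nearest labeled leaf.
    Exact patristic ties between subfamilies give "unresolved" (logged).
    """
    if not reference:
        raise ValueError("no labeled reference sequences supplied")
    seqs = dict(query_seqs)
    labels = {}
    for rid, (seq, subfam) in reference.items():
        seqs[rid] = seq
        labels[rid] = subfam
    msa = progressive_msa(seqs, alphabet="DNA")
    tree = upgma_tree(msa_distance_matrix(msa, model="jc"), msa.ids)
    raw = nearest_labeled_leaf(tree, labels)
    out = {}
    for qid in query_seqs:
        lab = raw.get(qid)
        if lab is None:
            if warnings is not None:
                warnings.append(f"{qid}: equidistant between subfamilies, unresolved")
            out[qid] = "unresolved"
        else:
            out[qid] = lab
    return out


def smallest_labeled_clade_label(tree: Tree, query: str, labels: dict[str, MechanismLabel]):
    """Labels of the smallest clade containing ``query`` and >= 1 labeled leaf."""
    node = tree.leaf(query)
    while node.parent is not None:
        node = node.parent
        found = [labels[n] for n in node.leaf_names() if n in labels]
        if found:
            return found
    return []


def assign_mechanism(queries: dict[str, str], panel: dict[str, tuple[str, MechanismLabel]],
                     subfamily: str, report: list | None = None
                     ) -> dict[str, MechanismLabel]:
    """Mechanism labels for one subfamily's queries (active-site sequences for
    TPS-a/TPS-b, full-length proteins for TPS-g).

    Joint protein MSA + UPGMA (p-distance) with the labeled panel; a query
    takes the label of its smallest enclosing clade whose labeled leaves are
    unanimous. Conflicting labels yield cyclization "unresolved" with the
    substrate union of the clade. Queries with empty sequences (no active
    site) are skipped and reported.
    """
    usable = {}
    for qid, seq in queries.items():
        if not seq:
            if report is not None:
                report.append(f"{qid}: no active-site region, excluded from mechanism tree")
            continue
        usable[qid] = seq
    if not usable:
        return {}
    if not panel:
        raise ValueError("mechanism panel is empty")
    seqs = dict(usable)
    labels = {}
    for pid, (seq, label) in panel.items():
        seqs[pid] = seq
        labels[pid] = label
    msa = progressive_msa(seqs, alphabet="protein")
    tree = upgma_tree(msa_distance_matrix(msa, model="p"), msa.ids)
    out = {}
    for qid in usable:
        found = smallest_labeled_clade_label(tree, qid, labels)
        keys = {lab.key() for lab in found}
        if len(keys) == 1:
            out[qid] = found[0]
        else:
            subs = frozenset().union(*(lab.substrates for lab in found))
            out[qid] = MechanismLabel(subfamily, subs, "unresolved",
                                      "conflicting clade labels")
    return out
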