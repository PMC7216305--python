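"""Gene-region discovery and ORF-integrity classification.

Family-like regions are found by a spliced homology search of reference gene
models (mRNA/CDS queries) against assembly contigs: exact k-mer seeds are
grouped into diagonal segments, segments are chained colinearly with target
gaps bounded by the maximum intron size (default 3000 bp, both strands),
exon boundaries are refined by match-maximizing split placement, and chains
are scored per aligned query base. Curated regions are classified as
complete/partial and, for complete regions, as fl-ORF (intact reading
frame), d-ORF premature-stop or d-ORF frameshift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from ._seq import START_CODON, STOP_CODONS, revcomp, translate
from .io import spliced_sequence

DEFAULT_MAX_INTRON = 3000
DEFAULT_SCORE_FLOOR = 0.90
DEFAULT_SEED_K = 15
#: target gap minus query gap above this is treated as an intron, not an indel
MAX_EXON_INDEL = 30
#: chains anchored over less query sequence than this are discarded
MIN_ANCHOR_SPAN = 300

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY*X")

#: Configurable motif patterns (regular expressions over the protein).
DEFAULT_MOTIFS = {
    "RRx8W": r"RR.{8}W",
    "RxR": r"R.R",
    "DDxxD": r"DD..[DE]",
    "NSE/DTE": r"[ND]D..[ST]...E",
}
#: RxR is only reported within this many residues upstream of a DDxxD hit.
RXR_UPSTREAM_WINDOW = 40


@dataclass
class Contig:
    id: str
    cultivar: str
    role: str  # "primary" | "haplotig"
    seq: str

    def __post_init__(self):
        if self.role not in ("primary", "haplotig"):
            raise ValueError(f"contig role must be primary|haplotig, got {self.role!r}")


@dataclass
class SplicedHit:
    query_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open contig intervals
    score: float  # matched bases / anchored query span
    identity: float  # matched bases / alignment columns
    matches: int
    query_span: tuple[int, int]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_bp(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneRegion:
    accession: str
    contig_id: str
    cultivar: str
    contig_role: str
    strand: str
    exons: list[tuple[int, int]]
    completeness: str = ""  # complete | partial
    orf_class: str = ""  # fl-ORF | d-ORF_premature_stop | d-ORF_frameshift | not_applicable
    parent_id: str | None = None
    protein: str | None = None
    cds: str | None = None
    query_id: str = ""
    score: float = 0.0

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class MotifHits:
    protein_id: str
    hits: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def has(self, motif: str) -> bool:
        return bool(self.hits.get(motif))


# ---------------------------------------------------------------------------
# spliced alignment


class ContigKmerIndex:
    """Exact k-mer position index of one contig (built once, queried per query)."""

    def __init__(self, contig: Contig, k: int = DEFAULT_SEED_K):
        self.contig = contig
        self.k = k
        index: dict[str, list[int]] = {}
        seq = contig.seq
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self._index = index

    def positions(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])


def _segments_from_seeds(seeds: list[tuple[int, int]], k: int, merge_gap: int = 60):
    """Collapse (qpos, tpos) seeds into maximal same-diagonal segments
    [qs, qe, ts, te] allowing small seed gaps (SNP interruptions)."""
    by_diag: dict[int, list[int]] = {}
    for q, t in seeds:
        by_diag.setdefault(t - q, []).append(q)
    segments = []
    for diag, qs in by_diag.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q - prev > merge_gap:
                segments.append([start, prev + k, start + diag, prev + k + diag])
                start = q
            prev = q
        segments.append([start, prev + k, start + diag, prev + k + diag])
    segments.sort(key=lambda s: (s[0], s[2]))
    return segments


def _chain_segments(segments, max_intron: int, k: int = DEFAULT_SEED_K):
    """Best colinear chain (max total query coverage) over diagonal segments.

    Transitions allow small query gaps/overlaps (mismatch runs, indels) and
    target gaps up to ``max_intron`` beyond the query gap (introns).
    """
    if not segments:
        return []
    n = len(segments)
    best = [s[1] - s[0] for s in segments]
    back = [-1] * n
    for j in range(n):
        qs_j, qe_j, ts_j, _ = segments[j]
        for i in range(j):
            _, qi_e, _, ti_e = segments[i]
            dq = qs_j - qi_e
            dt = ts_j - ti_e
            if dq < -k or dq > 200:
                continue
            if dt < dq - MAX_EXON_INDEL or dt - dq > max_intron:
                continue
            cand = best[i] + (qe_j - qs_j) - max(0, -dq)
            if cand > best[j]:
                best[j] = cand
                back[j] = i
    end = max(range(n), key=lambda j: (best[j], -segments[j][0]))
    chain = []
    while end != -1:
        chain.append(segments[end])
        end = back[end]
    chain.reverse()
    return chain


def _count_matches(a: str, b: str) -> int:
    if len(a) == len(b):
        return sum(x == y for x, y in zip(a, b))
    import edlib

    if not a or not b:
        return 0
    res = edlib.align(a, b, mode="NW", task="distance")
    return max(0, max(len(a), len(b)) - res["editDistance"])


def _extend_to_query_end(qseq: str, tseq: str, q0: int, t0: int, direction: int,
                         xdrop: int = 12) -> tuple[int, int]:
    """Ungapped terminal extension, kept only when it consumes the query to
    its end (a genuinely full-length terminal exon); extensions that stall
    inside the query (x-drop) or run off the contig are discarded, so a
    truncated (partial) gene never bleeds into flanking background sequence.
    Returns (extension length, matches)."""
    score = best = matches = length = 0
    q, t = q0, t0
    while True:
        q += direction
        t += direction
        if q < 0 or q >= len(qseq):
            return length, matches  # query exhausted: keep everything
        if t < 0 or t >= len(tseq):
            return 0, 0
        length += 1
        if qseq[q] == tseq[t]:
            score += 1
            matches += 1
        else:
            score -= 2
        best = max(best, score)
        if best - score > xdrop:
            return 0, 0


def _splice_bonus(tseq: str, donor: int, acceptor: int, strand: str) -> int:
    """+1 per canonical splice signal at an intron boundary (ties between
    equally matching boundary placements are broken toward GT..AG introns).
    On the contig's forward text a minus-strand intron reads CT..AC."""
    bonus = 0
    lead, trail = ("GT", "AG") if strand == "+" else ("CT", "AC")
    if tseq[donor : donor + 2] == lead:
        bonus += 1
    if tseq[acceptor - 2 : acceptor] == trail:
        bonus += 1
    return bonus


def _prefix_fit(chunk: str, window: str):
    """Best alignment of ``chunk`` against a prefix of ``window`` (gaps free at
    the window end); returns (approx matches, window bases consumed)."""
    if not chunk:
        return 0, 0
    if not window:
        return 0, 0
    import edlib

    res = edlib.align(chunk, window, mode="SHW", task="locations")
    dist = res["editDistance"]
    end = res["locations"][0][1] + 1 if res["locations"] else len(chunk)
    return max(0, len(chunk) - dist), end


def _refine_chain(qseq: str, tseq: str, chain, strand: str = "+"):
    """Turn a segment chain into exon intervals with match-maximizing,
    splice-site-aware boundary placement; returns (exons, matches, span,
    columns)."""
    # group chain segments into exon blocks (intron iff the target gap exceeds
    # the query gap by more than a small indel allowance)
    exons = []  # [q_start, q_end, t_start, t_end, matches]
    for qs, qe, ts, te in chain:
        seg_m = sum(1 for x, y in zip(qseq[qs:qe], tseq[ts:te]) if x == y)
        if exons:
            prev = exons[-1]
            dq, dt = qs - prev[1], ts - prev[3]
            if dt - dq <= MAX_EXON_INDEL:
                if dq < 0:  # overlapping anchors: clip the incoming segment
                    qs, ts = qs - dq, ts - dq
                    if qs >= qe:
                        continue
                    seg_m = sum(1 for x, y in zip(qseq[qs:qe], tseq[ts:te]) if x == y)
                gap_m = _count_matches(qseq[prev[1]:qs], tseq[prev[3]:ts])
                prev[4] += gap_m + seg_m
                prev[1], prev[3] = qe, te
                continue
        exons.append([qs, qe, ts, te, seg_m])

    # resolve each intron boundary: distribute the unanchored (or overlapping)
    # query chunk between the left exon end and the right exon start so that
    # matches are maximal, preferring canonical GT..AG intron ends on ties
    for i in range(len(exons) - 1):
        left, right = exons[i], exons[i + 1]
        ga, gb = left[1], right[0]
        if gb < ga:
            # anchor overlap: the overlapping bases match on both sides, so
            # only the splice signal decides where the boundary sits
            ov = ga - gb
            best = (-1, 0)
            for delta in range(ov + 1):  # trim delta bases off the left exon
                donor = left[3] - delta
                acceptor = right[2] + (ov - delta)
                b = _splice_bonus(tseq, donor, acceptor, strand)
                if b > best[0]:
                    best = (b, delta)
            delta = best[1]
            left[1] -= delta
            left[3] -= delta
            left[4] -= sum(1 for x, y in
                           zip(qseq[left[1]:left[1] + delta],
                               tseq[left[3]:left[3] + delta]) if x == y)
            take = ov - delta
            right[0] += take
            right[2] += take
            right[4] = _count_matches(qseq[right[0]:right[1]], tseq[right[2]:right[3]])
            continue
        if gb == ga:
            continue
        chunk = qseq[ga:gb]
        n = len(chunk)
        lwin = tseq[left[3] : left[3] + n + MAX_EXON_INDEL]
        rwin = tseq[max(0, right[2] - n - MAX_EXON_INDEL) : right[2]]
        best = None  # (score, gapped, s, consumed_left, consumed_right, ml, mr)
        for s in range(n + 1):
            # ungapped split: substitutions only, frame always preserved
            ml0 = sum(1 for x, y in zip(chunk[:s], tseq[left[3]:left[3] + s]) if x == y)
            mr0 = sum(1 for x, y in
                      zip(chunk[s:], tseq[right[2] - (n - s):right[2]]) if x == y)
            score0 = (4 * (ml0 + mr0)
                      + _splice_bonus(tseq, left[3] + s, right[2] - (n - s), strand))
            if best is None or score0 > best[0] or (score0 == best[0] and best[1]):
                best = (score0, False, s, s, n - s, ml0, mr0)
            # gapped split (indel evidence must be strictly better than the
            # substitution explanation, or the frame would drift on SNPs)
            ml, a = _prefix_fit(chunk[:s], lwin)
            mr, b = _prefix_fit(chunk[s:][::-1], rwin[::-1])
            score = (4 * (ml + mr) - 3 * (abs(a - s) + abs(b - (n - s)))
                     + _splice_bonus(tseq, left[3] + a, right[2] - b, strand))
            if score > best[0]:
                best = (score, True, s, a, b, ml, mr)
        _, _, s, a, b, ml, mr = best
        left[1] += s
        left[3] += a
        left[4] += ml
        right[0] = gb - (n - s)
        right[2] -= b
        right[4] += mr

    # terminal extension toward the query ends
    first, last = exons[0], exons[-1]
    ext, m = _extend_to_query_end(qseq, tseq, first[0], first[2], -1)
    first[0] -= ext
    first[2] -= ext
    first[4] += m
    ext, m = _extend_to_query_end(qseq, tseq, last[1] - 1, last[3] - 1, +1)
    last[1] += ext
    last[3] += ext
    last[4] += m

    matches = sum(e[4] for e in exons)
    span = sum(e[1] - e[0] for e in exons)
    columns = sum(max(e[1] - e[0], e[3] - e[2]) for e in exons)
    t_exons = [(e[2], e[3]) for e in exons]
    return t_exons, matches, span, columns


def spliced_align(query: str, contig: Contig, max_intron: int = DEFAULT_MAX_INTRON,
                  score_floor: float = DEFAULT_SCORE_FLOOR, query_id: str = "query",
                  k: int = DEFAULT_SEED_K, min_anchor_span: int = MIN_ANCHOR_SPAN,
                  index: ContigKmerIndex | None = None) -> list[SplicedHit]:
    """Spliced alignment of one gene-model query against one contig.

    Both strands are searched; exon chains never bridge a target gap larger
    than ``max_intron``; hits scoring below ``score_floor`` (matched bases per
    anchored query base) or anchored over less than ``min_anchor_span`` of the
    query are discarded. Hits are sorted by (score desc, contig position asc).
    """
    if not query or not contig.seq:
        raise ValueError("query and contig must be non-empty")
    if index is None:
        index = ContigKmerIndex(contig, k)
    hits: list[SplicedHit] = []
    for strand in "+-":
        qseq = query if strand == "+" else revcomp(query)
        seeds = []
        for i in range(len(qseq) - k + 1):
            for t in index.positions(qseq[i : i + k]):
                seeds.append((i, t))
        segments = _segments_from_seeds(seeds, k)
        # iteratively extract chains so tandem copies yield separate hits
        while segments:
            chain = _chain_segments(segments, max_intron, k)
            if not chain:
                break
            exons, matches, span, columns = _refine_chain(qseq, contig.seq, chain, strand)
            if span >= min_anchor_span:
                score = matches / span
                identity = matches / columns if columns else 0.0
                if score >= score_floor:
                    if strand == "+":
                        qspan = (chain[0][0], chain[-1][1])
                    else:
                        qspan = (len(qseq) - chain[-1][1], len(qseq) - chain[0][0])
                    hits.append(SplicedHit(
                        query_id=query_id, contig_id=contig.id, strand=strand,
                        exons=exons, score=round(score, 6),
                        identity=round(identity, 6), matches=matches,
                        query_span=qspan))
            used_t = (chain[0][2], chain[-1][3])
            segments = [s for s in segments if s[3] <= used_t[0] or s[2] >= used_t[1]]
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.start))
    return hits


# ---------------------------------------------------------------------------
# curation and classification


def curate_hits(hits: list[SplicedHit], contigs: dict[str, Contig],
                external: list | None = None) -> list[GeneRegion]:
    """Merge overlapping same-strand hits per contig into loci and assign
    accessions.

    Within a locus the hit with the greatest exon coverage, then the highest
    score, defines the exon structure. Accessions are two-letter cultivar code
    + "TPS" + sequential number in (contig id, position) order. ``external``
    optionally carries GffGene annotations; a region overlapping one inherits
    its id as parent_id.
    """
    by_key: dict[tuple[str, str], list[SplicedHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig_id, h.strand), []).append(h)

    chosen: list[SplicedHit] = []
    for (contig_id, strand), group in by_key.items():
        group = sorted(group, key=lambda h: h.start)
        clusters: list[list[SplicedHit]] = []
        cur, cur_end = [], -1
        for h in group:
            if cur and h.start >= cur_end:
                clusters.append(cur)
                cur = []
            cur.append(h)
            cur_end = max(cur_end, h.end)
        if cur:
            clusters.append(cur)
        for cluster in clusters:
            best = sorted(cluster, key=lambda h: (-h.exon_bp, -h.score, h.start, h.query_id))[0]
            chosen.append(best)

    chosen.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    regions = []
    counters: dict[str, int] = {}
    for h in chosen:
        contig = contigs[h.contig_id]
        counters[contig.cultivar] = counters.get(contig.cultivar, 0) + 1
        accession = f"{contig.cultivar}TPS{counters[contig.cultivar]:03d}"
        parent = None
        for g in external or []:
            if g.seqid == h.contig_id and g.strand == h.strand and \
                    g.start < h.end and h.start < g.end:
                parent = g.gene_id
                break
        regions.append(GeneRegion(
            accession=accession, contig_id=h.contig_id, cultivar=contig.cultivar,
            contig_role=contig.role, strand=h.strand, exons=list(h.exons),
            parent_id=parent, query_id=h.query_id, score=h.score))
    return regions


def classify_gene_region(region: GeneRegion, contig_seq: str) -> GeneRegion:
    """Set completeness and ORF class from the spliced sequence.

    Partial iff exon count <= 4 or the terminal start/stop codon is absent
    (either condition suffices; "complete" requires all of them). Complete
    regions with a codon-multiple length translate cleanly to fl-ORF, carry an
    internal stop (frame preserved) as d-ORF premature-stop, or a length not
    divisible by three as d-ORF frameshift.
    """
    for s, e in region.exons:
        if s < 0 or e > len(contig_seq):
            raise ValueError(f"exon ({s},{e}) outside contig bounds for {region.accession}")
    cds = spliced_sequence(contig_seq, region.exons, region.strand)
    region = replace(region, cds=cds)
    if len(region.exons) <= 4 or not cds.startswith(START_CODON) or cds[-3:] not in STOP_CODONS:
        return replace(region, completeness="partial", orf_class="not_applicable",
                       protein=None)
    if len(cds) % 3 != 0:
        return replace(region, completeness="complete", orf_class="d-ORF_frameshift",
                       protein=None)
    prot = translate(cds)
    if "*" in prot[:-1]:
        return replace(region, completeness="complete", orf_class="d-ORF_premature_stop",
                       protein=None)
    return replace(region, completeness="complete", orf_class="fl-ORF", protein=prot[:-1])


def scan_motifs(protein: str, protein_id: str = "protein",
                patterns: dict[str, str] | None = None) -> MotifHits:
    """Report all (possibly overlapping) matches of the TPS motif patterns.

    RxR hits are contextual: only matches within ``RXR_UPSTREAM_WINDOW``
    residues upstream of a DDxxD hit are reported.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    bad = set(protein) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid symbols in protein: {sorted(bad)}")
    patterns = patterns or DEFAULT_MOTIFS
    hits: dict[str, list[tuple[int, int]]] = {}
    for name, pat in patterns.items():
        found = []
        for m in re.finditer(f"(?=({pat}))", protein):
            found.append((m.start(), m.start() + len(m.group(1))))
        hits[name] = found
    if "RxR" in hits and "DDxxD" in hits:
        dd_starts = [s for s, _ in hits["DDxxD"]]
        hits["RxR"] = [
            (s, e) for s, e in hits["RxR"]
            if any(0 <= d - s <= RXR_UPSTREAM_WINDOW for d in dd_starts)
        ]
    return MotifHits(protein_id=protein_id, hits=hits)


# ---------------------------------------------------------------------------
# cultivar-level convenience


def annotate_cultivar(contigs: list[Contig], queries: dict[str, str],
                      max_intron: int = DEFAULT_MAX_INTRON,
                      score_floor: float = DEFAULT_SCORE_FLOOR,
                      external: list | None = None) -> list[GeneRegion]:
    """Full discovery for one cultivar: spliced search of every query against
    every contig, curation, and completeness/ORF classification."""
    contig_map = {c.id: c for c in contigs}
    hits: list[SplicedHit] = []
    for contig in contigs:
        index = ContigKmerIndex(contig)
        for qid, qseq in queries.items():
            hits.extend(spliced_align(qseq, contig, max_intron=max_intron,
                                      score_floor=score_floor, query_id=qid,
                                      index=index))
    regions = curate_hits(hits, contig_map, external=external)
    return [classify_gene_region(r, contig_map[r.contig_id].seq) for r in regions]
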