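"""Synthetic phased diploid assemblies with implanted TPS-like genes.

The generator emulates the end state of a FALCON-UNZIP-style phased assembly:
per synthetic cultivar a set of primary contigs (carrying both haplotypes'
gene complement) and haplotigs (carrying allelic variants), each carved from
a shared set of reference chromosome backbones so that reference-guided
chromosome grouping is testable. Multi-exon TPS-like genes bearing the
canonical class-I motifs (DDxxD, NSE/DTE, and RRx8W for TPS-b) are implanted
with controlled point-mutation / indel rates, producing full-length ORFs,
disrupted ORFs (premature stop or frameshift), partial (truncated) genes,
tandem duplicates, allelic pairs and hemizygous genes — together with a truth
table and truth GFF3 against which every downstream stage is scored.

Truth classes are *realized* classes: when a nonzero background SNP rate is
requested the generator re-derives completeness and ORF class from the final
implanted sequence, since background mutations can create genuine premature
stops. Noiseless designs always realize their designed classes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import DNA_ALPHABET, START_CODON, STOP_CODONS, random_dna, revcomp, translate
from .io import GffGene, write_fasta, write_gff3, write_tsv
from .mechanisms import MECHANISM_CLASSES, MechanismLabel

# Deterministic codon choice per amino acid (used when stamping motifs).
_CODON_FOR_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}

_SENSE_CODONS = [
    a + b + c
    for a in DNA_ALPHABET for b in DNA_ALPHABET for c in DNA_ALPHABET
    if a + b + c not in STOP_CODONS
]

# Motif instances stamped into every template (the x positions are fixed;
# the anchor residues match the configurable default patterns in gene_models).
_MOTIF_DDXXD = "DDTYD"
_MOTIF_NSE_DTE = "NDTASALAE"
_MOTIF_RRX8W = "RRSGTKEPLAW"
_MOTIF_RXR = "RVR"

#: Protein length (aa, excluding the stop) per subfamily.
_PROTEIN_LEN = {"TPS-a": 552, "TPS-b": 566, "TPS-g": 548, "TPS-c": 560, "TPS-e": 556}

#: Nucleotide divergence of a mechanism-class ancestor from its subfamily
#: ancestor, and of a panel member from its class ancestor. Members of one
#: class end up ~24% divergent pairwise (I' ~ 76, safely below the 80%
#: duplication threshold), while classes within a subfamily stay mutually
#: recognizable against the ~50%+ between-class divergence.
_CLASS_DIVERGENCE = 0.30
_MEMBER_DIVERGENCE = 0.13

ORF_CLASSES = ("fl-ORF", "d-ORF_premature_stop", "d-ORF_frameshift", "not_applicable")
TRUTH_CLASSES = ("fl-ORF", "d-ORF_stop", "d-ORF_frameshift", "partial")
DUPLICATION_TRUTH = ("tandem", "allelic", "hemizygous", "tentative", "unique")


@dataclass
class GeneTemplate:
    """A reference gene model: CDS split into exons, with concrete introns."""

    id: str
    subfamily: str
    mechanism: MechanismLabel
    mechanism_class: str
    exon_lengths: list[int]
    intron_lengths: list[int]
    cds: str
    protein: str
    introns: list[str]

    @property
    def exons(self) -> list[str]:
        out, pos = [], 0
        for ln in self.exon_lengths:
            out.append(self.cds[pos : pos + ln])
            pos += ln
        return out

    @property
    def gdna(self) -> str:
        pieces = []
        for i, ex in enumerate(self.exons):
            pieces.append(ex)
            if i < len(self.introns):
                pieces.append(self.introns[i])
        return "".join(pieces)

    def validate(self) -> None:
        if sum(self.exon_lengths) != len(self.cds):
            raise ValueError("exon lengths do not tile the CDS")
        if not self.cds.startswith(START_CODON) or self.cds[-3:] not in STOP_CODONS:
            raise ValueError("CDS lacks terminal start/stop")
        prot = translate(self.cds)
        if "*" in prot[:-1] or prot[-1] != "*":
            raise ValueError("CDS contains internal stop codons")


@dataclass
class ImplantSpec:
    """Placement + mutation recipe for one implanted gene copy."""

    template_id: str
    cultivar: str
    contig_role: str  # "primary" | "haplotig"
    contig_id: str
    offset: int  # backbone coordinate of the insertion window
    strand: str
    snp_rate: float = 0.0
    indel_ops: list = field(default_factory=list)
    premature_stop: bool = False
    truth_class: str = "fl-ORF"  # designed class
    duplication_truth: str = "unique"
    chromosome_truth: str = ""
    gene_id: str = ""  # generator-side stable id


@dataclass
class ContigPlan:
    cultivar: str
    contig_id: str
    role: str
    chromosome: str


@dataclass
class Design:
    contigs: list[ContigPlan]
    implants: list[ImplantSpec]


@dataclass
class Assembly:
    """Everything build_phased_assembly emits, plus writers."""

    primary: dict[str, dict[str, str]]  # cultivar -> {contig_id: seq}
    haplotigs: dict[str, dict[str, str]]
    reference: dict[str, str]  # chromosome -> seq
    truth: pd.DataFrame
    truth_genes: list[GffGene]
    cds_by_gene: dict[str, str]

    def contigs(self, cultivar: str) -> dict[str, str]:
        return {**self.primary.get(cultivar, {}), **self.haplotigs.get(cultivar, {})}

    @property
    def cultivars(self) -> list[str]:
        return sorted(set(self.primary) | set(self.haplotigs))

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        for cv in self.cultivars:
            write_fasta(os.path.join(outdir, f"{cv}_primary.fasta"), self.primary.get(cv, {}))
            write_fasta(os.path.join(outdir, f"{cv}_haplotigs.fasta"), self.haplotigs.get(cv, {}))
        write_fasta(os.path.join(outdir, "reference_chromosomes.fasta"), self.reference)
        write_gff3(os.path.join(outdir, "truth.gff3"), self.truth_genes)
        write_tsv(os.path.join(outdir, "truth.tsv"), self.truth)


# ---------------------------------------------------------------------------
# template panel


def _random_sense_cds(rng: np.random.Generator, n_aa: int) -> str:
    codons = [START_CODON]
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_aa - 1)
    codons.extend(_SENSE_CODONS[i] for i in idx)
    codons.append("TAA")
    return "".join(codons)


def _stamp(cds: str, aa_pos: int, motif: str) -> str:
    nt = aa_pos * 3
    block = "".join(_CODON_FOR_AA[a] for a in motif)
    return cds[:nt] + block + cds[nt + len(block):]


def _motif_layout(n_aa: int, subfamily: str) -> list[tuple[int, str]]:
    dd = int(n_aa * 0.55)
    layout = [(dd, _MOTIF_DDXXD), (dd + 40, _MOTIF_NSE_DTE)]
    if subfamily == "TPS-b":
        layout.append((25, _MOTIF_RRX8W))
        layout.append((dd - 21, _MOTIF_RXR))
    return layout


def _frozen_nt(layout: list[tuple[int, str]], cds_len: int) -> set[int]:
    frozen = set(range(3)) | set(range(cds_len - 3, cds_len))
    for aa_pos, motif in layout:
        frozen.update(range(aa_pos * 3, (aa_pos + len(motif)) * 3))
    return frozen


def _diverge_cds(cds: str, rate: float, frozen: set[int], rng: np.random.Generator) -> str:
    """Point-mutate a CDS at the given per-site rate, keeping frozen sites and
    never introducing an internal stop codon (such draws are re-rolled)."""
    seq = list(cds)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        if int(pos) in frozen:
            continue
        old = seq[pos]
        choices = [b for b in DNA_ALPHABET if b != old]
        seq[pos] = choices[rng.integers(0, 3)]
        cstart = (pos // 3) * 3
        codon = "".join(seq[cstart : cstart + 3])
        if codon in STOP_CODONS:
            seq[pos] = old  # revert rather than truncate the reading frame
    return "".join(seq)


def _split_lengths(total: int, parts: int, rng: np.random.Generator, jitter: int = 30) -> list[int]:
    base = total // parts
    lens = [base] * parts
    lens[-1] += total - base * parts
    for _ in range(parts):
        i, j = rng.integers(0, parts, size=2)
        d = int(rng.integers(-jitter, jitter + 1))
        if lens[i] - d > 60 and lens[j] + d > 60:
            lens[i] -= d
            lens[j] += d
    return lens


def make_reference_panel(n_per_subfamily: int, seed: int, n_exons: int = 7,
                         max_intron: int = 2500) -> list[GeneTemplate]:
    """Generate a labeled reference panel of TPS-like gene models.

    Per subfamily, mechanism classes are assigned round-robin, so all classes
    of a subfamily are covered once ``n_per_subfamily`` reaches its class
    count (4 for TPS-a). Members of a class descend from a common class
    ancestor and stay mutually recognizable, while distinct templates are
    divergent enough never to read as gene duplicates (I' well below 80).
    """
    if n_per_subfamily < 1:
        raise ValueError("n_per_subfamily must be >= 1")
    rng = np.random.default_rng(seed)
    panel: list[GeneTemplate] = []
    for subfamily, classes in MECHANISM_CLASSES.items():
        n_aa = _PROTEIN_LEN[subfamily]
        layout = _motif_layout(n_aa, subfamily)
        ancestor = _random_sense_cds(rng, n_aa)
        for aa_pos, motif in layout:
            ancestor = _stamp(ancestor, aa_pos, motif)
        frozen = _frozen_nt(layout, len(ancestor))
        class_ancestors = {
            key: _diverge_cds(ancestor, _CLASS_DIVERGENCE, frozen, rng)
            for key, _ in classes
        }
        for i in range(n_per_subfamily):
            class_key, label = classes[i % len(classes)]
            cds = _diverge_cds(class_ancestors[class_key], _MEMBER_DIVERGENCE, frozen, rng)
            exon_lengths = _split_lengths(len(cds), n_exons, rng)
            intron_lengths = [int(rng.integers(80, min(401, max_intron + 1)))
                              for _ in range(n_exons - 1)]
            introns = ["GT" + random_dna(rng, ln - 4) + "AG" for ln in intron_lengths]
            tpl = GeneTemplate(
                id=f"{subfamily.replace('-', '')}_m{i + 1:02d}",
                subfamily=subfamily,
                mechanism=label,
                mechanism_class=class_key,
                exon_lengths=exon_lengths,
                intron_lengths=intron_lengths,
                cds=cds,
                protein=translate(cds)[:-1],
                introns=introns,
            )
            tpl.validate()
            panel.append(tpl)
    return panel


def with_oversized_intron(template: GeneTemplate, seed: int, intron_index: int = 2,
                          length: int = 5000) -> GeneTemplate:
    """Violation mode: replace one intron with an oversized one (default 5 kb,
    beyond the 3 kb spliced-search limit)."""
    rng = np.random.default_rng(seed)
    introns = list(template.introns)
    introns[intron_index] = "GT" + random_dna(rng, length - 4) + "AG"
    lengths = list(template.intron_lengths)
    lengths[intron_index] = length
    return replace(template, id=template.id + "_bigintron",
                   introns=introns, intron_lengths=lengths)


# ---------------------------------------------------------------------------
# mutation


def mutate_sequence(dna: str, snp_rate: float, indel_ops: list | None = None,
                    stop_inject: bool = False, seed: int = 0) -> tuple[str, list[dict]]:
    """Apply point mutations, an optional in-frame premature stop, and
    explicit indel operations to a sequence; return the result plus an exact
    edit log.

    ``stop_inject`` assumes ``dna`` is a CDS read in frame 0: one internal
    sense codon (from the middle 20–80% of the frame) is replaced by TAA.
    ``indel_ops`` entries are ``("ins", pos, length)`` or ``("del", pos,
    length)`` applied left to right at coordinates of the current sequence.
    """
    if not 0 <= snp_rate <= 0.15:
        raise ValueError(f"snp_rate {snp_rate} outside [0, 0.15]")
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    seq = list(dna)

    if snp_rate > 0:
        hits = np.nonzero(rng.random(len(seq)) < snp_rate)[0]
        for pos in hits:
            old = seq[pos]
            alt = [b for b in DNA_ALPHABET if b != old][rng.integers(0, 3)]
            seq[pos] = alt
            log.append({"op": "snp", "pos": int(pos), "ref": old, "alt": alt})

    if stop_inject:
        n_codons = len(seq) // 3
        lo, hi = max(1, int(n_codons * 0.2)), int(n_codons * 0.8)
        for _ in range(100):
            c = int(rng.integers(lo, hi))
            codon = "".join(seq[c * 3 : c * 3 + 3])
            if codon not in STOP_CODONS:
                seq[c * 3 : c * 3 + 3] = list("TAA")
                log.append({"op": "stop", "pos": c * 3, "ref": codon, "alt": "TAA"})
                break
        else:  # pragma: no cover - only reachable on a stop-saturated input
            raise ValueError("no sense codon available for stop injection")

    for op in indel_ops or []:
        kind, pos, length = op
        if kind == "ins":
            ins = random_dna(rng, length, gc=0.5)
            seq[pos:pos] = list(ins)
            log.append({"op": "ins", "pos": int(pos), "alt": ins})
        elif kind == "del":
            ref = "".join(seq[pos : pos + length])
            del seq[pos : pos + length]
            log.append({"op": "del", "pos": int(pos), "ref": ref})
        else:
            raise ValueError(f"unknown indel op {kind!r}")

    return "".join(seq), log


# ---------------------------------------------------------------------------
# assembly construction


def _classify_cds(cds: str, n_exons: int) -> tuple[str, str, str]:
    """Generator-side truth classification -> (completeness, orf_class, protein)."""
    if n_exons <= 4 or not cds.startswith(START_CODON) or cds[-3:] not in STOP_CODONS:
        return "partial", "not_applicable", ""
    if len(cds) % 3 != 0:
        return "complete", "d-ORF_frameshift", ""
    prot = translate(cds)
    if "*" in prot[:-1]:
        return "complete", "d-ORF_premature_stop", ""
    return "complete", "fl-ORF", prot[:-1]


def _realize_implant(template: GeneTemplate, spec: ImplantSpec,
                     rng: np.random.Generator):
    """Apply the implant's mutation recipe; return exon seqs, intron seqs and
    the realized (completeness, orf_class, protein)."""
    if spec.truth_class == "partial":
        exon_lengths = template.exon_lengths[1:5]
        start = template.exon_lengths[0]
        cds = template.cds[start : start + sum(exon_lengths)]
        introns = list(template.introns[1:4])
    else:
        exon_lengths = list(template.exon_lengths)
        cds = template.cds
        introns = list(template.introns)

    seed_edit, seed_snp = int(rng.integers(2**31)), int(rng.integers(2**31))
    if spec.premature_stop:
        # keep the injected stop clear of splice boundaries: a disruption
        # inside the boundary ambiguity zone is not recoverable by spliced
        # alignment even without noise (class-feasibility guarantee)
        boundaries = [sum(exon_lengths[:i + 1]) for i in range(len(exon_lengths) - 1)]
        for attempt in range(100):
            cand, log = mutate_sequence(cds, 0.0, [], True,
                                        (seed_edit + attempt * 7919) % 2**31)
            pos = next(e["pos"] for e in log if e["op"] == "stop")
            if all(abs(pos - b) >= 21 and abs(pos + 3 - b) >= 21 for b in boundaries):
                cds = cand
                break
        else:  # pragma: no cover - would need pathological exon structure
            raise ValueError("could not place a premature stop away from boundaries")
    cds, _ = mutate_sequence(cds, 0.0, spec.indel_ops, False, seed_edit)
    # indels shift the length of the exon they hit
    for op in spec.indel_ops:
        kind, pos, length = op
        acc = 0
        for i, ln in enumerate(exon_lengths):
            if pos < acc + ln:
                exon_lengths[i] += length if kind == "ins" else -length
                break
            acc += ln
    if spec.snp_rate > 0:
        cds, _ = mutate_sequence(cds, spec.snp_rate, [], False, seed_snp)
        introns = [mutate_sequence(iv, spec.snp_rate, [], False,
                                   int(rng.integers(2**31)))[0] for iv in introns]

    exons, pos = [], 0
    for ln in exon_lengths:
        exons.append(cds[pos : pos + ln])
        pos += ln
    completeness, orf_class, protein = _classify_cds(cds, len(exons))
    return exons, introns, cds, completeness, orf_class, protein


def build_phased_assembly(panel: list[GeneTemplate], design: Design,
                          intergenic_len: int = 4000, seed: int = 0,
                          gc: float = 0.45) -> Assembly:
    """Emit primary/haplotig assemblies per cultivar, a reference chromosome
    set carved from the same backbones, the truth table and the truth GFF3.

    Implant offsets are backbone coordinates; each gene *replaces* the
    backbone window it covers, so truth exon intervals are exact final contig
    coordinates. Overlapping windows on one contig are a design error.
    """
    rng = np.random.default_rng(seed)
    templates = {t.id: t for t in panel}
    by_contig: dict[str, list[ImplantSpec]] = {}
    for spec in design.implants:
        if spec.template_id not in templates:
            raise ValueError(f"design targets unknown template {spec.template_id!r}")
        by_contig.setdefault(spec.contig_id, []).append(spec)
    plan_ids = {c.contig_id for c in design.contigs}
    missing = set(by_contig) - plan_ids
    if missing:
        raise ValueError(f"implants target contigs absent from the plan: {sorted(missing)}")

    # realize every implant first so window sizes are known
    realized: dict[str, dict] = {}
    for spec in design.implants:
        tpl = templates[spec.template_id]
        exons, introns, cds, completeness, orf_class, protein = _realize_implant(tpl, spec, rng)
        pieces = []
        for i, ex in enumerate(exons):
            pieces.append(ex)
            if i < len(introns):
                pieces.append(introns[i])
        gdna = "".join(pieces)
        realized[spec.gene_id] = dict(
            spec=spec, exons=exons, introns=introns, cds=cds, gdna=gdna,
            completeness=completeness, orf_class=orf_class, protein=protein,
        )

    # backbone length needed per contig
    backbone_len: dict[str, int] = {}
    for c in design.contigs:
        end = intergenic_len
        for spec in sorted(by_contig.get(c.contig_id, []), key=lambda s: s.offset):
            end = max(end, spec.offset + len(realized[spec.gene_id]["gdna"]))
        backbone_len[c.contig_id] = end + intergenic_len

    # reference chromosomes sized to hold every carved backbone window
    chrom_need: dict[str, int] = {}
    for c in design.contigs:
        chrom_need[c.chromosome] = chrom_need.get(c.chromosome, 0) + backbone_len[c.contig_id]
    reference = {chrom: random_dna(rng, need + 2000, gc=gc)
                 for chrom, need in sorted(chrom_need.items())}
    cursor = {chrom: 1000 for chrom in reference}

    primary: dict[str, dict[str, str]] = {}
    haplotigs: dict[str, dict[str, str]] = {}
    truth_rows, truth_genes = [], []
    cds_by_gene: dict[str, str] = {}

    for c in sorted(design.contigs, key=lambda c: (c.cultivar, c.contig_id)):
        blen = backbone_len[c.contig_id]
        start = cursor[c.chromosome]
        backbone = reference[c.chromosome][start : start + blen]
        cursor[c.chromosome] = start + blen
        specs = sorted(by_contig.get(c.contig_id, []), key=lambda s: s.offset)
        for a, b in zip(specs, specs[1:]):
            if a.offset + len(realized[a.gene_id]["gdna"]) > b.offset:
                raise ValueError(
                    f"overlapping implants {a.gene_id}/{b.gene_id} on {c.contig_id}")
        if specs and specs[-1].offset + len(realized[specs[-1].gene_id]["gdna"]) > blen:
            raise ValueError(f"implant beyond backbone on {c.contig_id}")

        parts, prev = [], 0
        for spec in specs:
            info = realized[spec.gene_id]
            gdna = info["gdna"]
            parts.append(backbone[prev : spec.offset])
            parts.append(revcomp(gdna) if spec.strand == "-" else gdna)
            prev = spec.offset + len(gdna)

            # exon intervals in final contig coordinates
            exon_iv, pos = [], 0
            for i, ex in enumerate(info["exons"]):
                exon_iv.append((pos, pos + len(ex)))
                pos += len(ex)
                if i < len(info["introns"]):
                    pos += len(info["introns"][i])
            L = len(gdna)
            if spec.strand == "-":
                exon_iv = sorted((L - e, L - s) for s, e in exon_iv)
            exon_iv = [(spec.offset + s, spec.offset + e) for s, e in exon_iv]

            tpl = templates[spec.template_id]
            truth_rows.append(dict(
                gene_id=spec.gene_id, cultivar=c.cultivar, contig_id=c.contig_id,
                role=c.role, chromosome=c.chromosome, strand=spec.strand,
                start=exon_iv[0][0], end=exon_iv[-1][1], n_exons=len(exon_iv),
                exons=",".join(f"{s}-{e}" for s, e in exon_iv),
                template_id=spec.template_id, subfamily=tpl.subfamily,
                mechanism_class=tpl.mechanism_class,
                designed_class=spec.truth_class,
                completeness=info["completeness"], orf_class=info["orf_class"],
                duplication_truth=spec.duplication_truth,
                snp_rate=spec.snp_rate, seed=seed,
            ))
            truth_genes.append(GffGene(
                gene_id=spec.gene_id, seqid=c.contig_id, strand=spec.strand,
                exons=exon_iv,
                attributes={"template": spec.template_id,
                            "truth_class": spec.truth_class,
                            "completeness": info["completeness"],
                            "orf_class": info["orf_class"]},
            ))
            cds_by_gene[spec.gene_id] = info["cds"]
        parts.append(backbone[prev:])
        seq = "".join(parts)
        bucket = primary if c.role == "primary" else haplotigs
        bucket.setdefault(c.cultivar, {})[c.contig_id] = seq

    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "cultivar", "contig_id", "role", "chromosome", "strand",
        "start", "end", "n_exons", "exons", "template_id", "subfamily",
        "mechanism_class", "designed_class", "completeness", "orf_class",
        "duplication_truth", "snp_rate", "seed"])
    if not truth.empty:
        truth["hemizygous"] = _truth_hemizygosity(truth)
    else:
        truth["hemizygous"] = pd.Series(dtype=bool)
    return Assembly(primary=primary, haplotigs=haplotigs, reference=reference,
                    truth=truth, truth_genes=truth_genes, cds_by_gene=cds_by_gene)


def _truth_hemizygosity(truth: pd.DataFrame) -> pd.Series:
    """A complete gene is hemizygous iff no complete copy of its template sits
    on the opposite assembly role (primary vs haplotig) of the same cultivar."""
    flags = []
    complete = truth[truth.completeness == "complete"]
    for _, row in truth.iterrows():
        if row.completeness != "complete":
            flags.append(False)
            continue
        other = complete[(complete.cultivar == row.cultivar)
                         & (complete.template_id == row.template_id)
                         & (complete.role != row.role)]
        flags.append(len(other) == 0)
    return pd.Series(flags, index=truth.index)


def expected_duplication_edges(truth: pd.DataFrame, cultivar: str) -> list[tuple[str, str, str]]:
    """Rule-based truth edges for one cultivar: complete genes sharing a
    template are duplicates; same contig -> tandem, primary<->haplotig on one
    chromosome -> haplotype, anything else -> tentative."""
    rows = truth[(truth.cultivar == cultivar) & (truth.completeness == "complete")]
    edges = []
    recs = rows.to_dict("records")
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a["template_id"] != b["template_id"]:
                continue
            if a["contig_id"] == b["contig_id"]:
                kind = "tandem"
            elif a["role"] != b["role"] and a["chromosome"] == b["chromosome"]:
                kind = "haplotype"
            else:
                kind = "tentative"
            pair = tuple(sorted((a["gene_id"], b["gene_id"])))
            edges.append((pair[0], pair[1], kind))
    return sorted(edges)


# ---------------------------------------------------------------------------
# the standard study design


def _indel_position(tpl: GeneTemplate, rng: np.random.Generator, margin: int = 21) -> int:
    """A CDS position for a designed frameshift indel, kept clear of splice
    boundaries (boundary-adjacent disruptions are not recoverable by spliced
    alignment even without noise)."""
    boundaries = [sum(tpl.exon_lengths[:i + 1]) for i in range(len(tpl.exon_lengths) - 1)]
    for _ in range(200):
        pos = int(rng.integers(100, len(tpl.cds) - 100))
        if all(abs(pos - b) >= margin for b in boundaries):
            return pos
    raise ValueError("no indel position away from exon boundaries")


def standard_design(panel: list[GeneTemplate], cultivars: tuple[str, ...] = ("S1", "S2"),
                    snp_rate: float = 0.0, seed: int = 0,
                    intergenic_len: int = 4000,
                    n_fl_pairs: int = 6, n_tandem_groups: int = 3, n_fl_hemi: int = 6,
                    n_dorf_pairs: int = 5, n_dorf_hemi: int = 5,
                    n_partial: int = 15) -> Design:
    """The study design used throughout: per cultivar 60 implants by default —
    30 fl-ORF (6 allelic pairs, 3 tandem groups of four, 6 hemizygous),
    15 d-ORF (5 allelic pairs, 5 hemizygous; premature stops and frameshifts),
    15 partial — across 6 primary contigs and 8 haplotigs on 6 chromosomes.

    The same template fills the same slot in every cultivar, so cross-cultivar
    homologs exist by construction. With 45 complete genes per cultivar and
    allelic partners coming in pairs, the hemizygous set size is forced to be
    odd; the default design has 11 hemizygous complete genes.
    """
    rng = np.random.default_rng(seed)
    n_templates = (n_fl_pairs + n_tandem_groups + n_fl_hemi + n_dorf_pairs
                   + n_dorf_hemi + n_partial)
    if len(panel) < n_templates:
        raise ValueError(f"panel too small: need {n_templates} templates, have {len(panel)}")
    # deterministic template shuffle so subfamilies mix across slot kinds
    order = rng.permutation(len(panel))
    slots = [panel[i] for i in order[:n_templates]]
    chroms = ["chr13", "chr18", "chr19", "chr10", "chr07", "chr01"]

    contigs: list[ContigPlan] = []
    implants: list[ImplantSpec] = []
    for cv in cultivars:
        n_primary = 6
        prim = [ContigPlan(cv, f"{cv}_P{i + 1:02d}", "primary", chroms[i % len(chroms)])
                for i in range(n_primary)]
        hap = [ContigPlan(cv, f"{cv}_H{i + 1:02d}", "haplotig", chroms[i % len(chroms)])
               for i in range(8)]
        contigs.extend(prim + hap)
        cursor: dict[str, int] = {}
        counter = [0]

        def place(tpl: GeneTemplate, contig: ContigPlan, truth_class: str,
                  dup: str, premature_stop=False, indel_ops=None, partial=False):
            counter[0] += 1
            gid = f"{cv}.g{counter[0]:03d}"
            if partial:
                glen = sum(tpl.exon_lengths[1:5]) + sum(tpl.intron_lengths[1:4])
            else:
                glen = len(tpl.gdna)
            for op in indel_ops or []:
                glen += op[2] if op[0] == "ins" else -op[2]
            off = cursor.get(contig.contig_id, intergenic_len)
            cursor[contig.contig_id] = off + glen + intergenic_len
            strand = "+" if counter[0] % 2 else "-"
            implants.append(ImplantSpec(
                template_id=tpl.id, cultivar=cv, contig_role=contig.role,
                contig_id=contig.contig_id, offset=off, strand=strand,
                snp_rate=snp_rate, indel_ops=list(indel_ops or []),
                premature_stop=premature_stop, truth_class=truth_class,
                duplication_truth=dup, chromosome_truth=contig.chromosome,
                gene_id=gid))

        it = iter(slots)
        for k in range(n_fl_pairs):
            tpl = next(it)
            place(tpl, prim[k % n_primary], "fl-ORF", "allelic")
            place(tpl, hap[k % n_primary], "fl-ORF", "allelic")
        for k in range(n_tandem_groups):
            tpl = next(it)
            for _ in range(2):
                place(tpl, prim[k % n_primary], "fl-ORF", "tandem")
            for _ in range(2):
                place(tpl, hap[k % n_primary], "fl-ORF", "tandem")
        for k in range(n_fl_hemi):
            place(next(it), prim[k % n_primary], "fl-ORF", "hemizygous")
        for k in range(n_dorf_pairs):
            tpl = next(it)
            if k % 2 == 0:
                kw = dict(premature_stop=True)
                cls = "d-ORF_stop"
            else:
                pos = _indel_position(tpl, rng)
                kw = dict(indel_ops=[("del", pos, 1)])
                cls = "d-ORF_frameshift"
            place(tpl, prim[k % n_primary], cls, "allelic", **kw)
            place(tpl, hap[k % n_primary], cls, "allelic", **kw)
        for k in range(n_dorf_hemi):
            tpl = next(it)
            if k % 2 == 0:
                kw = dict(premature_stop=True)
                cls = "d-ORF_stop"
            else:
                pos = _indel_position(tpl, rng)
                kw = dict(indel_ops=[("ins", pos, 1)])
                cls = "d-ORF_frameshift"
            place(tpl, prim[k % n_primary], cls, "hemizygous", **kw)
        all_contigs = prim + hap
        for k in range(n_partial):
            place(next(it), all_contigs[k % len(all_contigs)], "partial", "unique",
                  partial=True)
    return Design(contigs=contigs, implants=implants)
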