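"""FASTA / GFF3 / TSV readers and writers used by every stage.

FASTA goes through Bio.SeqIO. GFF3 here is the small subset the pipeline
emits (gene + exon features with ID/Parent and free-form attributes);
coordinates are converted between the package's 0-based half-open internal
convention and GFF3's 1-based inclusive one at this boundary only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class GffGene:
    """One gene feature with its exon children (internal 0-based half-open)."""

    gene_id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


def _fmt_attrs(attrs: Mapping[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(path: str | os.PathLike, genes: Iterable[GffGene], source: str = "phasetps") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = {"ID": g.gene_id, **g.attributes}
            fh.write(
                "\t".join(
                    [g.seqid, source, "gene", str(g.start + 1), str(g.end), ".",
                     g.strand, ".", _fmt_attrs(attrs)]
                )
                + "\n"
            )
            exons = sorted(g.exons)
            for i, (s, e) in enumerate(exons, 1):
                ex_attrs = {"ID": f"{g.gene_id}.exon{i}", "Parent": g.gene_id}
                fh.write(
                    "\t".join(
                        [g.seqid, source, "exon", str(s + 1), str(e), ".",
                         g.strand, ".", _fmt_attrs(ex_attrs)]
                    )
                    + "\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GffGene]:
    genes: dict[str, GffGene] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seqid, _src, ftype, start, end, _score, strand, _frame, attr_s = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attrs.pop("ID")
                genes[gid] = GffGene(gid, seqid, strand, [], attrs)
            elif ftype == "exon":
                parent = attrs["Parent"]
                genes[parent].exons.append((int(start) - 1, int(end)))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())


def spliced_sequence(contig_seq: str, exons: list[tuple[int, int]], strand: str) -> str:
    """Concatenate exon sequences in transcription order (revcomp on minus)."""
    from ._seq import revcomp

    parts = [contig_seq[s:e] for s, e in sorted(exons)]
    seq = "".join(parts)
    return revcomp(seq) if strand == "-" else seq


def write_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
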