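"""Low-level sequence helpers shared across the pipeline.

Thin wrappers over Bio.Seq plus k-mer utilities. Coordinates everywhere in the
package are 0-based half-open; GFF3 emission converts to 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

DNA_ALPHABET = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, to_stop: bool = False) -> str:
    """Standard-code translation of a CDS (length need not be a codon multiple;
    trailing partial codon is dropped)."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=to_stop))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    """I.i.d. uniform-within-class DNA at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(DNA_ALPHABET[i] for i in idx)


def kmers(seq: str, k: int):
    """Yield (offset, kmer) for every k-mer of seq."""
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_set(seq: str, k: int, canonical: bool = False) -> set[str]:
    out = set()
    for _, km in kmers(seq, k):
        out.add(canonical_kmer(km) if canonical else km)
    return out


def encode_dna(seq: str) -> np.ndarray:
    """DNA string -> uint8 array (A=0, C=1, G=2, T=3, other=4)."""
    lut = np.full(256, 4, dtype=np.uint8)
    for i, c in enumerate(DNA_ALPHABET):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
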