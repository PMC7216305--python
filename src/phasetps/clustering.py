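"""Greedy all-against-all protein clustering into representative sequences.

Centroid-style greedy set cover: proteins are ordered by (length descending,
id ascending); the first unassigned protein becomes a representative and
absorbs every unassigned protein that passes the bidirectional thresholds
against it (default minimum coverage 0.85 in both directions, minimum
identity 0.75, E-value floor 1e-5). Singletons are their own
representatives. The ordering rule makes the result independent of input
order.

Pairwise identity and coverage come from a global (Needleman-Wunsch, unit
cost) alignment of the pair: identity = matching columns / alignment
columns; coverage of each sequence = residue-to-residue aligned columns /
its length, and both directions must pass.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import edlib

DEFAULT_MIN_COV = 0.85
DEFAULT_MIN_ID = 0.75
DEFAULT_E_FLOOR = 1e-5
# Karlin-Altschul-style screen for the E-value floor on unit-cost matches
_KA_LAMBDA = 0.33
_KA_K = 0.14


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    mean_identity: float = 1.0


def pair_identity_coverage(seq_a: str, seq_b: str) -> tuple[float, float, float, int]:
    """(identity, coverage_a, coverage_b, matches) from a global alignment."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    cigar = res["cigar"]
    cols = matches = aligned_cols = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", cigar):
        num = int(num)
        cols += num
        if op == "=":
            matches += num
            aligned_cols += num
        elif op in "XM":
            aligned_cols += num
    identity = matches / cols if cols else 0.0
    cov_a = aligned_cols / len(seq_a)
    cov_b = aligned_cols / len(seq_b)
    return identity, cov_a, cov_b, matches


def _evalue(matches: int, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * matches)


def greedy_cluster(proteins: dict[str, str], min_cov: float = DEFAULT_MIN_COV,
                   min_id: float = DEFAULT_MIN_ID,
                   e_floor: float = DEFAULT_E_FLOOR) -> list[Cluster]:
    """Greedy clustering of a protein set; returns clusters partitioning the
    input (every protein in exactly one cluster)."""
    order = sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))
    assigned: set[str] = set()
    clusters: list[Cluster] = []
    for rep in order:
        if rep in assigned:
            continue
        assigned.add(rep)
        members = [rep]
        idents = [1.0]
        for cand in order:
            if cand in assigned:
                continue
            ident, cov_a, cov_b, matches = pair_identity_coverage(
                proteins[rep], proteins[cand])
            if ident < min_id or cov_a < min_cov or cov_b < min_cov:
                continue
            if _evalue(matches, len(proteins[rep]), len(proteins[cand])) > e_floor:
                continue
            assigned.add(cand)
            members.append(cand)
            idents.append(ident)
        clusters.append(Cluster(representative_id=rep, member_ids=members,
                                mean_identity=round(sum(idents) / len(idents), 6)))
    return clusters
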