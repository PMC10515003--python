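"""Greedy identity clustering of tandem-repeat monomers.

CD-HIT-style incremental clustering: monomers are sorted longest first and
each either joins the first existing cluster whose representative it
matches at or above the identity threshold, or founds a new cluster. The
word-filter heuristic of CD-HIT is unnecessary at monomer-set scale and is
replaced by exact alignment. Because monomers are reported from arbitrary
registers and strands, identity is computed circularly: the query is
aligned into the doubled representative (both strands) and identity is
matches over alignment columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from ._seq import revcomp
from .tandem_finder import Monomer, _cigar_counts


@dataclass
class MonomerCluster:
    """A family of mutually similar monomers."""

    representative: str  # canonical sequence of the founding (longest) member
    members: list[Monomer] = field(default_factory=list)

    @property
    def total_copies(self) -> float:
        return sum(m.copy_number for m in self.members)

    @property
    def mode_length(self) -> int:
        counts = Counter(len(m.sequence) for m in self.members)
        best = max(counts.values())
        return min(length for length, c in counts.items() if c == best)

    @property
    def length_histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(len(m.sequence) for m in self.members).items()))


def circular_identity(query: str, reference: str) -> float:
    """Best rotation/strand-invariant global identity of query vs reference.

    Aligns the query into the doubled reference (and its reverse
    complement) so any register offset is absorbed; identity is
    matches / alignment columns of the best alignment.
    """
    if not query or not reference:
        return 0.0
    best = 0.0
    doubled = reference + reference
    for q in (query, revcomp(query)):
        res = edlib.align(q, doubled, mode="HW", task="path")
        m, mm, ind = _cigar_counts(res["cigar"])
        cols = m + mm + ind
        if cols:
            best = max(best, m / cols)
    return best


def _as_monomer(m) -> Monomer:
    if isinstance(m, Monomer):
        return m
    from ._seq import canonical_monomer
    return Monomer(sequence=m, canonical=canonical_monomer(m), seq_id="",
                   start=0, end=len(m), copy_number=1.0)


def greedy_cluster(monomers, identity_threshold: float = 0.8) -> list[MonomerCluster]:
    """Cluster monomers at the given identity threshold.

    Input order does not matter: monomers are presorted by length
    descending, ties broken by canonical sequence. Clusters are returned
    sorted by total copy number descending (ties toward the
    lexicographically smaller representative).
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0.5, 1.0]")
    items = sorted((_as_monomer(m) for m in monomers),
                   key=lambda m: (-len(m.sequence), m.canonical, m.seq_id, m.start))
    clusters: list[MonomerCluster] = []
    for mono in items:
        for cl in clusters:
            if circular_identity(mono.canonical, cl.representative) >= identity_threshold:
                cl.members.append(mono)
                break
        else:
            clusters.append(MonomerCluster(representative=mono.canonical, members=[mono]))
    clusters.sort(key=lambda c: (-c.total_copies, c.representative))
    return clusters


def major_monomer(clusters):
    """Top cluster by total copies: (representative, mode_length, histogram).

    Ties between clusters are already broken deterministically by
    :func:`greedy_cluster` (lexicographically smaller representative).
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no monomers found: cannot determine a major monomer")
    top = clusters[0]
    return top.representative, top.mode_length, top.length_histogram
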