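"""Reference-guided contig anchoring with AGP emission.

Contigs are placed along guide pseudochromosomes by exact 31-mer anchors
(restricted to k-mers unique within a guide), chained per guide and
orientation with a longest-increasing-subsequence on guide coordinates.
A contig is placed at the diagonal extrapolation of its best chain when
the chain spans at least ``min_anchor_len`` on the guide and the implied
alignment identity reaches ``min_identity``; conflicts between
overlapping placements are resolved score-first by truncating small
overlaps and unplacing heavy losers. Gaps between non-adjacent consecutive
placements are emitted with their guide span as the length estimate; the
layout serializes to AGP v2.1 and back losslessly. Gaps are reported, not
filled.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from ._seq import kmer_codes, revcomp

ANCHOR_K = 31
_MAX_ANCHORS = 50_000  # subsample beyond this to bound LIS cost


@dataclass(frozen=True)
class Placement:
    """One contig anchored on a guide (0-based half-open guide interval)."""

    contig_id: str
    guide_id: str
    guide_start: int
    guide_end: int
    orientation: str  # '+' | '-'
    aligned_fraction: float = 1.0
    score: int = 0
    # portion of the oriented contig that the placement uses (for
    # truncated placements after conflict resolution)
    contig_start: int = 0
    contig_end: int | None = None


@dataclass(frozen=True)
class Gap:
    length: int | None  # None -> unknown size (AGP 'U', written as 100)

    @property
    def agp_length(self) -> int:
        return 100 if self.length is None else self.length


@dataclass
class AssemblyLayout:
    """Ordered contigs and gaps per guide, plus unplaced contigs."""

    components: dict = field(default_factory=dict)  # guide_id -> [Placement|Gap,...]
    unplaced: list = field(default_factory=list)  # (contig_id, reason)

    @property
    def n_gaps(self) -> int:
        return sum(sum(isinstance(c, Gap) for c in comps)
                   for comps in self.components.values())

    def placements(self, guide_id: str) -> list[Placement]:
        return [c for c in self.components.get(guide_id, []) if isinstance(c, Placement)]


class _GuideIndex:
    """Positions of k-mers that occur exactly once in the guide."""

    def __init__(self, sequence: str, k: int = ANCHOR_K):
        self.length = len(sequence)
        codes = kmer_codes(sequence, k)
        order = np.argsort(codes, kind="stable")
        sc = codes[order]
        uniq_mask = np.ones(len(sc), dtype=bool)
        uniq_mask[1:] &= sc[1:] != sc[:-1]
        uniq_mask[:-1] &= sc[:-1] != sc[1:]
        self.codes = sc[uniq_mask]
        self.positions = order[uniq_mask]

    def lookup(self, query_codes: np.ndarray):
        """(query_pos, guide_pos) anchor pairs for unique guide k-mers."""
        idx = np.searchsorted(self.codes, query_codes)
        idx_c = np.clip(idx, 0, len(self.codes) - 1)
        hit = len(self.codes) > 0
        mask = (self.codes[idx_c] == query_codes) if hit else \
            np.zeros(len(query_codes), dtype=bool)
        qpos = np.flatnonzero(mask)
        return qpos, self.positions[idx_c[mask]]


def _lis_chain(gpos: np.ndarray):
    """Longest strictly increasing subsequence of guide positions.

    Input is ordered by contig position; returns indices of the chain.
    """
    tails: list[int] = []  # gpos value of smallest tail per length
    tails_idx: list[int] = []
    parent = np.full(len(gpos), -1)
    for i, g in enumerate(gpos):
        j = bisect.bisect_left(tails, g)
        if j == len(tails):
            tails.append(g)
            tails_idx.append(i)
        else:
            tails[j] = g
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(i)
        i = parent[i]
    return chain[::-1]


def _best_chain(contig: str, guide_indexes: dict, k: int = ANCHOR_K):
    """Best (guide_id, orientation, chain anchors) and runner-up score."""
    results = []
    for orientation, seq in (("+", contig), ("-", revcomp(contig))):
        codes = kmer_codes(seq, k)
        if codes.size == 0:
            continue
        for guide_id, gidx in guide_indexes.items():
            qpos, gpos = gidx.lookup(codes)
            if qpos.size == 0:
                continue
            if qpos.size > _MAX_ANCHORS:
                stride = qpos.size // _MAX_ANCHORS + 1
                qpos, gpos = qpos[::stride], gpos[::stride]
            chain_idx = _lis_chain(gpos)
            if not chain_idx:
                continue
            cq, cg = qpos[chain_idx], gpos[chain_idx]
            results.append((len(chain_idx), guide_id, orientation, cq, cg))
    results.sort(key=lambda r: -r[0])
    if not results:
        return None, 0
    runner = results[1][0] if len(results) > 1 else 0
    return results[0], runner


def anchor_contigs(contigs: dict, guides: dict, min_anchor_len: int = 5000,
                   min_identity: float = 0.95, k: int = ANCHOR_K) -> AssemblyLayout:
    """Order and orient contigs along guide pseudochromosomes.

    Returns an :class:`AssemblyLayout`; contigs that cannot be placed are
    listed in ``layout.unplaced`` with a reason (``ambiguous`` for score
    ties between guides/orientations, ``no_anchor``, ``short_chain``,
    ``low_identity``, ``conflict``).
    """
    if not contigs or not guides:
        raise ValueError("contigs and guides must be non-empty")
    indexes = {gid: _GuideIndex(seq, k) for gid, seq in guides.items()}
    layout = AssemblyLayout(components={gid: [] for gid in guides})
    raw: dict[str, list[Placement]] = {gid: [] for gid in guides}

    for cid in sorted(contigs):
        contig = contigs[cid]
        best, runner = _best_chain(contig, indexes, k)
        if best is None:
            layout.unplaced.append((cid, "no_anchor"))
            continue
        score, guide_id, orientation, cq, cg = best
        if score == runner:
            layout.unplaced.append((cid, "ambiguous"))
            continue
        clen = len(contig)
        g_start = int(cg[0]) - int(cq[0])
        g_end = int(cg[-1]) + k + (clen - (int(cq[-1]) + k))
        g_start_cl = max(0, g_start)
        g_end_cl = min(indexes[guide_id].length, g_end)
        if g_end_cl - g_start_cl < min_anchor_len:
            layout.unplaced.append((cid, "short_chain"))
            continue
        oriented = contig if orientation == "+" else revcomp(contig)
        piece = oriented[g_start_cl - g_start: (g_start_cl - g_start) + (g_end_cl - g_start_cl)]
        guide_seq = guides[guide_id]
        dist = edlib.align(piece, guide_seq[g_start_cl:g_end_cl], mode="NW")["editDistance"]
        identity = 1.0 - dist / max(len(piece), g_end_cl - g_start_cl)
        if identity < min_identity:
            layout.unplaced.append((cid, "low_identity"))
            continue
        covered = min(clen, score * k)  # coarse anchor coverage bound
        raw[guide_id].append(Placement(
            contig_id=cid, guide_id=guide_id, guide_start=g_start_cl,
            guide_end=g_end_cl, orientation=orientation,
            aligned_fraction=round(covered / clen, 4), score=score,
            contig_start=g_start_cl - g_start,
            contig_end=(g_start_cl - g_start) + (g_end_cl - g_start_cl)))

    for guide_id, placements in raw.items():
        kept: list[Placement] = []
        for p in sorted(placements, key=lambda p: (-p.score, p.contig_id)):
            overlaps = [q for q in kept
                        if p.guide_start < q.guide_end and p.guide_end > q.guide_start]
            if overlaps:
                ov = sum(min(p.guide_end, q.guide_end) - max(p.guide_start, q.guide_start)
                         for q in overlaps)
                if ov >= 0.5 * (p.guide_end - p.guide_start) or len(overlaps) > 1:
                    layout.unplaced.append((p.contig_id, "conflict"))
                    continue
                q = overlaps[0]
                if p.guide_start < q.guide_start:  # truncate right side of p
                    trim = p.guide_end - q.guide_start
                    p = replace(p, guide_end=q.guide_start,
                                contig_end=p.contig_end - trim)
                else:  # truncate left side
                    trim = q.guide_end - p.guide_start
                    p = replace(p, guide_start=q.guide_end,
                                contig_start=p.contig_start + trim)
                if p.guide_end - p.guide_start < min_anchor_len:
                    layout.unplaced.append((p.contig_id, "conflict"))
                    continue
            kept.append(p)
        kept.sort(key=lambda p: p.guide_start)
        comps: list = []
        for i, p in enumerate(kept):
            if i > 0:
                gap_len = p.guide_start - kept[i - 1].guide_end
                if gap_len > 0:
                    comps.append(Gap(length=gap_len))
            comps.append(p)
        layout.components[guide_id] = comps
    return layout


def rebuild_sequence(layout: AssemblyLayout, contigs: dict, guide_id: str) -> str:
    """Assembled sequence for one guide; gaps become runs of N."""
    parts = []
    for comp in layout.components.get(guide_id, []):
        if isinstance(comp, Gap):
            parts.append("N" * comp.agp_length)
        else:
            seq = contigs[comp.contig_id]
            if comp.orientation == "-":
                seq = revcomp(seq)
            end = comp.contig_end if comp.contig_end is not None else len(seq)
            parts.append(seq[comp.contig_start:end])
    return "".join(parts)


def write_agp(layout: AssemblyLayout) -> str:
    """Serialize a layout as AGP v2.1 (1-based inclusive coordinates).

    Object coordinates start at 1 at the first placed component of each
    guide; known-size gaps become N lines, unknown-size gaps U lines of
    length 100 per AGP convention.
    """
    lines = ["##agp-version\t2.1"]
    for guide_id in sorted(layout.components):
        comps = layout.components[guide_id]
        if not comps:
            continue
        obj_pos = 1
        part = 1
        for comp in comps:
            if isinstance(comp, Gap):
                glen = comp.agp_length
                gtype = "U" if comp.length is None else "N"
                lines.append("\t".join(map(str, [
                    guide_id, obj_pos, obj_pos + glen - 1, part, gtype,
                    glen, "scaffold", "yes", "align_genus"])))
                obj_pos += glen
            else:
                cstart = comp.contig_start
                cend = comp.contig_end if comp.contig_end is not None \
                    else cstart + (comp.guide_end - comp.guide_start)
                clen = cend - cstart
                lines.append("\t".join(map(str, [
                    guide_id, obj_pos, obj_pos + clen - 1, part, "W",
                    comp.contig_id, cstart + 1, cend, comp.orientation])))
                obj_pos += clen
            part += 1
    return "\n".join(lines) + "\n"


def read_agp(text: str) -> AssemblyLayout:
    """Parse AGP v2.1 produced by :func:`write_agp`.

    Guide coordinates are reconstructed in object space (origin 0), so a
    write -> read -> write cycle reproduces the text exactly.
    """
    layout = AssemblyLayout()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        obj, obj_beg, obj_end, _part, ctype = f[0], int(f[1]), int(f[2]), f[3], f[4]
        comps = layout.components.setdefault(obj, [])
        if ctype in ("N", "U"):
            comps.append(Gap(length=None if ctype == "U" else int(f[5])))
        else:
            cstart, cend, orient = int(f[6]) - 1, int(f[7]), f[8]
            comps.append(Placement(
                contig_id=f[5], guide_id=obj, guide_start=obj_beg - 1,
                guide_end=obj_end, orientation=orient,
                contig_start=cstart, contig_end=cend))
    return layout
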