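"""Tandem-repeat array discovery and consensus monomer extraction.

A simplified tandem-repeat finder in the spirit of Benson's TRF: candidate
periods are proposed from the distance histogram of repeated k-mer seeds
inside sliding windows, then each candidate is verified by walking
period-sized copies against a provisional consensus with banded edit
distance, extending the array while per-copy identity stays above the
match-probability threshold. The classic TRF parameterization
(match 2, mismatch 7, indel 7, 80% match, 10% indel, min score 50,
max period 500) supplies the scoring weights and acceptance thresholds;
the probabilistic Bernoulli candidate model of the original tool is
replaced by the seed histogram.

Monomers destined for clustering are reported in a canonical form
(lexicographic minimum over rotations and strands) so that downstream
comparisons are register- and strand-invariant.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import canonical_monomer, kmer_codes

_SEED_K = 12
_WINDOW = 20_000
_STEP = 10_000
_MIN_SEED_SUPPORT = 3


@dataclass(frozen=True)
class TRFParams:
    """Scoring weights and thresholds (TRF '2 7 7 80 10 50 500' semantics)."""

    match_weight: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    match_prob_pct: int = 80
    indel_prob_pct: int = 10
    min_score: int = 50
    max_period: int = 500

    def validate(self) -> None:
        for f in ("match_weight", "mismatch_penalty", "indel_penalty",
                  "match_prob_pct", "indel_prob_pct", "min_score", "max_period"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class TandemArray:
    """One detected tandem-repeat locus (0-based half-open interval)."""

    seq_id: str
    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    score: int

    @property
    def canonical(self) -> str:
        return canonical_monomer(self.consensus)


@dataclass(frozen=True)
class Monomer:
    """A retained consensus monomer annotated with its source array."""

    sequence: str
    canonical: str
    seq_id: str
    start: int
    end: int
    copy_number: float


def _cigar_counts(cigar: str) -> tuple[int, int, int]:
    """(matches, mismatches, indels) from an edlib extended cigar."""
    matches = mismatches = indels = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            if ch == "=":
                matches += num
            elif ch == "X":
                mismatches += num
            else:  # I or D
                indels += num
            num = 0
    return matches, mismatches, indels


def _step_right(sequence: str, x: int, cons: str, max_dist: int):
    """Match one copy of ``cons`` starting at x; return (end, dist) or None."""
    band = max(2, len(cons) // 5)
    target = sequence[x: x + len(cons) + band]
    if len(target) < max(1, len(cons) - band):
        return None
    res = edlib.align(cons, target, mode="SHW", task="locations")
    if res["editDistance"] > max_dist:
        return None
    return x + res["locations"][0][1] + 1, res["editDistance"]


def _step_left(sequence: str, x: int, cons: str, max_dist: int):
    """Match one copy of ``cons`` ending at x; return (start, dist) or None."""
    band = max(2, len(cons) // 5)
    lo = max(0, x - len(cons) - band)
    target = sequence[lo:x][::-1]
    if len(target) < max(1, len(cons) - band):
        return None
    res = edlib.align(cons[::-1], target, mode="SHW", task="locations")
    if res["editDistance"] > max_dist:
        return None
    return x - (res["locations"][0][1] + 1), res["editDistance"]


def _collect_copies(sequence: str, anchor: int, cons: str, max_dist: int):
    """Greedy bidirectional copy collection around ``anchor``.

    Returns list of (start, end) copy intervals, sorted, or [] if the
    anchor itself does not match.
    """
    first = _step_right(sequence, anchor, cons, max_dist)
    if first is None:
        return []
    copies = [(anchor, first[0])]
    x = first[0]
    while True:
        nxt = _step_right(sequence, x, cons, max_dist)
        if nxt is None:
            break
        copies.append((x, nxt[0]))
        x = nxt[0]
    x = anchor
    while True:
        prv = _step_left(sequence, x, cons, max_dist)
        if prv is None:
            break
        copies.insert(0, (prv[0], x))
        x = prv[0]
    return copies


def _majority_consensus(sequence: str, copies, period: int) -> str | None:
    """Per-column majority vote over copies of exact period length.

    Ties broken toward the lexicographically smallest base.
    """
    full = [sequence[s:e] for s, e in copies if e - s == period]
    if not full:
        return None
    cols = np.array([list(c) for c in full])
    out = []
    for j in range(period):
        bases, counts = np.unique(cols[:, j], return_counts=True)
        best = counts.max()
        out.append(min(bases[counts == best]))  # lexicographic tie-break
    return "".join(out)


def _score_copies(sequence: str, copies, cons: str, params: TRFParams) -> int:
    score = 0
    for s, e in copies:
        res = edlib.align(sequence[s:e], cons, mode="NW", task="path")
        m, mm, ind = _cigar_counts(res["cigar"])
        score += params.match_weight * m - params.mismatch_penalty * mm \
            - params.indel_penalty * ind
    return score


def _build_array(sequence: str, seq_id: str, period: int, anchor: int,
                 params: TRFParams) -> TandemArray | None:
    """Verify one (period, anchor) candidate; two-pass consensus refinement."""
    if anchor + period > len(sequence):
        return None
    max_dist = int((1 - params.match_prob_pct / 100.0) * period)
    provisional = sequence[anchor: anchor + period]
    copies = _collect_copies(sequence, anchor, provisional, max_dist)
    if len(copies) < 2:
        return None
    cons = _majority_consensus(sequence, copies, period) or provisional
    # second pass with the voted consensus recovers copies the provisional
    # (itself a mutated copy) missed at the identity threshold
    copies = _collect_copies(sequence, copies[0][0], cons, max_dist)
    if len(copies) < 2:
        return None
    cons = _majority_consensus(sequence, copies, period) or cons
    start, end = copies[0][0], copies[-1][1]
    copy_number = (end - start) / period
    if copy_number < 1.8:
        return None
    score = _score_copies(sequence, copies, cons, params)
    if score < params.min_score:
        return None
    return TandemArray(seq_id=seq_id, start=start, end=end, period=period,
                       copy_number=round(copy_number, 2), consensus=cons, score=score)


def _seed_candidates(sequence: str, max_period: int, k: int = _SEED_K,
                     window: int = _WINDOW, step: int = _STEP,
                     min_support: int = _MIN_SEED_SUPPORT):
    """Candidate (period -> anchor positions) from repeated-seed distances."""
    candidates: dict[int, list[int]] = defaultdict(list)
    n = len(sequence)
    starts = range(0, max(1, n - k + 1), step)
    for w in starts:
        seg = sequence[w: w + window]
        if len(seg) < k + 1:
            continue
        codes = kmer_codes(seg, k)
        order = np.argsort(codes, kind="stable")
        sc, sp = codes[order], order  # positions ascend within equal codes (stable)
        same = sc[1:] == sc[:-1]
        dists = (sp[1:] - sp[:-1])[same]
        lo_pos = sp[:-1][same]
        valid = (dists >= 1) & (dists <= max_period)
        dists, lo_pos = dists[valid], lo_pos[valid]
        if dists.size == 0:
            continue
        uniq, counts = np.unique(dists, return_counts=True)
        for p in uniq[counts >= min_support]:
            pos = np.sort(lo_pos[dists == p]) + w
            candidates[int(p)].extend(int(x) for x in pos)
    return candidates


def _group_anchors(positions: list[int], gap: int) -> list[list[int]]:
    positions = sorted(set(positions))
    groups, cur = [], [positions[0]]
    for x in positions[1:]:
        if x - cur[-1] <= gap:
            cur.append(x)
        else:
            groups.append(cur)
            cur = [x]
    groups.append(cur)
    return groups


def find_arrays(sequence: str, params: TRFParams | None = None,
                seq_id: str = "seq") -> list[TandemArray]:
    """Detect tandem-repeat arrays in ``sequence``.

    Candidate periods come from equal-distance repeated 12-mer seeds in
    20 kb windows (10 kb step); candidates are processed shortest period
    first, and a candidate anchored inside an already-accepted array is
    skipped, which suppresses the period-multiple echoes every true array
    produces. Overlapping accepted calls with the same period are merged
    and re-scored over the union interval. Zero arrays is a valid result.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    params = params or TRFParams()
    params.validate()
    candidates = _seed_candidates(sequence, params.max_period)
    accepted: list[TandemArray] = []

    def covered(pos: int) -> bool:
        return any(a.start <= pos < a.end for a in accepted)

    for period in sorted(candidates):
        for group in _group_anchors(candidates[period], gap=max(3 * period, 500)):
            anchors = [group[0], group[len(group) // 2], group[-1]]
            best = None
            for anchor in dict.fromkeys(anchors):
                if covered(anchor):
                    continue
                arr = _build_array(sequence, seq_id, period, anchor, params)
                if arr and (best is None or arr.score > best.score):
                    best = arr
            if best is None:
                continue
            # harmonic echo: an array mostly covered by an accepted
            # shorter-period array is the same locus read at a multiple
            shorter_cov = sum(
                max(0, min(best.end, a.end) - max(best.start, a.start))
                for a in accepted if a.period < best.period)
            if shorter_cov >= 0.5 * (best.end - best.start):
                continue
            merged = False
            for i, other in enumerate(accepted):
                if abs(other.period - best.period) <= 1 and \
                        best.start < other.end and best.end > other.start:
                    start = min(best.start, other.start)
                    end = max(best.end, other.end)
                    max_dist = int((1 - params.match_prob_pct / 100.0) * other.period)
                    copies = _collect_copies(sequence, start, other.consensus, max_dist)
                    if copies:
                        end = max(end, copies[-1][1])
                        score = _score_copies(sequence, copies, other.consensus, params)
                    else:
                        score = max(best.score, other.score)
                    accepted[i] = TandemArray(
                        seq_id=seq_id, start=start, end=end, period=other.period,
                        copy_number=round((end - start) / other.period, 2),
                        consensus=other.consensus, score=score)
                    merged = True
                    break
            if not merged:
                accepted.append(best)
    accepted.sort(key=lambda a: (a.start, a.period))
    return accepted


def filter_monomers(arrays, min_len: int = 100, max_len: int = 200) -> list[Monomer]:
    """Retain arrays whose period lies in [min_len, max_len]; emit consensi.

    The 100-200 bp default brackets the length range of plant centromeric
    satellite monomers and is the filter applied to whole-genome tandem
    repeats before clustering.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    out = []
    for a in arrays:
        if min_len <= a.period <= max_len:
            out.append(Monomer(sequence=a.consensus, canonical=a.canonical,
                               seq_id=a.seq_id, start=a.start, end=a.end,
                               copy_number=a.copy_number))
    return out
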