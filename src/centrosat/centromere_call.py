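"""Centromere localization from satellite-monomer hit density.

The dominant monomer cluster is scanned across each chromosome; windows
with many monomer hits are thresholded and merged into candidate runs, and
the longest continuous high-frequency run becomes the centromere call.
The call is then cross-checked against gene density (expected lower inside
the centromere) and class-I retrotransposon density (expected at least as
high inside), and a windowed self-similarity matrix can be emitted to
visualize the satellite block the way a 50-kb dotplot heatmap does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from ._seq import kmer_codes, revcomp
from .monomer_cluster import greedy_cluster, major_monomer
from .tandem_finder import TRFParams, filter_monomers, find_arrays

_HIT_SEED_K = 12


@dataclass
class DensityTrack:
    """Per-window counts along one chromosome."""

    seq_id: str
    window: int
    step: int
    seq_length: int
    values: np.ndarray
    label: str = ""  # what was counted (cluster id, "gene", "te_I", ...)
    hit_positions: np.ndarray | None = None  # start of each verified hit
    hit_length: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.values)


def _window_count(seq_length: int, window: int, step: int) -> int:
    if seq_length <= window:
        return 1
    return int(np.ceil((seq_length - window) / step)) + 1


def _bin_positions(positions: np.ndarray, seq_length: int, window: int, step: int):
    nw = _window_count(seq_length, window, step)
    pos = np.sort(positions)
    values = np.empty(nw, dtype=int)
    for i in range(nw):
        lo, hi = i * step, i * step + window
        values[i] = np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
    return values


def monomer_hit_track(sequence: str, clusters, window: int = 10_000,
                      step: int = 10_000, identity: float = 0.8,
                      seq_id: str = "seq") -> DensityTrack:
    """Count top-cluster monomer occurrences per window, both strands.

    Candidate loci are pre-filtered with shared 12-mers against the
    doubled representative (so all registers are caught), then verified by
    rotation/strand-tolerant edit distance at the given identity.
    """
    if window < step:
        raise ValueError("window must be >= step")
    rep = clusters[0].representative if clusters else ""
    if not rep:
        return DensityTrack(seq_id, window, step, len(sequence),
                            np.zeros(_window_count(len(sequence), window, step), dtype=int))
    L = len(rep)
    max_dist = int(round((1 - identity) * L))
    targets = (rep + rep, revcomp(rep) + revcomp(rep))
    seeds = np.unique(np.concatenate([kmer_codes(t, _HIT_SEED_K) for t in targets]))
    codes = kmer_codes(sequence, _HIT_SEED_K)
    marked = np.flatnonzero(np.isin(codes, seeds))

    hits = []
    i = 0
    n = len(sequence)
    while i < len(marked):
        x = int(marked[i])
        if hits and x < hits[-1] + L:
            i += 1
            continue
        seg = sequence[x: x + L]
        if len(seg) == L:
            dists = [edlib.align(seg, t, mode="HW", k=max_dist)["editDistance"]
                     for t in targets]
            # edlib reports -1 when the distance exceeds k
            if any(d != -1 for d in dists):
                hits.append(x)
                # skip seeds inside the accepted copy
                i = int(np.searchsorted(marked, x + L))
                continue
        i += 1
    hits = np.array(hits, dtype=int)
    values = _bin_positions(hits, n, window, step)
    return DensityTrack(seq_id=seq_id, window=window, step=step, seq_length=n,
                        values=values, label="monomer", hit_positions=hits,
                        hit_length=L)


def interval_track(intervals, seq_length: int, window: int = 10_000,
                   step: int = 10_000, mode: str = "count", seq_id: str = "seq",
                   label: str = "") -> DensityTrack:
    """Density track from annotation intervals.

    ``mode='count'`` counts intervals overlapping each window (gene
    density); ``mode='bp'`` sums overlap bp (TE density).
    """
    nw = _window_count(seq_length, window, step)
    values = np.zeros(nw, dtype=float)
    for i in range(nw):
        lo, hi = i * step, i * step + window
        for iv in intervals:
            s, e = iv[0], iv[1]
            ov = min(e, hi) - max(s, lo)
            if ov > 0:
                values[i] += ov if mode == "bp" else 1
    return DensityTrack(seq_id=seq_id, window=window, step=step,
                        seq_length=seq_length, values=values, label=label)


@dataclass
class CentromereCall:
    """One candidate centromere interval (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    supporting_cluster: str
    hit_fraction: float
    mean_gene_density_inside: float | None = None
    mean_gene_density_outside: float | None = None
    status: str = "candidate"  # candidate | pass | warn
    flags: dict = field(default_factory=dict)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def report_interval(self) -> tuple[int, int]:
        """1-based inclusive coordinates for human-readable reports."""
        return self.start + 1, self.end


def call_centromere(track: DensityTrack, min_density: float = 5,
                    max_gap: int = 2) -> CentromereCall | None:
    """Call the centromere from a monomer-hit density track.

    Windows at >= ``min_density`` hits are merged into runs, runs
    separated by <= ``max_gap`` sub-threshold windows are joined, and the
    longest run (ties: highest total hits) becomes the call, with
    boundaries snapped to the outermost verified monomer hit inside it.
    Returns None when no window passes the threshold (no definite
    centromere).
    """
    if track.n_windows == 0:
        return None
    above = np.flatnonzero(track.values >= min_density)
    if above.size == 0:
        return None
    runs = []
    run_start = prev = above[0]
    for idx in above[1:]:
        if idx - prev <= max_gap + 1:
            prev = idx
        else:
            runs.append((run_start, prev))
            run_start = prev = idx
    runs.append((run_start, prev))

    def run_key(r):
        i, j = r
        total = track.values[i:j + 1].sum()
        return (j - i, total)

    i, j = max(runs, key=run_key)
    start = i * track.step
    end = min(track.seq_length, j * track.step + track.window)
    total_hits = track.values.sum() if track.hit_positions is None \
        else len(track.hit_positions)
    if track.hit_positions is not None and len(track.hit_positions):
        inside = track.hit_positions[(track.hit_positions >= start)
                                     & (track.hit_positions < end)]
        if inside.size:
            start = int(inside.min())
            end = int(inside.max()) + track.hit_length
        n_inside = inside.size
    else:
        n_inside = float(track.values[i:j + 1].sum())
    frac = float(n_inside / total_hits) if total_hits else 0.0
    return CentromereCall(seq_id=track.seq_id, start=start, end=end,
                          supporting_cluster=track.label or "cluster0",
                          hit_fraction=frac)


def _mean_inside_outside(call: CentromereCall, track: DensityTrack):
    nw = track.n_windows
    inside = []
    outside = []
    for i in range(nw):
        lo, hi = i * track.step, i * track.step + track.window
        (inside if (min(hi, call.end) - max(lo, call.start)) > 0 else outside).append(
            track.values[i])
    m_in = float(np.mean(inside)) if inside else 0.0
    m_out = float(np.mean(outside)) if outside else 0.0
    return m_in, m_out


def evidence_check(call: CentromereCall, gene_track: DensityTrack,
                   te_track: DensityTrack) -> CentromereCall:
    """Cross-check a call against gene and class-I TE density.

    Pass requires mean gene density inside < outside and class-I TE
    density inside >= outside; a failed criterion downgrades the call to
    'warn' but never deletes it.
    """
    g_in, g_out = _mean_inside_outside(call, gene_track)
    t_in, t_out = _mean_inside_outside(call, te_track)
    flags = {"gene_density": g_in < g_out, "te_class_i": t_in >= t_out}
    status = "pass" if all(flags.values()) else "warn"
    return replace(call, mean_gene_density_inside=g_in,
                   mean_gene_density_outside=g_out, status=status, flags=flags)


def similarity_heatmap(sequence: str, window: int = 50_000, k: int = 21) -> np.ndarray:
    """Pairwise window self-similarity matrix (satellite blocks light up).

    Windows tile the sequence; similarity is the Jaccard fraction of
    shared canonical k-mers (k=21), giving an alignment-free analogue of a
    50-kb dotplot: exactly symmetric with unit diagonal.
    """
    if len(sequence) < 2 * window:
        raise ValueError("sequence must span at least two windows")
    n = len(sequence) // window
    sets = []
    for i in range(n):
        seg = sequence[i * window:(i + 1) * window]
        fwd = kmer_codes(seg, k)
        rev = kmer_codes(revcomp(seg), k)[::-1]
        sets.append(np.unique(np.minimum(fwd, rev)))
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.intersect1d(sets[i], sets[j], assume_unique=True).size
            union = sets[i].size + sets[j].size - inter
            m[i, j] = m[j, i] = inter / union if union else 0.0
    return m


def locate_centromeres(sequences: dict, gene_truth: dict | None = None,
                       te_truth: dict | None = None,
                       params: TRFParams | None = None,
                       monomer_min_len: int = 100, monomer_max_len: int = 200,
                       cluster_identity: float = 0.8, window: int = 10_000,
                       step: int = 10_000, hit_identity: float = 0.8,
                       min_density: float = 5, max_gap: int = 2) -> dict:
    """Full centromere pipeline over a genome.

    Runs tandem-repeat discovery on every chromosome, filters monomers to
    the centromeric length band, clusters them genome-wide, builds
    monomer-hit tracks against the dominant cluster and calls one
    centromere per chromosome, with density evidence checks when gene/TE
    annotations are supplied. Returns
    ``{"clusters", "major_monomer", "calls", "tracks"}``.
    """
    monomers = []
    for seq_id, seq in sequences.items():
        arrays = find_arrays(seq, params=params, seq_id=seq_id)
        monomers.extend(filter_monomers(arrays, monomer_min_len, monomer_max_len))
    clusters = greedy_cluster(monomers, cluster_identity) if monomers else []
    result = {"clusters": clusters, "major_monomer": None, "calls": {}, "tracks": {}}
    if not clusters:
        return result
    result["major_monomer"] = major_monomer(clusters)
    for seq_id, seq in sequences.items():
        track = monomer_hit_track(seq, clusters, window=window, step=step,
                                  identity=hit_identity, seq_id=seq_id)
        call = call_centromere(track, min_density=min_density, max_gap=max_gap)
        if call is not None and gene_truth is not None and te_truth is not None:
            gt = interval_track(gene_truth.get(seq_id, []), len(seq), window, step,
                                mode="count", seq_id=seq_id, label="gene")
            tes = [(s, e) for s, e, cls in te_truth.get(seq_id, []) if cls == "I"]
            tt = interval_track(tes, len(seq), window, step, mode="bp",
                                seq_id=seq_id, label="te_I")
            call = evidence_check(call, gt, tt)
        result["tracks"][seq_id] = track
        result["calls"][seq_id] = call
    return result
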