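"""Telomeric repeat detection at chromosome termini.

Counts copies of the plant telomeric heptamer (canonical search query
``AAACCCT``, i.e. the TTTAGGG family) in a terminal window at each
chromosome end. All seven circular rotations of the motif are accepted so
that register shifts inside an array do not split counts; the 5' end is
searched with the reverse-complement (C-rich) rotations and the 3' end
with the forward (G-rich) rotations, matching the strand layout of plant
chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp, rotations

DEFAULT_MOTIF = "AAACCCT"
DEFAULT_WINDOW = 10_000
DEFAULT_MIN_COPIES = 20


@dataclass(frozen=True)
class TelomereReport:
    """Motif counts for one chromosome end."""

    seq_id: str
    end: str  # "five_prime" | "three_prime"
    repeat_count: int
    span_bp: int
    present: bool
    window: int
    truncated: bool = False  # window shortened on a short sequence


def _orientation_sets(motif: str) -> tuple[set[str], set[str]]:
    """(five_prime_rotations, three_prime_rotations) for a 7-mer query.

    The G-richer of motif/reverse-complement is taken as the forward (3')
    orientation; its reverse complement serves the 5' end. For the default
    query AAACCCT the forward family is the TTTAGGG rotations.
    """
    rc = revcomp(motif)
    forward = motif if motif.count("G") >= rc.count("G") else rc
    return set(rotations(revcomp(forward))), set(rotations(forward))


def _greedy_count(window_seq: str, motifs: set[str], k: int) -> tuple[int, int]:
    """Non-overlapping greedy left-to-right motif count and run span."""
    count, first, last, pos = 0, -1, -1, 0
    n = len(window_seq)
    while pos <= n - k:
        if window_seq[pos:pos + k] in motifs:
            if first < 0:
                first = pos
            last = pos + k
            count += 1
            pos += k
        else:
            pos += 1
    span = (last - first) if count else 0
    return count, span


def count_terminal_repeats(sequence: str, seq_id: str = "seq",
                           motif: str = DEFAULT_MOTIF,
                           window: int = DEFAULT_WINDOW,
                           min_copies: int = DEFAULT_MIN_COPIES):
    """Count telomeric repeats in the two terminal windows of a sequence.

    Returns a ``(five_prime, three_prime)`` pair of
    :class:`TelomereReport`. Sequences shorter than twice the window are
    scanned with half-length windows and flagged ``truncated``.
    """
    if len(motif) != 7:
        raise ValueError("telomeric query motif must be 7 bp")
    truncated = len(sequence) <= 2 * window
    win = len(sequence) // 2 if truncated else window
    five_set, three_set = _orientation_sets(motif)
    reports = []
    for end, motifs, segment in (
        ("five_prime", five_set, sequence[:win]),
        ("three_prime", three_set, sequence[len(sequence) - win:]),
    ):
        count, span = _greedy_count(segment, motifs, 7)
        reports.append(TelomereReport(seq_id=seq_id, end=end, repeat_count=count,
                                      span_bp=span, present=count >= min_copies,
                                      window=win, truncated=truncated))
    return tuple(reports)


def scan_genome(sequences: dict, **kwargs) -> list[TelomereReport]:
    """Run :func:`count_terminal_repeats` on every sequence of a genome."""
    reports = []
    for seq_id in sequences:
        reports.extend(count_terminal_repeats(sequences[seq_id], seq_id=seq_id, **kwargs))
    return reports


def summarize_telomeres(reports) -> dict:
    """Genome-level telomere summary.

    ``n_telomeres`` counts ends called present; ``n_t2t_chromosomes``
    counts chromosomes with both ends present (telomere-to-telomere);
    range and mean are over the counts of present ends only.
    """
    reports = list(reports)
    if not reports:
        return {"n_telomeres": 0, "n_t2t_chromosomes": 0,
                "count_range": (0, 0), "count_mean": 0.0}
    by_chrom: dict[str, dict[str, bool]] = {}
    present_counts = []
    for r in reports:
        by_chrom.setdefault(r.seq_id, {})[r.end] = r.present
        if r.present:
            present_counts.append(r.repeat_count)
    n_t2t = sum(1 for ends in by_chrom.values()
                if ends.get("five_prime") and ends.get("three_prime"))
    if present_counts:
        rng = (min(present_counts), max(present_counts))
        mean = sum(present_counts) / len(present_counts)
    else:
        rng, mean = (0, 0), 0.0
    return {"n_telomeres": len(present_counts), "n_t2t_chromosomes": n_t2t,
            "count_range": rng, "count_mean": mean}
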