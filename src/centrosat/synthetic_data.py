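"""Synthetic genomes, contig sets and allele count tables with planted truth.

Every downstream stage of the pipeline (telomere scan, tandem-repeat
discovery, monomer clustering, centromere calling, contig anchoring, ASE
calling) is exercised against genomes produced here, so each generator
records the planted ground truth alongside its output.

A simulated chromosome is laid out as::

    [5' telomere][arm 1][centromeric region][arm 2][3' telomere]

* Telomeres are tandem runs of the plant heptamer family: the 5' end
  carries the reverse-complement orientation (CCCTAAA rotations) and the
  3' end the forward TTTAGGG orientation, each copy substituted at
  ``telomere_mutation_rate``.
* The centromeric region is a satellite array built by head-to-tail
  concatenation of a single random seed monomer (default 153 bp, the
  length of the major kiwifruit centromeric monomer), each copy
  independently substituted at ``monomer_divergence``. Real plant
  centromeres are punctuated by LTR retrotransposon insertions, so the
  array is split into blocks separated by class-I TE cassettes; the truth
  interval spans the whole region.
* Arms are uniform i.i.d. DNA overwritten with TE-like cassettes (a fixed
  library of three 500-3000 bp elements, two class-I and one class-II,
  reused with 2% per-copy mutation) up to ``te_density``, and carry the
  gene models. Genes are deliberately excluded from the centromeric
  region, mirroring the low gene density of real centromeres.

All randomness flows through one ``numpy`` generator per call, seeded from
the spec, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import mutate, random_dna, revcomp

TELOMERE_FORWARD = "TTTAGGG"  # 3' orientation; 5' ends carry its reverse complement

#: dispersion (1/size) of the negative binomial used for allele counts;
#: corresponds to a ~22% biological CV on top of Poisson noise.
NB_DISPERSION = 0.05

_TE_CLASS_I_ARM_SHARE = 0.4  # fraction of arm TE bp assigned to class-I elements
_CENTROMERE_TE_SPACING = 10_000  # one class-I insertion per this many array bp


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one simulated genome."""

    n_chromosomes: int = 5
    chrom_length: int = 500_000
    telomere_copies_per_end: int = 300
    telomere_mutation_rate: float = 0.02
    centromere_monomer_length: int = 153
    centromere_array_length: int = 30_600
    monomer_divergence: float = 0.05
    te_density: float = 0.10
    n_genes_per_chrom: int = 40
    rng_seed: int = 0
    #: (chromosome index, "five_prime"/"three_prime") ends left bare
    telomere_dropout_ends: tuple = ()

    def validate(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "telomere_copies_per_end",
                     "centromere_monomer_length", "centromere_array_length",
                     "n_genes_per_chrom"):
            if getattr(self, name) < 0 or (name.endswith("length") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        for name in ("telomere_mutation_rate", "monomer_divergence", "te_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.centromere_array_length >= self.chrom_length / 2:
            raise ValueError(
                "centromere_array_length must be < chrom_length/2 "
                "(layout with telomeres and arms is otherwise unbuildable)")


@dataclass
class TruthSet:
    """Planted ground truth for one simulated dataset.

    Intervals are 0-based half-open. Fields populated by a generator that
    was not run stay empty.
    """

    telomere_truth: dict = field(default_factory=dict)  # (seq_id, end) -> copies
    centromere_truth: dict = field(default_factory=dict)  # seq_id -> (start, end)
    centromere_copy_starts: dict = field(default_factory=dict)  # seq_id -> [int]
    monomer_truth: str = ""
    gene_truth: dict = field(default_factory=dict)  # seq_id -> [(start, end)]
    te_truth: dict = field(default_factory=dict)  # seq_id -> [(start, end, "I"|"II")]
    contig_truth: list = field(default_factory=list)  # ContigPlacementTruth
    ase_truth: pd.DataFrame | None = None

    def to_jsonable(self) -> dict:
        d = {
            "telomere_truth": {f"{s}:{e}": c for (s, e), c in self.telomere_truth.items()},
            "centromere_truth": {s: list(v) for s, v in self.centromere_truth.items()},
            "monomer_truth": self.monomer_truth,
            "gene_truth": {s: [list(g) for g in v] for s, v in self.gene_truth.items()},
            "te_truth": {s: [list(t) for t in v] for s, v in self.te_truth.items()},
            "contig_truth": [dataclasses.asdict(c) for c in self.contig_truth],
        }
        if self.ase_truth is not None:
            d["ase_truth"] = self.ase_truth.to_dict(orient="records")
        return d


@dataclass(frozen=True)
class ContigPlacementTruth:
    contig_id: str
    seq_id: str
    start: int
    end: int
    orientation: str  # '+' or '-'
    withheld: bool


def _round_count(fraction: float, n: int) -> int:
    """Half-up rounding used for 'fraction of n items' draws."""
    return int(fraction * n + 0.5)


def _plant_telomere(rng, copies: int, rate: float, orientation: str) -> str:
    unit = revcomp(TELOMERE_FORWARD) if orientation == "five_prime" else TELOMERE_FORWARD
    return "".join(mutate(rng, unit, rate) for _ in range(copies))


def _build_centromere(rng, spec: GenomeSpec, monomer: str, te_library):
    """Satellite array split into blocks by class-I cassettes.

    Returns (sequence, copy_starts, te_intervals) with region-relative
    coordinates.
    """
    n_copies = spec.centromere_array_length // spec.centromere_monomer_length
    n_inserts = max(1, round(spec.centromere_array_length / _CENTROMERE_TE_SPACING))
    n_inserts = min(n_inserts, max(0, n_copies - 1))
    # insertion points between copies, distinct
    cuts = sorted(rng.choice(np.arange(1, n_copies), size=n_inserts, replace=False)) \
        if n_inserts else []
    class_i = [e for e, cls in te_library if cls == "I"]
    parts, copy_starts, te_intervals = [], [], []
    pos = 0
    prev = 0
    for cut in list(cuts) + [n_copies]:
        for _ in range(prev, cut):
            copy_starts.append(pos)
            copy = mutate(rng, monomer, spec.monomer_divergence)
            parts.append(copy)
            pos += len(copy)
        if cut < n_copies:
            elem = class_i[rng.integers(0, len(class_i))]
            cassette = mutate(rng, elem, 0.02)
            te_intervals.append((pos, pos + len(cassette), "I"))
            parts.append(cassette)
            pos += len(cassette)
        prev = cut
    return "".join(parts), copy_starts, te_intervals


def _plant_arm_tes(rng, arm: str, te_library, te_density: float):
    """Overwrite background with TE cassettes up to ``te_density`` of arm bp."""
    target = te_density * len(arm)
    class_i_target = _TE_CLASS_I_ARM_SHARE * target
    arm_list = list(arm)
    placed, planted_bp, class_i_bp = [], 0, 0
    attempts = 0
    while planted_bp < target and attempts < 10 * len(te_library):
        attempts += 1
        want_class_i = class_i_bp < class_i_target
        pool = [t for t in te_library if (t[1] == "I") == want_class_i] or te_library
        elem, cls = pool[rng.integers(0, len(pool))]
        if len(elem) >= len(arm_list):
            break
        start = int(rng.integers(0, len(arm_list) - len(elem)))
        if any(start < e and start + len(elem) > s for s, e, _ in placed):
            continue
        cassette = mutate(rng, elem, 0.02)
        arm_list[start:start + len(cassette)] = list(cassette)
        placed.append((start, start + len(cassette), cls))
        planted_bp += len(cassette)
        if cls == "I":
            class_i_bp += len(cassette)
    placed.sort()
    return "".join(arm_list), placed


def _place_genes(rng, n: int, lo: int, hi: int):
    """Non-overlapping gene intervals within [lo, hi); best effort."""
    genes = []
    for _ in range(20 * n):
        if len(genes) == n:
            break
        length = int(rng.integers(1000, 5001))
        if hi - lo <= length:
            continue
        start = int(rng.integers(lo, hi - length))
        if any(start < e and start + length > s for s, e in genes):
            continue
        genes.append((start, start + length))
    genes.sort()
    return genes


def simulate_genome(spec: GenomeSpec):
    """Simulate a genome with planted telomeres, centromeres, TEs and genes.

    Returns ``(sequences, annotations, truth)`` where ``sequences`` maps
    seq_id to DNA string, ``annotations`` maps seq_id to gene interval
    lists (same object as ``truth.gene_truth``), and ``truth`` is the
    :class:`TruthSet`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    monomer = random_dna(rng, spec.centromere_monomer_length)
    # class-I (retrotransposon-like) elements are the long ones, as in real
    # genomes where LTR elements dominate pericentromeric repeat mass
    te_library = []
    for cls, lo, hi in (("I", 1500, 3001), ("I", 1500, 3001), ("II", 500, 1501)):
        te_library.append((random_dna(rng, int(rng.integers(lo, hi))), cls))

    truth = TruthSet(monomer_truth=monomer)
    sequences: dict[str, str] = {}
    dropped = set(spec.telomere_dropout_ends)
    for ci in range(spec.n_chromosomes):
        seq_id = f"chr{ci + 1:02d}"
        tel = {}
        for end in ("five_prime", "three_prime"):
            copies = 0 if (ci, end) in dropped else spec.telomere_copies_per_end
            tel[end] = _plant_telomere(rng, copies, spec.telomere_mutation_rate, end)
            truth.telomere_truth[(seq_id, end)] = copies

        cen_seq, rel_copy_starts, rel_tes = _build_centromere(rng, spec, monomer, te_library)

        arms_total = spec.chrom_length - len(tel["five_prime"]) - len(tel["three_prime"]) - len(cen_seq)
        if arms_total < 2 * len(cen_seq) // 10 + 2000:
            raise ValueError("chromosome too short for the requested layout")
        frac = rng.uniform(0.3, 0.7)
        arm1_len = int(arms_total * frac)
        arm1, tes1 = _plant_arm_tes(rng, random_dna(rng, arm1_len), te_library, spec.te_density)
        arm2, tes2 = _plant_arm_tes(rng, random_dna(rng, arms_total - arm1_len),
                                    te_library, spec.te_density)

        off_arm1 = len(tel["five_prime"])
        off_cen = off_arm1 + len(arm1)
        off_arm2 = off_cen + len(cen_seq)
        sequences[seq_id] = tel["five_prime"] + arm1 + cen_seq + arm2 + tel["three_prime"]

        truth.centromere_truth[seq_id] = (off_cen, off_arm2)
        truth.centromere_copy_starts[seq_id] = [off_cen + s for s in rel_copy_starts]
        tes = [(off_arm1 + s, off_arm1 + e, c) for s, e, c in tes1]
        tes += [(off_cen + s, off_cen + e, c) for s, e, c in rel_tes]
        tes += [(off_arm2 + s, off_arm2 + e, c) for s, e, c in tes2]
        truth.te_truth[seq_id] = sorted(tes)

        n1 = min(spec.n_genes_per_chrom, max(0, round(spec.n_genes_per_chrom * frac)))
        genes = _place_genes(rng, n1, off_arm1, off_cen)
        genes += _place_genes(rng, spec.n_genes_per_chrom - n1, off_arm2,
                              off_arm2 + len(arm2))
        truth.gene_truth[seq_id] = genes

    return sequences, truth.gene_truth, truth


def fragment_contigs(sequences: dict, n_breaks_per_chrom: int, dropout: float = 0.0,
                     invert_prob: float = 0.0, rng_seed: int = 0,
                     min_piece: int = 10_000):
    """Cut chromosomes into contigs; withhold and reverse-complement some.

    Per chromosome, ``n_breaks_per_chrom`` internal breakpoints partition
    the sequence into pieces no shorter than ``min_piece`` (breakpoints
    are drawn uniformly with that spacing constraint, mimicking
    assembler-scale contigs); ``round(dropout * n_pieces)`` pieces
    (half-up rounding) are withheld to create true gaps, and
    ``round(invert_prob * n_pieces)`` of the source pieces are emitted
    reverse-complemented. Returns ``(contigs, truth_placements)``; contig
    output order is shuffled so downstream anchoring is non-trivial.
    """
    if n_breaks_per_chrom < 0:
        raise ValueError("n_breaks_per_chrom must be >= 0")
    for name, v in (("dropout", dropout), ("invert_prob", invert_prob)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    contigs: dict[str, str] = {}
    truth: list[ContigPlacementTruth] = []
    for seq_id in sorted(sequences):
        seq = sequences[seq_id]
        n_breaks = min(n_breaks_per_chrom, len(seq) - 1)
        # spacing transform: uniform draws in the shrunken interval plus
        # fixed offsets guarantee every piece is >= spacing long
        spacing = min(min_piece, len(seq) // (n_breaks + 1)) if n_breaks else 0
        slack = len(seq) - (n_breaks + 1) * spacing
        raw = np.sort(rng.integers(0, slack + 1, size=n_breaks))
        breaks = [int(raw[i]) + (i + 1) * spacing for i in range(n_breaks)]
        bounds = [0] + breaks + [len(seq)]
        n_pieces = len(bounds) - 1
        withheld = set(rng.choice(n_pieces, size=_round_count(dropout, n_pieces),
                                  replace=False).tolist())
        inverted = set(rng.choice(n_pieces, size=_round_count(invert_prob, n_pieces),
                                  replace=False).tolist())
        for i in range(n_pieces):
            start, end = bounds[i], bounds[i + 1]
            cid = f"ctg_{seq_id}_{i:03d}"
            orient = "-" if i in inverted else "+"
            truth.append(ContigPlacementTruth(cid, seq_id, start, end, orient, i in withheld))
            if i not in withheld:
                piece = seq[start:end]
                contigs[cid] = revcomp(piece) if orient == "-" else piece
    order = list(contigs)
    perm = rng.permutation(len(order))
    contigs = {order[i]: contigs[order[i]] for i in perm}
    return contigs, truth


def simulate_allele_counts(n_pairs: int, n_samples: int = 6, ase_fraction: float = 0.1,
                           inconsistent_fraction: float = 0.0, mean_depth: int = 200,
                           rng_seed: int = 0, fold_change: float = 4.0):
    """Negative-binomial allele count tables with planted ASE structure.

    Non-ASE pairs share the allele mean ``mean_depth``. Planted ASE pairs
    get a ``fold_change``-fold mean ratio (default 4, always >= 2.5)
    split symmetrically around ``mean_depth``; inconsistent pairs flip the
    bias direction in a random non-empty proper subset of samples.
    ``inconsistent_fraction`` is a fraction of all pairs and must not
    exceed ``ase_fraction``. Counts use dispersion :data:`NB_DISPERSION`.

    Returns ``(counts, gene_lengths, ase_truth)``: a long-format DataFrame
    (pair_id, allele, sample, count), a Series of per-pair gene lengths in
    bp, and a truth DataFrame (pair_id, is_ase, pattern, direction columns
    per sample; direction +1 = allele A up, -1 = allele B up, 0 = none).
    """
    for name, v in (("ase_fraction", ase_fraction),
                    ("inconsistent_fraction", inconsistent_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if inconsistent_fraction > ase_fraction:
        raise ValueError("inconsistent_fraction must be <= ase_fraction")
    if fold_change < 2.5:
        raise ValueError("planted fold_change must be >= 2.5")
    rng = np.random.default_rng(rng_seed)
    samples = [f"sample{j + 1}" for j in range(n_samples)]
    pair_ids = [f"pair{i + 1:05d}" for i in range(n_pairs)]

    n_ase = _round_count(ase_fraction, n_pairs)
    n_inc = min(_round_count(inconsistent_fraction, n_pairs), n_ase)
    ase_idx = rng.choice(n_pairs, size=n_ase, replace=False)
    inc_idx = set(rng.choice(ase_idx, size=n_inc, replace=False).tolist()) if n_inc else set()
    ase_set = set(ase_idx.tolist())

    size = 1.0 / NB_DISPERSION
    hi = mean_depth * np.sqrt(fold_change)
    lo = mean_depth / np.sqrt(fold_change)

    rows = []
    truth_rows = []
    gene_lengths = pd.Series(rng.integers(500, 5001, size=n_pairs), index=pair_ids,
                             name="length_bp")
    for i, pid in enumerate(pair_ids):
        direction = np.zeros(n_samples, dtype=int)
        if i in ase_set:
            base = 1 if rng.random() < 0.5 else -1
            direction[:] = base
            if i in inc_idx:
                n_flip = int(rng.integers(1, n_samples))  # proper non-empty subset
                flip = rng.choice(n_samples, size=n_flip, replace=False)
                direction[flip] = -base
        for j, s in enumerate(samples):
            if direction[j] > 0:
                mu_a, mu_b = hi, lo
            elif direction[j] < 0:
                mu_a, mu_b = lo, hi
            else:
                mu_a = mu_b = float(mean_depth)
            ca = int(rng.negative_binomial(size, size / (size + mu_a)))
            cb = int(rng.negative_binomial(size, size / (size + mu_b)))
            rows.append((pid, "A", s, ca))
            rows.append((pid, "B", s, cb))
        if i not in ase_set:
            pattern = "not_ase"
        elif i in inc_idx:
            pattern = "inconsistent"
        else:
            pattern = "consistent"
        truth_rows.append({"pair_id": pid, "is_ase": i in ase_set, "pattern": pattern,
                           **{f"direction_{s}": int(d) for s, d in zip(samples, direction)}})

    counts = pd.DataFrame(rows, columns=["pair_id", "allele", "sample", "count"])
    ase_truth = pd.DataFrame(truth_rows)
    return counts, gene_lengths, ase_truth
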