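"""Allele-specific expression classification and NG86 Ka/Ks.

ASE calling follows the haplotype-genome convention: per sample, the two
alleles of a pair are compared by log2 fold change of FPKM (pseudocount 1
on raw counts) and a two-sided binomial test of the allele-A count against
the library-size-expected proportion; a sample is ASE-significant when
|log2FC| > 1 and p < 0.05. Across samples a pair is labelled

* ``consistent``   -- >= 1 significant sample, all biased the same way,
* ``inconsistent`` -- significant samples disagree on direction
  (overdominance-style switching between tissues),
* ``not_ase``      -- no significant sample.

No multiple-testing correction is applied by default (the classification
threshold is a raw p-value); Benjamini-Hochberg across the whole table is
available behind a flag.

Ka/Ks is the Nei-Gojobori (1986) estimator: per-codon synonymous site
fractions averaged over the two sequences, observed differences averaged
over all shortest mutational pathways (pathways through stop codons are
excluded when any stop-free pathway exists), and a Jukes-Cantor correction
applied separately to the synonymous and nonsynonymous proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import binomtest

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        aa = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
              "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
        i = 0
        for b1 in _BASES:
            for b2 in _BASES:
                for b3 in _BASES:
                    _CODON_TABLE[b1 + b2 + b3] = aa[i]
                    i += 1
    return _CODON_TABLE


def fpkm(counts: float, gene_length: int, library_size: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if gene_length <= 0 or library_size <= 0:
        raise ValueError("gene_length and library_size must be positive")
    return counts * 1e9 / (gene_length * library_size)


@dataclass(frozen=True)
class SampleASE:
    sample: str
    fpkm_a: float
    fpkm_b: float
    log2fc: float
    p_value: float
    significant: bool
    direction: int  # +1 allele A up, -1 allele B up, 0 none
    excluded: bool = False  # all-zero counts in this sample


@dataclass
class ASERecord:
    """Cross-sample ASE classification for one allele pair."""

    pair_id: str
    samples: list[SampleASE] = field(default_factory=list)
    pattern: str = "not_ase"  # not_ase | consistent | inconsistent

    @property
    def is_ase(self) -> bool:
        return self.pattern != "not_ase"


def classify_pattern(directions) -> str:
    """Pattern label from the bias directions of significant samples."""
    dirs = {d for d in directions if d != 0}
    if not dirs:
        return "not_ase"
    return "consistent" if len(dirs) == 1 else "inconsistent"


def call_ase(pair_id: str, counts_a, counts_b, gene_length: int,
             library_sizes_a, library_sizes_b, sample_names=None,
             lfc_threshold: float = 1.0, alpha: float = 0.05) -> ASERecord:
    """Classify one allele pair across samples.

    ``counts_a``/``counts_b`` are per-sample raw counts for alleles A and
    B; ``library_sizes_a``/``library_sizes_b`` the per-sample total mapped
    counts of the two haplotype alignments. Samples with all-zero counts
    are excluded from pattern assignment but reported.
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    lib_a = np.asarray(library_sizes_a, dtype=float)
    lib_b = np.asarray(library_sizes_b, dtype=float)
    if not (len(counts_a) == len(counts_b) == len(lib_a) == len(lib_b)):
        raise ValueError("alleles must share the same samples")
    if sample_names is None:
        sample_names = [f"sample{j + 1}" for j in range(len(counts_a))]
    rec = ASERecord(pair_id=pair_id)
    for j, name in enumerate(sample_names):
        ca, cb = int(counts_a[j]), int(counts_b[j])
        fa = fpkm(ca + 1, gene_length, int(lib_a[j]))
        fb = fpkm(cb + 1, gene_length, int(lib_b[j]))
        log2fc = math.log2(fa / fb)
        if ca + cb == 0:
            rec.samples.append(SampleASE(name, fa, fb, log2fc, float("nan"),
                                         False, 0, excluded=True))
            continue
        expected = lib_a[j] / (lib_a[j] + lib_b[j])
        p = binomtest(ca, ca + cb, expected, alternative="two-sided").pvalue
        sig = abs(log2fc) > lfc_threshold and p < alpha
        direction = (1 if log2fc > 0 else -1) if sig else 0
        rec.samples.append(SampleASE(name, fa, fb, log2fc, p, sig, direction))
    rec.pattern = classify_pattern(s.direction for s in rec.samples if not s.excluded)
    return rec


def call_ase_table(counts: pd.DataFrame, gene_lengths: pd.Series,
                   lfc_threshold: float = 1.0, alpha: float = 0.05,
                   fdr: bool = False) -> list[ASERecord]:
    """Run :func:`call_ase` over a long-format count table.

    ``counts`` has columns pair_id, allele (A/B), sample, count; library
    sizes are the per-sample per-allele column totals. With ``fdr=True``
    the per-sample p-values are Benjamini-Hochberg adjusted across the
    whole table before thresholding (off by default: the classification
    rule is a raw p-value).
    """
    wide = counts.pivot_table(index="pair_id", columns=["allele", "sample"],
                              values="count", aggfunc="sum", fill_value=0)
    samples = sorted({s for _, s in wide.columns})
    lib = {(al, s): int(wide[(al, s)].sum()) for al in ("A", "B") for s in samples}
    records = []
    for pid in wide.index:
        rec = call_ase(
            pid,
            [wide.loc[pid, ("A", s)] for s in samples],
            [wide.loc[pid, ("B", s)] for s in samples],
            int(gene_lengths[pid]),
            [lib[("A", s)] for s in samples],
            [lib[("B", s)] for s in samples],
            sample_names=samples, lfc_threshold=lfc_threshold, alpha=alpha)
        records.append(rec)
    if fdr:
        flat = [(i, j, s.p_value) for i, r in enumerate(records)
                for j, s in enumerate(r.samples) if not s.excluded]
        pvals = np.array([p for _, _, p in flat])
        order = np.argsort(pvals)
        n = len(pvals)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            running = min(running, pvals[i] * n / (rank + 1))
            adj[i] = running
        for (i, j, _), q in zip(flat, adj):
            s = records[i].samples[j]
            sig = abs(s.log2fc) > lfc_threshold and q < alpha
            direction = (1 if s.log2fc > 0 else -1) if sig else 0
            records[i].samples[j] = SampleASE(s.sample, s.fpkm_a, s.fpkm_b,
                                              s.log2fc, q, sig, direction)
        for r in records:
            r.pattern = classify_pattern(s.direction for s in r.samples
                                         if not s.excluded)
    return records


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    ka: float
    ks: float
    ratio: float  # nan when ks == 0 or saturated
    saturated: bool = False


def _codon_site_counts(codon: str) -> float:
    """Synonymous site count of one codon (out of 3).

    Each of the nine single-base mutations contributes 1/3 site to the
    synonymous total if it preserves the amino acid; changes to stop
    codons count as nonsynonymous.
    """
    table = _codon_table()
    aa = table[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if table[alt] == aa:
                syn += 1
    return syn / 3.0


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over pathways.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are dropped unless every pathway does.
    """
    table = _codon_table()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if table[nxt] == "*" and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked] \
        or [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for u, v in steps:
            if table[u] == table[v]:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def _strip_gaps(a: str, b: str) -> tuple[str, str]:
    kept = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    return "".join(x for x, _ in kept), "".join(y for _, y in kept)


def _jc_correct(p: float) -> tuple[float, bool]:
    if p == 0:
        return 0.0, False
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * math.log(1 - 4 * p / 3), False


def kaks_ng86(cds_a: str, cds_b: str, pair_id: str = "") -> KaKsResult:
    """Nei-Gojobori (1986) Ka and Ks for one aligned allele CDS pair.

    Sequences may contain '-' gap columns (stripped pairwise); the gapless
    sequences must be equal length, a multiple of 3, and stop-free except
    for a trailing stop (which is trimmed).
    """
    a, b = _strip_gaps(cds_a.upper(), cds_b.upper())
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    if len(a) % 3:
        raise ValueError("coding length must be a multiple of 3")
    table = _codon_table()
    codons = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
    if codons and (table[codons[-1][0]] == "*" or table[codons[-1][1]] == "*"):
        codons = codons[:-1]
    for ca, cb in codons:
        if table[ca] == "*" or table[cb] == "*":
            raise ValueError("internal stop codon in coding sequence")
    if not codons:
        raise ValueError("no codons after gap/stop trimming")

    s_sites = sum(_codon_site_counts(ca) + _codon_site_counts(cb)
                  for ca, cb in codons) / 2.0
    n_sites = 3 * len(codons) - s_sites
    sd = nd = 0.0
    for ca, cb in codons:
        ds, dn = _pathway_diffs(ca, cb)
        sd += ds
        nd += dn
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    saturated = sat_s or sat_n
    if saturated or ks == 0 or math.isnan(ks) or math.isnan(ka):
        ratio = float("nan")
    else:
        ratio = ka / ks
    return KaKsResult(pair_id=pair_id, ka=ka, ks=ks, ratio=ratio, saturated=saturated)


def cds_identity(cds_a: str, cds_b: str) -> float:
    """Ungapped-column identity of one aligned coding-sequence pair."""
    a, b = _strip_gaps(cds_a.upper(), cds_b.upper())
    if not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)
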