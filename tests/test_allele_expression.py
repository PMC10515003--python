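"""ASE calling and NG86 Ka/Ks against independent oracles."""

import math
from itertools import permutations

import numpy as np
import pytest
from scipy.stats import binom

from centrosat.allele_expression import (call_ase, call_ase_table, cds_identity,
                                         classify_pattern, fpkm, kaks_ng86)
from centrosat.synthetic_data import simulate_allele_counts

# --- independent NG86 oracle -------------------------------------------------
# built from Biopython's codon table rather than the implementation's own
from Bio.Data.CodonTable import standard_dna_table

_ORACLE_AA = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    _ORACLE_AA[stop] = "*"
_NT = "ACGT"


def oracle_sites(codon):
    syn = sum(1 for pos in range(3) for b in _NT
              if b != codon[pos]
              and _ORACLE_AA[codon[:pos] + b + codon[pos + 1:]] == _ORACLE_AA[codon])
    return syn / 3.0


def oracle_diffs(c1, c2):
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(pos):
        cur, steps, blocked = c1, [], False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if _ORACLE_AA[nxt] == "*" and nxt != c2:
                blocked = True
            steps.append(_ORACLE_AA[cur] == _ORACLE_AA[nxt])
            cur = nxt
        paths.append((blocked, steps))
    usable = [s for bl, s in paths if not bl] or [s for _, s in paths]
    sd = sum(sum(s) for s in usable) / len(usable)
    nd = sum(len(s) - sum(s) for s in usable) / len(usable)
    return sd, nd


def oracle_kaks(a, b):
    codons = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
    S = sum(oracle_sites(x) + oracle_sites(y) for x, y in codons) / 2
    N = 3 * len(codons) - S
    sd = sum(oracle_diffs(x, y)[0] for x, y in codons)
    nd = sum(oracle_diffs(x, y)[1] for x, y in codons)
    ps, pn = sd / S, nd / N

    def jc(p):
        return float("nan") if p >= 0.75 else (
            0.0 if p == 0 else -0.75 * math.log(1 - 4 * p / 3))
    return jc(pn), jc(ps)


def random_codons(rng, n):
    sense = [c for c in _ORACLE_AA if _ORACLE_AA[c] != "*"]
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n))


# --- FPKM --------------------------------------------------------------------

@pytest.mark.parametrize("counts,length,lib,expected", [
    (10, 1_000, 1_000_000, 10.0),
    (0, 1_000, 1_000_000, 0.0),
    (1, 2_000, 10_000_000, 0.05),
])
def test_fpkm_closed_form(counts, length, lib, expected):
    assert fpkm(counts, length, lib) == pytest.approx(expected)
    assert fpkm(2 * counts, length, lib) == pytest.approx(2 * expected)


def test_fpkm_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        fpkm(1, 0, 100)


# --- per-pair ASE calls ------------------------------------------------------

def exact_binom_p(k, n, p0):
    """Two-sided exact binomial p by pmf summation (independent oracle)."""
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-9)].sum())


class TestCallASE:
    LIB = [10_000_000]

    def test_strong_imbalance_flagged(self):
        rec = call_ase("p", [200], [40], 1_000, self.LIB, self.LIB)
        s = rec.samples[0]
        assert s.log2fc == pytest.approx(math.log2(201 / 41), abs=1e-12)
        assert s.p_value == pytest.approx(exact_binom_p(200, 240, 0.5), rel=1e-9)
        assert s.significant and rec.pattern == "consistent"

    def test_balanced_counts_not_flagged(self):
        rec = call_ase("p", [100], [100], 1_000, self.LIB, self.LIB)
        assert rec.samples[0].log2fc == 0.0
        assert not rec.samples[0].significant
        assert rec.pattern == "not_ase"

    def test_direction_conflict_is_inconsistent(self):
        a = [200, 210, 190, 40]
        b = [40, 45, 38, 200]
        rec = call_ase("p", a, b, 1_000, self.LIB * 4, self.LIB * 4)
        assert [s.direction for s in rec.samples] == [1, 1, 1, -1]
        assert rec.pattern == "inconsistent"

    def test_library_size_imbalance_shifts_null(self):
        # counts 2:1 exactly matching a 2:1 library ratio: not significant
        rec = call_ase("p", [200], [100], 1_000, [20_000_000], [10_000_000])
        assert rec.samples[0].p_value > 0.5
        assert abs(rec.samples[0].log2fc) < 0.1

    def test_swap_symmetry(self):
        a, b = [200, 30, 120], [50, 150, 118]
        lib = self.LIB * 3
        r1 = call_ase("p", a, b, 1_000, lib, lib)
        r2 = call_ase("p", b, a, 1_000, lib, lib)
        for s1, s2 in zip(r1.samples, r2.samples):
            assert s1.log2fc == pytest.approx(-s2.log2fc, abs=1e-12)
            assert s1.p_value == pytest.approx(s2.p_value, rel=1e-12)
        assert r1.pattern == r2.pattern

    def test_all_zero_sample_excluded(self):
        rec = call_ase("p", [0, 200], [0, 40], 1_000, self.LIB * 2, self.LIB * 2)
        assert rec.samples[0].excluded
        assert rec.pattern == "consistent"

    def test_classify_pattern_rules(self):
        assert classify_pattern([0, 0]) == "not_ase"
        assert classify_pattern([1, 0, 1]) == "consistent"
        assert classify_pattern([-1, -1]) == "consistent"
        assert classify_pattern([1, -1, 1]) == "inconsistent"


class TestCallASETable:
    def test_recovers_planted_truth(self):
        counts, lengths, truth = simulate_allele_counts(
            300, 6, ase_fraction=0.1, inconsistent_fraction=0.02,
            mean_depth=200, rng_seed=21)
        records = {r.pair_id: r for r in call_ase_table(counts, lengths)}
        tr = truth.set_index("pair_id")
        planted = tr[tr.is_ase]
        sens = np.mean([records[p].is_ase for p in planted.index])
        assert sens >= 0.95
        match = np.mean([records[p].pattern == planted.loc[p, "pattern"]
                         for p in planted.index if records[p].is_ase])
        assert match >= 0.9

    def test_fdr_flag_is_more_conservative(self):
        counts, lengths, _ = simulate_allele_counts(200, 4, ase_fraction=0.05,
                                                    rng_seed=5)
        raw = call_ase_table(counts, lengths)
        adj = call_ase_table(counts, lengths, fdr=True)
        n_raw = sum(s.significant for r in raw for s in r.samples)
        n_adj = sum(s.significant for r in adj for s in r.samples)
        assert n_adj <= n_raw


# --- Ka/Ks -------------------------------------------------------------------

class TestKaKs:
    def test_identical_sequences(self):
        r = kaks_ng86("ATGAAACCC", "ATGAAACCC")
        assert r.ka == 0.0 and r.ks == 0.0
        assert math.isnan(r.ratio)  # ks == 0: ratio undefined

    def test_single_synonymous_change(self):
        # Phe TTT -> TTC: the one difference is synonymous
        r = kaks_ng86("TTT", "TTC")
        assert r.ka == 0.0
        # a lone codon has 1/3 synonymous site, so p_s saturates JC
        assert r.saturated or r.ks > 0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            a = random_codons(rng, 30)
            b_list = list(a)
            for pos in rng.choice(len(a), size=8, replace=False):
                b_list[pos] = "ACGT"[rng.integers(0, 4)]
            b = "".join(b_list)
            codons = [b[i:i + 3] for i in range(0, len(b), 3)]
            if any(_ORACLE_AA[c] == "*" for c in codons):
                continue
            got = kaks_ng86(a, b)
            exp_ka, exp_ks = oracle_kaks(a, b)
            if math.isnan(exp_ks):
                assert got.saturated or math.isnan(got.ks)
            else:
                assert got.ka == pytest.approx(exp_ka, abs=1e-9)
                assert got.ks == pytest.approx(exp_ks, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        while True:
            a = random_codons(rng, 20)
            b_list = list(a)
            for pos in rng.choice(len(a), size=4, replace=False):
                b_list[pos] = "ACGT"[rng.integers(0, 4)]
            b = "".join(b_list)
            if all(_ORACLE_AA[b[i:i + 3]] != "*" for i in range(0, len(b), 3)):
                break
        r1, r2 = kaks_ng86(a, b), kaks_ng86(b, a)
        assert r1.ka == r2.ka
        assert r1.ks == r2.ks or (math.isnan(r1.ks) and math.isnan(r2.ks))
        assert r1.saturated == r2.saturated

    def test_gap_stripping_and_validation(self):
        r = kaks_ng86("ATG---AAACCC", "ATGTTTAAACCC"[0:3] + "---" + "AAACCC")
        assert r.ka == r.ks == 0.0
        with pytest.raises(ValueError):
            kaks_ng86("ATGA", "ATGC")
        with pytest.raises(ValueError):
            kaks_ng86("ATGTAAAAA", "ATGTAAAAA")  # internal stop

    def test_purifying_selection_dominates_synonymous_mutants(self):
        rng = np.random.default_rng(23)
        below_one = 0
        total = 0
        for _ in range(60):
            a = random_codons(rng, 100)
            b_codons = []
            for i in range(0, len(a), 3):
                codon = a[i:i + 3]
                if rng.random() < 0.3:  # mostly synonymous wobble changes
                    aa = _ORACLE_AA[codon]
                    syns = [c for c in _ORACLE_AA
                            if _ORACLE_AA[c] == aa and c != codon]
                    if syns:
                        codon = syns[rng.integers(0, len(syns))]
                b_codons.append(codon)
            b = "".join(b_codons)
            r = kaks_ng86(a, b)
            if not (r.saturated or math.isnan(r.ratio)):
                total += 1
                below_one += r.ratio < 1
        assert total >= 50
        assert below_one / total > 0.95


def test_cds_identity():
    assert cds_identity("ATGATG", "ATGATG") == 1.0
    assert cds_identity("ATG-TG", "ATGCTG") == pytest.approx(1.0)
    assert cds_identity("AAAA", "AAAT") == 0.75
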