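"""Centromere localization: hit tracks, run merging, evidence, heatmap."""

import numpy as np
import pytest

from centrosat._seq import random_dna
from centrosat.centromere_call import (CentromereCall, DensityTrack,
                                       call_centromere, evidence_check,
                                       interval_track, locate_centromeres,
                                       monomer_hit_track, similarity_heatmap)
from centrosat.monomer_cluster import greedy_cluster
from centrosat.synthetic_data import GenomeSpec, simulate_genome


def track_from_values(values, window=10_000, seq_length=None):
    values = np.asarray(values)
    return DensityTrack(seq_id="t", window=window, step=window,
                        seq_length=seq_length or window * len(values),
                        values=values, label="monomer")


class TestHitTrack:
    def test_counts_equal_planted_copies(self, small_exact_genome):
        _, seqs, truth = small_exact_genome
        chrom = seqs["chr01"]
        clusters = greedy_cluster([truth.monomer_truth])
        track = monomer_hit_track(chrom, clusters, seq_id="chr01")
        starts = np.array(truth.centromere_copy_starts["chr01"])
        # partition additivity: window sums reproduce total planted copies
        assert track.values.sum() == len(starts) == 100
        for i in range(track.n_windows):
            lo, hi = i * track.step, i * track.step + track.window
            assert track.values[i] == ((starts >= lo) & (starts < hi)).sum()

    def test_monomer_free_sequence_has_empty_track(self):
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            seq = random_dna(rng, 200_000)
            clusters = greedy_cluster([random_dna(rng, 153)])
            track = monomer_hit_track(seq, clusters, identity=0.8)
            assert track.values.sum() == 0

    def test_window_count_formula(self, small_exact_genome):
        _, seqs, truth = small_exact_genome
        clusters = greedy_cluster([truth.monomer_truth])
        track = monomer_hit_track(seqs["chr01"], clusters, window=10_000, step=5_000)
        n = len(seqs["chr01"])
        assert track.n_windows == int(np.ceil((n - 10_000) / 5_000)) + 1


class TestCallCentromere:
    def test_longest_run_wins(self):
        values = [0] * 30
        values[2:22] = [30] * 20   # 200 kb run
        values[27:29] = [30] * 2   # 20 kb run
        call = call_centromere(track_from_values(values))
        assert call.start == 2 * 10_000 and call.end == 22 * 10_000

    def test_gap_merging(self):
        values = [0] * 20
        values[4:8] = [20] * 4
        values[10:14] = [20] * 4   # gap of 2 empty windows: merged
        call = call_centromere(track_from_values(values), max_gap=2)
        assert call.start == 4 * 10_000 and call.end == 14 * 10_000
        call2 = call_centromere(track_from_values(values), max_gap=1)
        assert call2.end - call2.start == 4 * 10_000

    def test_all_zero_returns_none(self):
        assert call_centromere(track_from_values([0] * 10)) is None

    def test_boundaries_snap_to_hits(self, small_exact_genome):
        _, seqs, truth = small_exact_genome
        clusters = greedy_cluster([truth.monomer_truth])
        track = monomer_hit_track(seqs["chr01"], clusters, seq_id="chr01")
        call = call_centromere(track)
        ts, te = truth.centromere_truth["chr01"]
        assert abs(call.start - ts) <= 153
        assert abs(call.end - te) <= 153
        assert call.hit_fraction == 1.0


class TestEvidence:
    @staticmethod
    def _call():
        return CentromereCall("t", 40_000, 60_000, "c0", 1.0)

    def test_genes_excluded_pass(self):
        genes = [(i * 3_000, i * 3_000 + 1_000) for i in range(13)]  # < 40 kb
        gt = interval_track(genes, 100_000, label="gene")
        tt = interval_track([(45_000, 47_000)], 100_000, mode="bp", label="te_I")
        call = evidence_check(self._call(), gt, tt)
        assert call.status == "pass" and all(call.flags.values())
        assert call.mean_gene_density_inside < call.mean_gene_density_outside

    def test_uniform_genes_warn(self):
        genes = [(i * 5_000, i * 5_000 + 2_000) for i in range(20)]
        gt = interval_track(genes, 100_000, label="gene")
        tt = interval_track([(45_000, 47_000)], 100_000, mode="bp", label="te_I")
        call = evidence_check(self._call(), gt, tt)
        assert call.status == "warn"
        assert not call.flags["gene_density"]

    def test_warn_never_deletes_call(self):
        gt = interval_track([], 100_000, label="gene")
        tt = interval_track([], 100_000, mode="bp", label="te_I")
        call = evidence_check(self._call(), gt, tt)
        assert isinstance(call, CentromereCall)


class TestHeatmap:
    def test_symmetry_and_diagonal(self, rng):
        seq = random_dna(rng, 300_000)
        m = similarity_heatmap(seq, window=50_000)
        assert np.array_equal(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_identical_windows_score_one(self, rng):
        block = random_dna(rng, 50_000)
        m = similarity_heatmap(block + block, window=50_000)
        assert m[0, 1] == 1.0

    def test_random_windows_dissimilar(self):
        for seed in range(10):
            seq = random_dna(np.random.default_rng(3000 + seed), 100_000)
            m = similarity_heatmap(seq, window=50_000)
            assert m[0, 1] < 0.05

    def test_centromeric_block_lights_up(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=400_000,
                          centromere_array_length=100_000, rng_seed=2)
        seqs, _, truth = simulate_genome(spec)
        m = similarity_heatmap(seqs["chr01"], window=50_000)
        ts, te = truth.centromere_truth["chr01"]
        cen = range(ts // 50_000 + 1, te // 50_000)  # fully centromeric windows
        arm = [i for i in range(m.shape[0]) if i < ts // 50_000 or i > te // 50_000]
        cen_pairs = [m[i, j] for i in cen for j in cen if i < j]
        cross = [m[i, j] for i in cen for j in arm]
        assert cen_pairs and min(cen_pairs) > max(cross)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            similarity_heatmap("ACGT" * 100, window=50_000)


def test_locate_centromeres_end_to_end(default_genome):
    _, seqs, truth = default_genome
    res = locate_centromeres(seqs, gene_truth=truth.gene_truth,
                             te_truth=truth.te_truth)
    assert res["major_monomer"][1] == 153
    for sid, call in res["calls"].items():
        ts, te = truth.centromere_truth[sid]
        inter = max(0, min(call.end, te) - max(call.start, ts))
        union = max(call.end, te) - min(call.start, ts)
        assert inter / union >= 0.9
        assert call.hit_fraction >= 0.95
        assert call.status == "pass"
        lo, hi = call.report_interval()
        assert (lo, hi) == (call.start + 1, call.end)
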