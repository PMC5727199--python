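"""Denoising, shadow removal, spike-in normalization and size cutoffs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tubahdr.calling import (
    DenoiseConfig, TumorCall, abundance_pvalue, apply_cutoff,
    clusters_to_calls, denoise, normalize_to_spikein, remove_shadows,
    replicate_concordance,
)
from tubahdr.design import InvalidInputError, spikein_allele
from tubahdr.reads import SamplePileup, process_reads
from tubahdr.simulate import (
    ErrorModel, MouseTruth, TrueTumor, simulate_cohort, simulate_sample_reads,
)

RATE = 1e-4


def _pileup(counts):
    return SamplePileup("s", counts)


def _mutate(seq, pos, to=None):
    alt = to or ("A" if seq[pos] != "A" else "C")
    return seq[:pos] + alt + seq[pos + 1:]


class TestAbundancePvalue:
    def test_matches_poisson_tail_oracle(self):
        lam, n = 0.33, 1000
        oracle = sps.poisson.sf(n - 1, lam) / (1 - math.exp(-lam))
        assert abundance_pvalue(n, lam) == pytest.approx(oracle)
        assert abundance_pvalue(n, lam) < 1e-10

    def test_consistent_count_is_not_significant(self):
        # a neighbor at its expected error abundance is unsurprising
        assert abundance_pvalue(3, 3.3) > 0.5

    def test_zero_lambda(self):
        assert abundance_pvalue(5, 0.0) == 0.0


class TestDenoise:
    def test_error_neighbors_absorbed_into_one_cluster(self):
        center = "A" * 42
        lam = int(RATE * 1e5 / 3)           # ~3 reads per 1-mismatch neighbor
        counts = {center: 100_000}
        for pos in range(10):
            counts[_mutate(center, pos)] = lam
        clusters = denoise(_pileup(counts), DenoiseConfig(error_rate=RATE))
        assert clusters == {center: sum(counts.values())}

    def test_distant_sequences_split(self):
        a = "A" * 42
        b = "C" * 3 + "A" * 39              # 3 mismatches away
        clusters = denoise(_pileup({a: 10_000, b: 10_000}),
                           DenoiseConfig(error_rate=RATE))
        assert clusters == {a: 10_000, b: 10_000}

    def test_overabundant_neighbor_founds_cluster(self):
        # lambda ~ 0.33 but 1000 reads observed: p-value << omega_a
        a = "A" * 42
        b = _mutate(a, 0)
        clusters = denoise(_pileup({a: 10_000, b: 1000}),
                           DenoiseConfig(error_rate=RATE))
        assert set(clusters) == {a, b}
        assert clusters[b] >= 1000

    def test_zero_error_rate_splits_everything(self):
        a, b = "A" * 42, _mutate("A" * 42, 5)
        clusters = denoise(_pileup({a: 50, b: 1}),
                           DenoiseConfig(error_rate=0.0))
        assert set(clusters) == {a, b}

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 41), st.integers(1, 500)),
                    min_size=0, max_size=8))
    def test_reads_conserved(self, perturbations):
        center = "G" * 42
        counts = {center: 20_000}
        for pos, n in perturbations:
            seq = _mutate(center, pos)
            counts[seq] = counts.get(seq, 0) + n
        clusters = denoise(_pileup(counts), DenoiseConfig(error_rate=RATE))
        assert sum(clusters.values()) == sum(counts.values())


class TestRemoveShadows:
    def test_tiny_neighbor_of_huge_cluster_removed(self):
        a = "A" * 42
        kept, frac = remove_shadows({a: 10 ** 6, _mutate(a, 3): 10})
        assert list(kept) == [a]
        assert frac == pytest.approx(0.5)

    def test_ratio_below_threshold_kept(self):
        a = "A" * 42
        clusters = {a: 10 ** 4, _mutate(a, 3): 10}
        kept, _ = remove_shadows(clusters)
        assert kept == clusters             # ratio 10^3 < 10^4

    def test_distance_two_kept(self):
        a = "A" * 42
        b = _mutate(_mutate(a, 3), 7)
        clusters = {a: 10 ** 9, b: 10}
        kept, _ = remove_shadows(clusters)
        assert kept == clusters

    def test_dominant_lesion_leaves_no_large_spurious_calls(self, design):
        """With 1e-4 errors and a dominant 1e6-read lesion, nothing >= 1e-3
        of its size survives denoising plus shadow removal."""
        mouse = MouseTruth("m", "PT", [TrueTumor("G12D", "ACGTACGA", 1e6)])
        reads, _ = simulate_sample_reads(mouse, design, ErrorModel(RATE),
                                         reads_per_cell=1.0, seed=41,
                                         include_spikein=False)
        pileup = process_reads(reads, design)
        clusters = denoise(pileup, DenoiseConfig(error_rate=RATE))
        clusters, _ = remove_shadows(clusters)
        top = max(clusters.values())
        spurious = [n for n in clusters.values() if n != top]
        assert all(n < 1e-3 * top for n in spurious)


class TestSpikein:
    def _calls(self, design, tumor_reads, spike_reads):
        spike = spikein_allele(design)
        return [
            TumorCall("s", "G12D", "ACGTACGA", tumor_reads),
            TumorCall("s", spike.variant_label, spike.barcode, spike_reads),
        ]

    def test_equal_reads_give_spikein_cells(self, design):
        calls = normalize_to_spikein(self._calls(design, 100, 100), design)
        tumor = next(c for c in calls if not c.is_spikein)
        assert tumor.cells == pytest.approx(5e5)

    def test_double_reads_give_double_cells(self, design):
        calls = normalize_to_spikein(self._calls(design, 200, 100), design)
        tumor = next(c for c in calls if not c.is_spikein)
        assert tumor.cells == pytest.approx(1e6)

    def test_missing_spikein_errors(self, design):
        with pytest.raises(InvalidInputError):
            normalize_to_spikein(
                [TumorCall("s", "G12D", "ACGTACGA", 10)], design)

    def test_size_recovery_error_free(self, design, pool):
        """Error-free sample at ~100 reads per 1e4 cells: relative RMSE of
        recovered cell numbers below 5%."""
        truth = simulate_cohort(pool, n_mice=1, mean_tumors_per_mouse=30,
                                seed=42).mice[0]
        reads, _ = simulate_sample_reads(truth, design, ErrorModel(0.0),
                                         reads_per_cell=0.01, seed=43)
        pileup = process_reads(reads, design)
        clusters = denoise(pileup, DenoiseConfig(error_rate=0.0))
        calls, _ = clusters_to_calls(clusters, design, "m")
        calls = normalize_to_spikein(calls, design)
        true_cells = {}
        for t in truth.tumors:
            true_cells[(t.variant, t.barcode)] = \
                true_cells.get((t.variant, t.barcode), 0) + t.cells
        rel = []
        for c in calls:
            if c.is_spikein:
                continue
            rel.append((c.cells - true_cells[c.key]) / true_cells[c.key])
        assert rel and np.sqrt(np.mean(np.square(rel))) < 0.05

    def test_error_free_calls_equal_truth_exactly(self, design, pool):
        truth = simulate_cohort(pool, n_mice=1, mean_tumors_per_mouse=25,
                                seed=44).mice[0]
        reads, _ = simulate_sample_reads(truth, design, ErrorModel(0.0),
                                         reads_per_cell=0.02, seed=45)
        clusters = denoise(process_reads(reads, design),
                           DenoiseConfig(error_rate=0.0))
        calls, dropped = clusters_to_calls(clusters, design, "m")
        assert not dropped
        calls = normalize_to_spikein(calls, design)
        called = {c.key for c in calls if not c.is_spikein}
        assert called == {(t.variant, t.barcode) for t in truth.tumors}


class TestCutoff:
    def _call(self, cells=None, reads=1, variant="G12D"):
        return TumorCall("s", variant, "ACGTACGA", reads, cells=cells)

    def test_lung_cutoff_is_strict(self):
        kept, dropped = apply_cutoff(
            [self._call(100_001.0), self._call(100_000.0)], mode="lung")
        assert [c.cells for c in kept] == [100_001.0]
        assert [c.cells for c in dropped] == [100_000.0]

    def test_pancreas_twice_max_wt(self):
        calls = [self._call(reads=500, variant="WT"),
                 self._call(reads=1001), self._call(reads=999)]
        kept, dropped = apply_cutoff(calls, mode="pancreas")
        assert [c.reads for c in kept] == [1001]
        assert {c.reads for c in dropped} == {500, 999}

    def test_pancreas_without_wt_keeps_all(self):
        calls = [self._call(reads=3), self._call(reads=7)]
        kept, dropped = apply_cutoff(calls, mode="pancreas")
        assert len(kept) == 2 and not dropped

    def test_empty_input(self):
        assert apply_cutoff([], mode="lung") == ([], [])


class TestReplicateConcordance:
    def _calls(self, sizes, sample="a"):
        return [TumorCall(sample, "G12D", f"{'ACGTACGA'[:7]}{'AT'[i % 2]}", 1,
                          cells=s)
                for i, s in enumerate(sizes[:2])] + [
            TumorCall(sample, "G12V", f"AAAAAAG{'AT'[i % 2]}", 1, cells=s)
            for i, s in enumerate(sizes[2:])]

    def test_identical_sets_r2_one(self):
        calls = self._calls([1e5, 2e5, 5e5, 1e6])
        assert replicate_concordance(calls, calls) == pytest.approx(1.0)

    def test_technical_replicates_above_099(self, design, pool):
        truth = simulate_cohort(pool, n_mice=1, mean_tumors_per_mouse=40,
                                seed=46).mice[0]

        def one_rep(seed):
            reads, _ = simulate_sample_reads(truth, design, ErrorModel(RATE),
                                             reads_per_cell=4e-3, seed=seed)
            clusters, _ = remove_shadows(denoise(
                process_reads(reads, design), DenoiseConfig(error_rate=RATE)))
            calls, _ = clusters_to_calls(clusters, design, "m")
            calls = normalize_to_spikein(calls, design)
            kept, _ = apply_cutoff(calls, mode="lung")
            return kept

        r2 = replicate_concordance(one_rep(47), one_rep(48))
        assert r2 > 0.99

    def test_unrelated_sizes_near_zero(self, rng):
        a = self._calls(list(rng.lognormal(12, 1, 4)))
        b = self._calls(list(rng.lognormal(12, 1, 4)))
        assert replicate_concordance(a, b) < 0.9

    def test_fewer_than_three_shared_errors(self):
        calls = self._calls([1e5, 2e5])
        with pytest.raises(InvalidInputError):
            replicate_concordance(calls[:1], calls[:1])
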