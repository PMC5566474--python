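"""Coverage uniformity, GC bias, Lorenz/Gini, error rates, end bias."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stst
from scipy import stats

from cfseq.core import CoverageTrack, Fragment, GenomeSequence, coverage_from_fragments
from cfseq.qc import (
    CoverageHistogram,
    end_composition,
    error_rates,
    gc_bias,
    gini_pairwise,
    indel_by_run_length,
    lorenz_gini,
    one_way_chi2,
    poisson_fit,
    subsample_fragments,
    umi_resampling_test,
)
from cfseq.simulate import SimConfig, apply_end_bias, EndBiasProfile, simulate_reads


class TestSubsample:
    def test_subset_size_from_coverage_arithmetic(self, genome, rng):
        frags = [
            Fragment(genome.contig, int(s), int(s) + 100)
            for s in rng.integers(0, len(genome) - 100, size=5000)
        ]
        subs = subsample_fragments(frags, len(genome), target_coverage=2.0, seed=1)
        assert len(subs[0]) == round(2.0 * len(genome) / 100)

    def test_replicates_reproducible_and_distinct(self, genome, rng):
        frags = [
            Fragment(genome.contig, int(s), int(s) + 100)
            for s in rng.integers(0, len(genome) - 100, size=3000)
        ]
        a = subsample_fragments(frags, len(genome), 1.0, seed=7, replicates=3)
        b = subsample_fragments(frags, len(genome), 1.0, seed=7, replicates=3)
        assert a == b
        assert a[0] != a[1] and a[1] != a[2]

    def test_target_above_available_rejected(self, genome):
        frags = [Fragment(genome.contig, 0, 100)]
        with pytest.raises(ValueError):
            subsample_fragments(frags, len(genome), 16.0, seed=0)


class TestPoissonFit:
    def test_exact_poisson_histogram_r2_one(self):
        lam, G = 16.0, 10**7
        d = np.arange(80)
        counts = np.round(stats.poisson.pmf(d, lam) * G).astype(int)
        hist = CoverageHistogram(d, counts, float((d * counts).sum() / counts.sum()))
        assert poisson_fit(hist) > 0.999

    def test_delta_histogram_poor_fit(self):
        counts = np.zeros(20, dtype=int)
        counts[16] = 10**6
        counts[15] = 1  # avoid the degenerate single-depth signal
        hist = CoverageHistogram(np.arange(20), counts, 16.0)
        assert poisson_fit(hist) < 0.5

    def test_uniform_random_fragments_near_poisson(self, rng):
        G = 200_000
        n = int(16 * G / 150)
        frags = [
            Fragment("c", int(s), int(s) + 150)
            for s in rng.integers(0, G - 150, size=n)
        ]
        tracks, _ = coverage_from_fragments(frags, {"c": G})
        assert poisson_fit(CoverageHistogram.from_track(tracks["c"])) >= 0.95

    def test_single_depth_degenerate_signaled(self):
        hist = CoverageHistogram(np.arange(17), np.eye(17, dtype=int)[16] * 100, 16.0)
        with pytest.raises(ValueError):
            poisson_fit(hist)


class TestGcBias:
    def test_uniform_coverage_flat_at_one(self, genome):
        track = CoverageTrack(genome.contig, np.full(len(genome), 7))
        curve = gc_bias(track, genome)
        np.testing.assert_allclose(curve.normalized_coverage, 1.0)
        assert abs(curve.slope) < 1e-9

    def test_coverage_proportional_to_gc(self, genome):
        gc = np.array([b in "GC" for b in genome.sequence], dtype=float)
        curve = gc_bias(CoverageTrack(genome.contig, gc * 10), genome)
        assert curve.slope > 0
        assert curve.r_squared > 0.999  # window mean depth is exactly linear in GC

    def test_window_longer_than_genome_rejected(self):
        g = GenomeSequence("c", "ACGT" * 10)
        track = CoverageTrack("c", np.ones(40))
        with pytest.raises(ValueError):
            gc_bias(track, g, window=100)


class TestLorenzGini:
    def test_equal_depths_gini_zero(self):
        assert lorenz_gini([5, 5, 5, 5]).gini == pytest.approx(0.0, abs=1e-12)

    def test_single_loaded_window(self):
        assert lorenz_gini([0, 0, 0, 8]).gini == pytest.approx(0.75, abs=1e-12)

    def test_pairwise_oracle_1234(self):
        # sum|xi-xj| over ordered pairs = 20; 2 n^2 mu = 80
        assert lorenz_gini([1, 2, 3, 4]).gini == pytest.approx(0.25, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        res = lorenz_gini(rng.random(100))
        assert res.cum_coverage_fraction[0] == 0.0
        assert res.cum_coverage_fraction[-1] == pytest.approx(1.0)
        assert (np.diff(res.cum_coverage_fraction) >= 0).all()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lorenz_gini([0.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(stst.lists(stst.floats(0, 1e3), min_size=2, max_size=60).filter(
        lambda v: sum(v) > 0
    ))
    def test_matches_quadratic_pairwise_formula(self, values):
        assert lorenz_gini(values).gini == pytest.approx(
            gini_pairwise(values), abs=1e-9
        )


class TestErrorRates:
    def test_perfect_reads_zero_rates(self, genome):
        config = SimConfig(seed=1, substitution_rate=0.0, duplication_mean=1.0,
                           t_run_deletion={}, a_run_insertion={})
        frags = [Fragment(genome.contig, s, s + 150) for s in range(0, 30_000, 300)]
        reads, _ = simulate_reads(frags, genome, config)
        rep = error_rates(reads, genome)
        assert rep.substitution_rate == rep.insertion_rate == rep.deletion_rate == 0

    def test_rate_definition_one_error_per_kb(self, genome):
        from cfseq.simulate import SimulatedRead

        seq = list(genome.sequence[0:1000])
        seq[500] = "A" if seq[500] != "A" else "C"
        read = SimulatedRead(
            "r", genome.contig, 0, "".join(seq), np.full(1000, 30),
            [("M", 1000)], 0, 1, "A" * 13, (0, 1000),
        )
        rep = error_rates([read], genome)
        assert rep.substitution_rate == pytest.approx(1e-3)

    def test_run_restricted_indels_vanish_under_mask(self, genome):
        config = SimConfig(
            seed=2, substitution_rate=0.0, duplication_mean=1.0,
            t_run_deletion={L: 0.5 for L in range(5, 13)},
            a_run_insertion={L: 0.5 for L in range(5, 13)},
        )
        rng = np.random.default_rng(4)
        frags = [
            Fragment(genome.contig, int(s), int(s) + 150)
            for s in rng.integers(0, len(genome) - 150, size=4000)
        ]
        reads, ledger = simulate_reads(frags, genome, config)
        assert ledger.insertions or ledger.deletions
        unmasked = error_rates(reads, genome)
        masked = error_rates(reads, genome, mask_runs_ge=4)
        assert unmasked.insertion_rate + unmasked.deletion_rate > 0
        assert masked.insertion_rate + masked.deletion_rate == 0

    def test_order_invariance(self, genome):
        config = SimConfig(seed=3, duplication_mean=1.0)
        frags = [Fragment(genome.contig, s, s + 150) for s in range(0, 60_000, 600)]
        reads, _ = simulate_reads(frags, genome, config)
        a = error_rates(reads, genome)
        b = error_rates(list(reversed(reads)), genome)
        assert a == b


class TestIndelByRunLength:
    def test_no_indels_all_zero(self, genome):
        config = SimConfig(seed=1, substitution_rate=0.0, duplication_mean=1.0,
                           t_run_deletion={}, a_run_insertion={})
        frags = [Fragment(genome.contig, s, s + 150) for s in range(0, 30_000, 300)]
        reads, _ = simulate_reads(frags, genome, config)
        prof = indel_by_run_length(reads, genome)
        assert prof and all(v == 0 for v in prof.values())

    def test_injection_restricted_to_length_6(self, genome):
        config = SimConfig(
            seed=2, substitution_rate=0.0, duplication_mean=1.0,
            t_run_deletion={6: 0.9}, a_run_insertion={6: 0.9},
        )
        rng = np.random.default_rng(5)
        frags = [
            Fragment(genome.contig, int(s), int(s) + 150)
            for s in rng.integers(0, len(genome) - 150, size=5000)
        ]
        reads, ledger = simulate_reads(frags, genome, config)
        assert ledger.insertions or ledger.deletions
        prof = indel_by_run_length(reads, genome)
        assert prof.get(6, 0) > 0
        for L, v in prof.items():
            if L not in (5, 6, 7):  # adjacency attribution can bleed one bin
                assert v == 0

    def test_monotone_under_exponential_slippage(self, genome):
        config = SimConfig(seed=6, substitution_rate=0.0, duplication_mean=1.0)
        rng = np.random.default_rng(6)
        frags = [
            Fragment(genome.contig, int(s), int(s) + 150)
            for s in rng.integers(0, len(genome) - 150, size=30_000)
        ]
        reads, _ = simulate_reads(frags, genome, config)
        prof = indel_by_run_length(reads, genome, min_run=4)
        ls = [L for L in sorted(prof) if 4 <= L <= 7]  # longer runs too rare
        freqs = [prof[L] for L in ls]
        assert all(a < b for a, b in zip(freqs, freqs[1:]))


class TestEndComposition:
    def test_all_a_genome(self):
        g = GenomeSequence("c", "A" * 11_000)
        frags = [Fragment("c", s, s + 100) for s in range(0, 10_000, 100)]
        obs = end_composition(frags, g)
        np.testing.assert_allclose(obs.five_prime[0], 1.0)  # row A
        np.testing.assert_allclose(obs.three_prime[0], 1.0)

    def test_biased_generator_round_trip(self, genome, rng):
        n = 60_000
        starts = rng.integers(0, len(genome) - 150, size=n)
        frags = [Fragment(genome.contig, int(s), int(s) + 150, "+") for s in starts]
        profile = EndBiasProfile(five_prime={2: {"C": 4.0}})
        kept = apply_end_bias(frags, genome, profile, rng)
        obs = end_composition(kept, genome)
        c_row = obs.five_prime[1]  # row C
        assert c_row[1] > c_row[4:10].mean() + 0.05

    def test_unbiased_matches_base_composition(self, genome, rng):
        n = 20_000
        starts = rng.integers(0, len(genome) - 150, size=n)
        frags = [Fragment(genome.contig, int(s), int(s) + 150, "+") for s in starts]
        obs = end_composition(frags, genome)
        base_freq = np.array(
            [genome.sequence.count(b) / len(genome) for b in "ACGT"]
        )
        counts = (obs.five_prime * n).T  # per position
        pvals = [
            stats.chisquare(c, base_freq * n).pvalue for c in counts
        ]
        assert min(pvals) > 0.01 / len(pvals)  # Bonferroni-adjusted null check


class TestResamplingChi2:
    def test_hand_computed_statistic(self):
        stat, p = one_way_chi2([30, 970], [10, 990])
        assert stat == pytest.approx(40.404, abs=0.001)
        assert p < 1e-9

    def test_matched_observation_gives_statistic_zero(self):
        stat, p = one_way_chi2([10, 990], [10, 990])
        assert stat == 0 and p == pytest.approx(1.0)

    def test_forced_template_reuse_detected(self):
        config = SimConfig(seed=5, genome_length=10_000)
        from cfseq.simulate import make_genome

        g, _ = make_genome(config)
        rng = np.random.default_rng(7)
        letters = np.array(list("ACGT"))
        frags = [
            Fragment(
                g.contig, int(s), int(s) + 167, "+",
                "".join(letters[rng.integers(0, 4, size=8)]),
            )
            for s in rng.integers(0, len(g) - 167, size=800)
        ]
        # template reuse: same coordinates, fresh UMI
        for _ in range(40):
            f = frags[int(rng.integers(0, 800))]
            frags.append(
                Fragment(f.contig, f.start, f.end, "+",
                         "".join(letters[rng.integers(0, 4, size=8)]))
            )
        res = umi_resampling_test(frags, g, None, seed=3)
        assert res.p_value < 0.01
        assert res.observed_duplicate_pct > res.expected_duplicate_pct
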