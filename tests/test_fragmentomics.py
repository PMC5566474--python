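"""WPS, peak calling, spacing, periodicity, dinucleotides, FFT ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stst

from cfseq.core import Fragment, GenomeSequence, SiteAnnotation
from cfseq.fragmentomics import (
    LONG,
    SHORT,
    LengthDistribution,
    NucleosomePeak,
    WpsTrack,
    call_peaks,
    compare_rankings,
    compute_wps,
    compute_wps_brute,
    dinucleotide_profile,
    estimate_length_periodicity,
    internucleosome_distances,
    length_distribution,
    meta_profile,
    nearest_center_distances,
    rank_tissues,
    scale_track,
    tss_band_intensity,
)


class TestComputeWps:
    def test_no_fragments_zero_track(self):
        t = compute_wps([], LONG, ("c", 0, 100))
        assert (t.values == 0).all() and t.window == 120

    def test_single_fragment_boundary_positions(self):
        # fragment [10,130) with w=120: at p=70 the window is exactly the
        # fragment (spanning, +1); at p=71 only the endpoint is inside (-1)
        frags = [Fragment("c", 10, 130)]
        t = compute_wps(frags, LONG, ("c", 60, 80))
        assert t.values[70 - 60] == 1
        assert t.values[71 - 60] == -1

    def test_window_sizes_by_class(self):
        assert LONG.window == 120 and SHORT.window == 16
        assert (LONG.min_length, LONG.max_length) == (120, 180)
        assert (SHORT.min_length, SHORT.max_length) == (35, 80)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(stst.integers(0, 2**31 - 1))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        frags = []
        for _ in range(n):
            s = int(rng.integers(0, 4800))
            L = int(rng.integers(20, 220))
            frags.append(Fragment("c", s, s + L))
        region = ("c", 50, 1050)
        for cls in (LONG, SHORT):
            fast = compute_wps(frags, cls, region).values
            slow = compute_wps_brute(frags, cls, region)
            np.testing.assert_array_equal(fast, slow)


class TestScaleTrack:
    def test_population_standardization(self):
        t = WpsTrack("c", 0, np.array([1.0, 2.0, 3.0]), 120)
        s = scale_track(t)
        np.testing.assert_allclose(s.values, [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert abs(s.values.mean()) < 1e-9
        assert abs(s.values.std() - 1) < 1e-9

    def test_idempotent_and_affine_invariant(self, rng):
        v = rng.normal(size=500)
        base = scale_track(WpsTrack("c", 0, v, 120)).values
        again = scale_track(WpsTrack("c", 0, base.copy(), 120)).values
        affine = scale_track(WpsTrack("c", 0, 3.5 * v - 11.0, 120)).values
        np.testing.assert_allclose(again, base, atol=1e-9)
        np.testing.assert_allclose(affine, base, atol=1e-9)

    def test_constant_track_rejected(self):
        with pytest.raises(ValueError):
            scale_track(WpsTrack("c", 0, np.ones(10), 120))


class TestCallPeaks:
    def test_flat_track_no_peaks(self):
        t = WpsTrack("c", 0, np.zeros(5000), 120)
        assert call_peaks(t) == []

    def test_isolated_protected_region_centered(self):
        # a single 147-bp protected plateau: one peak at its midpoint +/- 5
        v = np.zeros(5000)
        v[2400:2547] = 10.0
        peaks = call_peaks(WpsTrack("c", 0, v, 120))
        assert len(peaks) == 1
        assert abs(peaks[0].center - 2473) <= 5

    def test_planted_array_recovery(self):
        from cfseq.simulate import SimConfig, make_genome, simulate_cfdna_fragments

        config = SimConfig(seed=13, n_fragments=30_000, genome_length=50_000)
        genome, _ = make_genome(config)
        frags, truth = simulate_cfdna_fragments(config, genome)
        track = compute_wps(frags, LONG, (genome.contig, 0, len(genome)))
        peaks = call_peaks(track)
        centers = np.sort([p.center for p in peaks])
        hits = 0
        for c in truth.nucleosome_centers:
            i = np.searchsorted(centers, c)
            near = [centers[j] for j in (i - 1, i) if 0 <= j < len(centers)]
            if near and min(abs(x - c) for x in near) <= 20:
                hits += 1
        assert hits / len(truth.nucleosome_centers) >= 0.9


class TestSpacing:
    @staticmethod
    def _peaks(centers):
        return [NucleosomePeak("c", c, c - 50, c + 50, 1.0) for c in centers]

    def test_exact_grid_mode(self):
        res = internucleosome_distances(self._peaks(range(0, 3600, 180)))
        assert res.mode == 180 and res.smoothed_mode == 180

    def test_nearest_method_matches_hand_computation(self):
        res = internucleosome_distances(self._peaks([0, 150, 360]), method="nearest")
        assert sorted(res.distances.tolist()) == [150, 150, 210]

    def test_adjacent_method_gaps(self):
        res = internucleosome_distances(self._peaks([0, 150, 360]))
        assert sorted(res.distances.tolist()) == [150, 210]

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            internucleosome_distances(self._peaks([5]))


class TestNearestCenterDistances:
    @staticmethod
    def _peaks(centers):
        return [NucleosomePeak("c", c, c - 10, c + 10, 1.0) for c in centers]

    def test_identical_sets_all_zero(self):
        a = self._peaks([100, 400, 900])
        h = nearest_center_distances(a, a)
        assert (h.distances == 0).all()
        assert h.fraction_beyond_cutoff == 0.0

    def test_signed_distance_and_binning(self):
        h = nearest_center_distances(self._peaks([1000]), self._peaks([1010, 2500]))
        assert h.distances.tolist() == [10]
        # bin width 6 centered on zero: +10 falls in [9, 15)
        idx = np.digitize(10, h.bin_edges) - 1
        lo, hi = h.bin_edges[idx], h.bin_edges[idx + 1]
        assert (lo, hi) == (9.0, 15.0)
        assert h.counts[idx] == 1

    def test_empty_comparison_set_rejected(self):
        with pytest.raises(ValueError):
            nearest_center_distances(self._peaks([1]), [])


class TestLengthPeriodicity:
    def test_exact_comb_period_10(self):
        counts = np.zeros(200)
        counts[50:160:10] = 100.0  # teeth every 10 bases
        counts += 1.0
        dist = LengthDistribution(np.arange(200), counts, 167)
        est = estimate_length_periodicity(dist)
        assert est.period == pytest.approx(10.0, abs=0.01)

    def test_smooth_unimodal_histogram_rejected(self):
        x = np.arange(200, dtype=float)
        counts = np.exp(-0.5 * ((x - 167) / 20) ** 2) * 1000
        dist = LengthDistribution(x, counts, 167)
        with pytest.raises(ValueError):
            estimate_length_periodicity(dist)

    def test_default_cohort_recovers_nick_periodicity(self):
        from cfseq.simulate import SimConfig, make_genome, simulate_cfdna_fragments

        config = SimConfig(seed=11, n_fragments=100_000)
        genome, _ = make_genome(config)
        frags, _ = simulate_cfdna_fragments(config, genome)
        est = estimate_length_periodicity(length_distribution(frags))
        assert est.period == pytest.approx(10.4, abs=0.3)


class TestMetaProfile:
    def test_single_site_equals_local_track(self):
        v = np.sin(np.arange(4000) / 50.0)
        track = WpsTrack("c", 0, v, 120)
        sites = SiteAnnotation([("c", 1999, 2001, "+", "s")], anchor="midpoint")
        prof = meta_profile({"c": track}, sites, flank=100)
        np.testing.assert_allclose(prof.mean, v[1900:2101])

    def test_opposite_strand_flip_cancels_ramp(self):
        ramp = np.arange(-1000, 1001, dtype=float)
        track = WpsTrack("c", 0, np.concatenate([ramp, ramp]), 120)
        sites = SiteAnnotation(
            [("c", 999, 1001, "+", "a"), ("c", 3000, 3002, "-", "b")],
            anchor="midpoint",
        )
        prof = meta_profile({"c": track}, sites)
        np.testing.assert_allclose(prof.mean, 0.0, atol=1e-9)

    def test_no_usable_sites_rejected(self):
        track = WpsTrack("c", 0, np.zeros(100), 120)
        sites = SiteAnnotation([("other", 10, 12, "+", "x")])
        with pytest.raises(ValueError):
            meta_profile({"c": track}, sites)

    def test_phased_arrays_show_planted_spacing(self):
        from cfseq.simulate import SimConfig, make_genome, simulate_cfdna_fragments
        from scipy import signal as sps

        config = SimConfig(seed=17, n_fragments=60_000, genome_length=60_000)
        genome, _ = make_genome(config)
        frags, truth = simulate_cfdna_fragments(config, genome)
        raw = compute_wps(frags, LONG, (genome.contig, 0, len(genome)))
        scaled = scale_track(raw)
        anchors = [
            (genome.contig, int(c) - 1, int(c) + 1, "+", f"n{i}")
            for i, c in enumerate(truth.nucleosome_centers[5:-5])
        ]
        prof = meta_profile({genome.contig: scaled}, SiteAnnotation(anchors))
        peaks, _ = sps.find_peaks(prof.mean, distance=100)
        spac = np.diff(prof.positions[peaks])
        assert abs(np.median(spac) - config.nucleosome_spacing) <= 5


class TestDinucleotideProfile:
    def test_all_a_genome_flat(self):
        g = GenomeSequence("c", "A" * 15_000)
        frags = [Fragment("c", 300 + 11 * i, 300 + 11 * i + 167) for i in range(150)]
        prof = dinucleotide_profile(frags, g)
        np.testing.assert_allclose(prof.raw.loc["AA"], 1.0)
        np.testing.assert_allclose(prof.normalized.loc["AA"], 1.0)

    def test_planted_10bp_phasing_recovered(self, rng):
        # W/S content oscillates with 10-bp period; fragments phase-locked
        # to the same grid, so AT and GC normalized profiles oscillate in
        # antiphase at period 10
        n = 20_000
        phase_at = (np.arange(n) % 10) < 5
        p_at = np.where(phase_at, 0.85, 0.15)
        bases = np.where(
            rng.random(n) < p_at,
            np.where(rng.random(n) < 0.5, "A", "T"),
            np.where(rng.random(n) < 0.5, "G", "C"),
        )
        g = GenomeSequence("c", "".join(bases))
        frags = [Fragment("c", 200 + 10 * i, 200 + 10 * i + 167) for i in range(1500)]
        prof = dinucleotide_profile(frags, g)
        at = prof.normalized.loc["AT"].to_numpy()
        gc = prof.normalized.loc["GC"].to_numpy()
        assert not np.isnan(at).any()
        spec_at = np.abs(np.fft.rfft(at - at.mean()))
        freq = np.fft.rfftfreq(len(at))
        dominant_period = 1 / freq[np.argmax(spec_at[1:]) + 1]
        assert dominant_period == pytest.approx(10.0, abs=0.5)
        assert np.corrcoef(at, gc)[0, 1] < -0.5

    def test_too_few_target_fragments_rejected(self):
        g = GenomeSequence("c", "ACGT" * 3000)
        with pytest.raises(ValueError):
            dinucleotide_profile([Fragment("c", 500, 667)], g)


class TestTssBandIntensity:
    @staticmethod
    def _tss(label="g1", strand="+", pos=0):
        return SiteAnnotation([("c", pos, pos + 1, strand, label)], anchor="start")

    def test_sinusoid_period_195_dominates_control_band(self):
        sig = np.sin(2 * np.pi * np.arange(10_000) / 195.0)
        track = WpsTrack("c", 0, sig, 120)
        band = tss_band_intensity({"c": track}, self._tss())["g1"]
        ctrl = tss_band_intensity({"c": track}, self._tss(), band=(150, 159))["g1"]
        assert band > 100 * ctrl

    def test_constant_signal_zero_intensity(self):
        track = WpsTrack("c", 0, np.full(10_000, 5.0), 120)
        assert tss_band_intensity({"c": track}, self._tss())["g1"] == 0.0

    def test_invariant_to_added_constant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=10_000)
        a = tss_band_intensity({"c": WpsTrack("c", 0, v, 120)}, self._tss())["g1"]
        b = tss_band_intensity({"c": WpsTrack("c", 0, v + 42.0, 120)}, self._tss())["g1"]
        assert a == pytest.approx(b, rel=1e-9)

    def test_insufficient_coverage_gene_dropped(self):
        track = WpsTrack("c", 0, np.ones(3000), 120)
        with pytest.raises(ValueError):
            tss_band_intensity({"c": track}, self._tss())


class TestRankTissues:
    def test_anticorrelated_tissue_ranks_first(self, rng):
        genes = [f"g{i}" for i in range(200)]
        expr = pd.DataFrame(
            rng.lognormal(1, 1, size=(200, 5)), index=genes,
            columns=[f"t{i}" for i in range(5)],
        )
        intensity = pd.Series(
            -np.log2(expr["t2"] + 1) + rng.normal(0, 1e-6, 200), index=genes
        )
        ranking = rank_tissues(intensity, expr)
        assert ranking.ranking[0] == "t2"
        assert ranking.correlations.iloc[0] < -0.99

    def test_zero_variance_column_excluded(self, rng):
        genes = [f"g{i}" for i in range(150)]
        expr = pd.DataFrame(
            {"t0": rng.lognormal(1, 1, 150), "flat": np.ones(150)}, index=genes
        )
        ranking = rank_tissues(pd.Series(rng.normal(size=150), index=genes), expr)
        assert "flat" in ranking.excluded

    def test_spearman_identical_rankings(self):
        assert compare_rankings(["a", "b", "c"], ["a", "b", "c"]) == 1.0
        assert compare_rankings(["a", "b", "c"], ["c", "b", "a"]) == -1.0
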