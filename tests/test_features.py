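import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopsmooth.features import (
    SequenceSet,
    at_frequency,
    autocorrelation,
    band_power,
    cross_correlation,
    dinuc_ww_frequency,
    dyad_profile,
    peak_period,
    polyat_coverage,
    power_spectrum,
    quartile_split,
    tune_amplitude_ratio,
)
from loopsmooth.sequences import reverse_complement
from loopsmooth.tracks import PositionTrack


def make_set(sequences, scores=None):
    scores = scores if scores is not None else np.zeros(len(sequences))
    return SequenceSet([f"s{i}" for i in range(len(sequences))], sequences, scores)


class TestSequenceSet:
    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            make_set(["AXGT"])

    def test_length_enforced(self):
        with pytest.raises(ValueError):
            make_set(["ACGT", "ACG"])

    def test_lowercase_uppercased(self):
        sset = make_set(["acgt"])
        assert sset.sequences[0] == "ACGT"


class TestQuartileSplit:
    def test_eight_sequences(self):
        sset = make_set(["A" * 10] * 8, scores=[1, 2, 3, 4, 5, 6, 7, 8])
        top, bottom = quartile_split(sset)
        assert sorted(top.scores) == [7, 8]
        assert sorted(bottom.scores) == [1, 2]

    def test_stable_tie_rule(self):
        sset = make_set(["A" * 10] * 8, scores=[1.0] * 8)
        top, bottom = quartile_split(sset)
        assert top.ids == ["s0", "s1"]
        assert bottom.ids == ["s0", "s1"]

    def test_rejects_small_sets(self):
        with pytest.raises(ValueError):
            quartile_split(make_set(["ACGT"] * 3))

    def test_fixture_top_quartile_enriched_for_periodic_ww(self, fixture_data):
        # sequences with planted periodic WW were designed to score high
        lib = fixture_data.library
        sset = SequenceSet(
            list(lib["id"]), list(lib["sequence"]), lib["c0_true"].to_numpy()
        )
        top, bottom = quartile_split(sset)
        ww_top = dinuc_ww_frequency(top).values.mean()
        ww_bottom = dinuc_ww_frequency(bottom).values.mean()
        assert ww_top > ww_bottom


class TestDinucWW:
    def test_single_sequence_aatt(self):
        profile = dinuc_ww_frequency(make_set(["AATT" + "G" * 46]))
        np.testing.assert_allclose(profile.values[:3], 1.0)
        np.testing.assert_allclose(profile.values[3:], 0.0)

    def test_all_gc_zero(self):
        profile = dinuc_ww_frequency(make_set(["GCGC" * 10]))
        np.testing.assert_allclose(profile.values, 0.0)

    def test_half_frequency(self):
        profile = dinuc_ww_frequency(make_set(["AAGG", "GGGG"]))
        assert profile.values[0] == pytest.approx(0.5)

    def test_n_does_not_count(self):
        profile = dinuc_ww_frequency(make_set(["ANAT"]))
        np.testing.assert_allclose(profile.values, [0.0, 0.0, 1.0])

    def test_values_in_unit_interval(self, fixture_data):
        lib = fixture_data.library.head(500)
        profile = dinuc_ww_frequency(
            SequenceSet(list(lib["id"]), list(lib["sequence"]), lib["c26"].to_numpy())
        )
        assert (profile.values >= 0).all() and (profile.values <= 1).all()

    def test_reverse_complement_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, 30)) for _ in range(40)]
        fwd = dinuc_ww_frequency(make_set(seqs)).values
        rev = dinuc_ww_frequency(
            make_set([reverse_complement(s) for s in seqs])
        ).values
        np.testing.assert_allclose(fwd, rev[::-1])

    def test_union_is_weighted_mean(self, rng):
        bases = np.array(list("ACGT"))
        seqs_a = ["".join(rng.choice(bases, 20)) for _ in range(10)]
        seqs_b = ["".join(rng.choice(bases, 20)) for _ in range(30)]
        pa = dinuc_ww_frequency(make_set(seqs_a)).values
        pb = dinuc_ww_frequency(make_set(seqs_b)).values
        pu = dinuc_ww_frequency(make_set(seqs_a + seqs_b)).values
        np.testing.assert_allclose(pu, (10 * pa + 30 * pb) / 40, atol=1e-12)


class TestPolyAT:
    def test_single_run(self):
        profile = polyat_coverage(make_set(["GGAAAAGG" + "C" * 42]))
        expected = np.zeros(50)
        expected[2:6] = 1.0
        np.testing.assert_allclose(profile.values, expected)

    def test_alternating_at_does_not_qualify(self):
        profile = polyat_coverage(make_set(["ATATATATAT"]))
        np.testing.assert_allclose(profile.values, 0.0)

    def test_all_t_fully_covered(self):
        profile = polyat_coverage(make_set(["T" * 50]))
        np.testing.assert_allclose(profile.values, 1.0)

    def test_min_len_boundary(self):
        assert polyat_coverage(make_set(["AAAG"]), min_len=4).values.sum() == 0
        assert polyat_coverage(make_set(["AAAAG"]), min_len=4).values.sum() == 4

    def test_n_breaks_runs(self):
        profile = polyat_coverage(make_set(["AANAA"]))
        np.testing.assert_allclose(profile.values, 0.0)

    def test_rejects_min_len_below_two(self):
        with pytest.raises(ValueError):
            polyat_coverage(make_set(["ACGT"]), min_len=1)


class TestCorrelations:
    def test_autocorrelation_at_zero_is_one(self, rng):
        track = PositionTrack("c", 1, rng.normal(size=200))
        series = autocorrelation(track, 5)
        assert series[0] == pytest.approx(1.0)

    def test_shifted_sinusoid_peak_at_shift(self):
        l = np.arange(500)
        base = np.sin(2 * np.pi * l / 10.4)
        a = PositionTrack("c", 1, base)
        b = PositionTrack("c", 1, np.sin(2 * np.pi * (l - 5) / 10.4))
        series = cross_correlation(b, a, max_lag=9)
        assert int(np.argmax(series)) == 5

    def test_insufficient_overlap_rejected(self):
        track = PositionTrack("c", 1, np.arange(20.0))
        with pytest.raises(ValueError):
            autocorrelation(track, 5)


class TestSpectrum:
    def test_constant_track_zero_power(self):
        spec = power_spectrum(PositionTrack("c", 1, np.full(128, 3.0)))
        np.testing.assert_allclose(spec.power, 0.0, atol=1e-20)

    def test_pure_sinusoid_peak(self):
        l = np.arange(16384)
        spec = power_spectrum(PositionTrack("c", 1, np.sin(2 * np.pi * l / 10.4)))
        assert 10.3 <= peak_period(spec, (5, 50)) <= 10.5

    def test_parseval(self, rng):
        values = rng.normal(size=1024)
        spec = power_spectrum(PositionTrack("c", 1, values))
        assert spec.total_power() == pytest.approx(values.var(), rel=0.01)

    def test_requires_gapfree(self):
        values = np.ones(128)
        values[3] = np.nan
        with pytest.raises(ValueError):
            power_spectrum(PositionTrack("c", 1, values))

    def test_requires_min_length(self):
        with pytest.raises(ValueError):
            power_spectrum(PositionTrack("c", 1, np.ones(32)))

    def test_empty_band_rejected(self):
        spec = power_spectrum(PositionTrack("c", 1, np.random.default_rng(0).normal(size=128)))
        with pytest.raises(ValueError):
            peak_period(spec, (10, 5))


class TestDyadProfile:
    def test_constant_track(self):
        track = PositionTrack("c", 1, np.full(500, 1.5))
        profile = dyad_profile(track, [250], flank=10)
        np.testing.assert_allclose(profile.mean, 1.5)
        assert profile.n_dyads == 1

    def test_single_dyad_verbatim(self, rng):
        values = rng.normal(size=300)
        track = PositionTrack("c", 1, values)
        profile = dyad_profile(track, [150], flank=5)
        np.testing.assert_allclose(profile.mean, values[144:155])

    def test_edge_dyads_skipped_and_counted(self):
        track = PositionTrack("c", 1, np.arange(100.0))
        profile = dyad_profile(track, [2, 50, 99], flank=10)
        assert profile.n_dyads == 1
        assert profile.n_skipped == 2

    def test_no_usable_dyads_rejected(self):
        track = PositionTrack("c", 1, np.arange(30.0))
        with pytest.raises(ValueError):
            dyad_profile(track, [1], flank=50)

    def test_phase_locked_bias_oscillates_then_smooths_away(self):
        # planted 10.4-bp sinusoidal bias with dyads spaced five helical
        # turns apart: the dyad-aligned profile oscillates; after the
        # helical-window smoothing + six-track averaging the oscillation
        # collapses by more than 10x
        from loopsmooth.smoothing import c0s_estimate, moving_average

        rng = np.random.default_rng(5)
        n = 6000
        l = np.arange(n)
        c0 = np.cumsum(rng.normal(0, 0.01, n))
        biased = PositionTrack("c", 1, c0 + 1.5 * np.sin(2 * np.pi * l / 10.4))
        smoothed6 = [
            moving_average(
                PositionTrack(
                    "c", 1,
                    c0 + 1.5 * np.sin(2 * np.pi * l / 10.4 + phase),
                ),
                10.4,
            )
            for phase in np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ]
        clean = c0s_estimate(smoothed6)
        dyads = list(range(200, n - 200, 52))

        def oscillation(track):
            profile = dyad_profile(track, dyads, flank=40).mean
            profile = profile - np.nanmean(profile)
            return np.nanmax(profile) - np.nanmin(profile)

        assert oscillation(biased) > 10 * oscillation(clean)


class TestTuneRatio:
    def _library(self, rng, n=1200):
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, 50)) for _ in range(n)]
        return seqs

    def test_single_element_grid(self, rng):
        seqs = self._library(rng)
        c26 = rng.normal(size=len(seqs))
        c31 = rng.normal(size=len(seqs))
        result = tune_amplitude_ratio(seqs, c26, c31, [0.55], top_n=1000)
        assert result.best_f == 0.55

    def test_random_library_flagged_unstable(self, rng):
        seqs = self._library(rng)
        c26 = rng.normal(size=len(seqs))
        c31 = rng.normal(size=len(seqs))
        result = tune_amplitude_ratio(
            seqs, c26, c31, [0.4, 0.7, 1.0, 1.3], top_n=1000
        )
        assert not result.stable

    def test_planted_periodicity_recovers_f(self, rng):
        # construct a library where sequences whose tether bias survives the
        # wrong weighting carry phased A/T periodicity: ranking by
        # q = c26 + f*c31 cancels the bias exactly at f = 0.7, so the top
        # set's 10-bp A/T band power is minimized there
        n = 2000
        bases = np.array(list("CG"))
        seqs, c26, c31 = [], [], []
        phases = rng.uniform(0, 2 * np.pi, n)
        c0s = rng.normal(0, 1.0, n)
        for phase, c0 in zip(phases, c0s):
            amp26 = 2.0
            amp31 = amp26 / 0.7
            b26 = amp26 * np.sin(2 * np.pi * 26 / 10.4 + phase)
            b31 = amp31 * np.sin(2 * np.pi * 31 / 10.4 + phase)
            c26.append(c0 + b26)
            c31.append(c0 + b31)
            # A/T placed at helical crests aligned with the sequence phase
            x = np.arange(50)
            crest = np.cos(2 * np.pi * x / 10.4 - phase) > 0.4
            seq = rng.choice(bases, 50)
            seq[crest] = "A"
            seqs.append("".join(seq))
        result = tune_amplitude_ratio(
            seqs, np.array(c26), np.array(c31), [0.4, 0.55, 0.7, 0.85, 1.0],
            top_n=500,
        )
        assert result.best_f == pytest.approx(0.7)
        assert result.stable


class TestBandPowerHelpers:
    def test_at_frequency_counts(self):
        freq = at_frequency(["AT", "GC", "AC"])
        np.testing.assert_allclose(freq, [2 / 3, 1 / 3])

    def test_band_power_of_pure_period_ten(self):
        x = np.sin(2 * np.pi * np.arange(50) / 10.0)
        assert band_power(x, (9, 12)) > 100 * band_power(
            np.zeros(50) + 1e-9, (9, 12)
        )

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_profiles_bounded(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGTN"))
        seqs = ["".join(rng.choice(bases, 12)) for _ in range(5)]
        sset = make_set(seqs)
        ww = dinuc_ww_frequency(sset).values
        cov = polyat_coverage(sset).values
        assert ((ww >= 0) & (ww <= 1)).all()
        assert ((cov >= 0) & (cov <= 1)).all()
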