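"""Tone-cloud generator: grid arithmetic, marginal statistics, change
injection, chord sampling, rendering and event series."""

import numpy as np
import pytest
from scipy.io import wavfile

from tonecloud import stimulus as st


class TestFrequencyGrid:
    def test_semitone_enumeration_matches_brute_force(self):
        # inclusive enumeration: every k >= 0 with 400 * 2^(k/12) <= 400 * 2^2.2
        f_max = 400 * 2 ** 2.2
        expected = sum(1 for k in range(100) if 400 * 2 ** (k / 12) <= f_max)
        g = st.build_frequency_grid(n_tones=None)
        assert g.n_tones == expected == 27

    def test_default_grid_keeps_26_tones(self, grid):
        assert grid.n_tones == 26
        assert np.all(np.diff(np.log2(grid.tone_freqs)) * 12 == pytest.approx(1.0))
        assert grid.tone_freqs[0] == 400.0

    def test_bins_are_contiguous_with_3_or_4_tones(self, grid):
        sizes = grid.bin_sizes
        assert sizes.tolist() == [4, 3, 3, 3, 4, 3, 3, 3]
        assert np.all(np.diff(grid.bin_membership) >= 0)
        assert set(grid.bin_membership) == set(range(8))

    @pytest.mark.parametrize("d, st_expected", [(2, 6.6), (3, 9.9), (5, 16.5), (7, 23.1)])
    def test_bin_distance_table(self, grid, d, st_expected):
        assert grid.pair_distance_st((1, 1 + d)) == pytest.approx(st_expected)

    def test_localized_span_is_two_bins(self, grid):
        assert grid.localized_span_oct() == pytest.approx(0.55)

    def test_single_bin_degenerate_partition(self):
        g = st.build_frequency_grid(n_bins=1)
        assert np.all(g.bin_membership == 0)

    @pytest.mark.parametrize("kwargs", [dict(span=-1), dict(n_bins=0), dict(n_tones=100)])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            st.build_frequency_grid(**kwargs)


class TestBaselineMarginal:
    def test_normalized_and_correct_level_multiset(self, rng):
        m = st.sample_baseline_marginal(rng)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
        # recover the nominal level of each bin from the renormalized vector
        nominal = m.p * sum(np.repeat(st.MARGINAL_LEVELS, st.MARGINAL_LEVEL_COUNTS))
        counts = {lv: int(np.isclose(nominal, lv, atol=1e-6).sum())
                  for lv in st.MARGINAL_LEVELS}
        assert counts == dict(zip(st.MARGINAL_LEVELS, st.MARGINAL_LEVEL_COUNTS))

    def test_uniform_permutation_frequencies(self, rng):
        # every level multiset permutation is equally likely, so bin b carries
        # level l with probability count(l)/8 (exact enumeration expectation)
        n = 20_000
        low_in_bin0 = 0
        for _ in range(n):
            m = st.sample_baseline_marginal(rng)
            nominal = m.p * 1.063
            low_in_bin0 += bool(abs(nominal[0] - 0.083) < 1e-6)
        p_hat = low_in_bin0 / n
        se = np.sqrt(3 / 8 * 5 / 8 / n)
        assert abs(p_hat - 3 / 8) < 4 * se

    def test_tone_draw_probability_extremes(self):
        lo, hi = st.tone_draw_probability_range()
        assert round(lo, 3) == 0.021
        assert round(hi, 3) == 0.063


class TestChangeTime:
    def test_draws_respect_cap(self, rng):
        draws = [st.sample_change_time(rng) for _ in range(2000)]
        assert 0 <= min(draws) and max(draws) <= 8.0

    def test_untruncated_mean(self, rng):
        draws = np.array([st.sample_change_time(rng, cap=1e9) for _ in range(50_000)])
        assert draws.mean() == pytest.approx(3.2, rel=0.03)

    def test_density_stays_exponential_on_the_interval(self, rng):
        # redraw-truncation keeps p(t) proportional to exp(-t/mean) on [0, cap]:
        # per-bin counts divided by the untruncated exponential bin mass are flat
        draws = np.array([st.sample_change_time(rng) for _ in range(200_000)])
        edges = np.arange(0.0, 8.01, 0.25)
        counts, _ = np.histogram(draws, edges)
        mass = np.exp(-edges[:-1] / 3.2) - np.exp(-edges[1:] / 3.2)
        ratio = counts / mass
        sel = (edges[:-1] >= 0.5) & (edges[:-1] < 6.0)
        assert ratio[sel].max() / ratio[sel].min() < 1.1

    def test_bad_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            st.sample_change_time(rng, mean=-1)


class TestApplyChange:
    def test_50_percent_increment_is_00625(self):
        assert st.change_increment(50) == pytest.approx(0.0625)

    def test_zero_size_is_identity(self, rng):
        base = st.sample_baseline_marginal(rng)
        post = st.apply_change(base, st.ChangeSpec(0, (1, 2), 1.0))
        assert np.allclose(post.p, base.p)

    def test_uniform_base_110_percent_hand_oracle(self):
        base = st.MarginalDistribution(np.full(8, 0.125))
        post = st.apply_change(base, st.ChangeSpec(110, (1, 2), 1.0))
        inc = 1.10 * 0.125
        expected = np.full(8, 0.125)
        expected[[0, 1]] += inc
        expected /= expected.sum()
        assert np.allclose(post.p, expected)

    @pytest.mark.parametrize("size", [30, 50, 80, 110, 140])
    def test_changed_bins_rise_others_fall(self, rng, size):
        base = st.sample_baseline_marginal(rng)
        post = st.apply_change(base, st.ChangeSpec(size, (3, 6), 1.0))
        assert post.p.sum() == pytest.approx(1.0, abs=1e-12)
        up = np.array([2, 5])
        down = np.setdiff1d(np.arange(8), up)
        assert np.all(post.p[up] > base.p[up])
        assert np.all(post.p[down] < base.p[down])

    def test_invalid_bins_rejected(self, rng):
        base = st.sample_baseline_marginal(rng)
        with pytest.raises(ValueError):
            st.apply_change(base, st.ChangeSpec(50, (0, 2), 1.0))
        with pytest.raises(ValueError):
            st.ChangeSpec(50, (3, 3), 1.0)


class TestChords:
    def test_tone_rate_near_147_per_second(self, grid, rng):
        base = st.sample_baseline_marginal(rng)
        seq = st.generate_chords(grid, base, base, 0.0, 20.0, rng)
        rate = seq.tone_count() / seq.duration
        assert rate == pytest.approx(2.0 * 2.2 / 0.030, rel=0.05)

    def test_concentrated_marginal_hits_one_bin(self, grid, rng):
        p = np.full(8, 1e-9)
        p[4] = 1.0
        conc = st.MarginalDistribution(p)
        seq = st.generate_chords(grid, conc, conc, 0.0, 3.0, rng)
        counts = seq.bin_counts(grid)
        assert counts[:, 4].sum() == seq.tone_count()

    def test_pre_post_marginals_switch_at_change_time(self, grid, rng):
        lo = np.full(8, 1e-9); lo[0] = 1.0
        hi = np.full(8, 1e-9); hi[7] = 1.0
        seq = st.generate_chords(grid, st.MarginalDistribution(lo),
                                 st.MarginalDistribution(hi), 1.5, 3.0, rng)
        counts = seq.bin_counts(grid)
        assert counts[:50, 0].sum() == counts[:50].sum()
        assert counts[50:, 7].sum() == counts[50:].sum()

    def test_bad_durations_rejected(self, grid, rng):
        base = st.sample_baseline_marginal(rng)
        with pytest.raises(ValueError):
            st.generate_chords(grid, base, base, 0.0, -1.0, rng)
        with pytest.raises(ValueError):
            st.generate_chords(grid, base, base, 5.0, 3.0, rng)


class TestWaveform:
    def test_empty_sequence_renders_silence(self, grid):
        seq = st.ChordSequence([np.empty(0, dtype=int)] * 10)
        w = st.render_waveform(seq, grid, sample_rate=16_000)
        assert w.shape == (10 * 480,)
        assert np.all(w == 0)

    def test_single_tone_spectral_peak(self, grid):
        seq = st.ChordSequence([np.array([0])] * 4)   # 400 Hz tone
        w = st.render_waveform(seq, grid, sample_rate=16_000)
        f = np.fft.rfftfreq(w.size, 1 / 16_000)
        peak = f[np.argmax(np.abs(np.fft.rfft(w)))]
        assert peak == pytest.approx(400.0, abs=10)

    def test_doubling_amplitude_adds_6dB(self, grid, rng):
        base = st.sample_baseline_marginal(rng)
        seq = st.generate_chords(grid, base, base, 0.0, 1.0, rng)
        w1 = st.render_waveform(seq, grid, level_db=64.0, sample_rate=16_000)
        w2 = st.render_waveform(seq, grid, level_db=64.0 + 20 * np.log10(2), sample_rate=16_000)
        rms_gain = 20 * np.log10(np.sqrt((w2 ** 2).mean()) / np.sqrt((w1 ** 2).mean()))
        assert rms_gain == pytest.approx(6.02, abs=0.01)

    def test_nyquist_violation_rejected(self, grid):
        seq = st.ChordSequence([np.array([0])])
        with pytest.raises(ValueError):
            st.render_waveform(seq, grid, sample_rate=3000)

    def test_wav_roundtrip(self, grid, rng, tmp_path):
        base = st.sample_baseline_marginal(rng)
        seq = st.generate_chords(grid, base, base, 0.0, 0.5, rng)
        w = st.render_waveform(seq, grid, sample_rate=16_000)
        st.save_wav(tmp_path / "x.wav", w, 16_000)
        rate, back = st.load_wav(tmp_path / "x.wav")
        assert rate == 16_000
        assert np.allclose(back, w, atol=1e-6)


class TestEventSeries:
    def test_single_tone_maps_to_its_pair_channel(self, grid):
        tone_in_bin3 = int(np.nonzero(grid.bin_membership == 2)[0][0])
        chords = [np.array([tone_in_bin3])] + [np.empty(0, dtype=int)] * 3
        S = st.bin_event_series(st.ChordSequence(chords), grid)
        assert S.shape == (4, 12)
        assert np.all(S[1, :3] == 1)           # channel {3,4}
        assert S.sum() == 3

    def test_silent_chords_give_zero_series(self, grid):
        S = st.bin_event_series(st.ChordSequence([np.empty(0, dtype=int)] * 5), grid)
        assert np.all(S == 0)

    def test_presence_rate_matches_poisson_thinning(self, grid, rng):
        # P(channel active) = 1 - exp(-lambda * p_pair), lambda = mean tones/chord
        base = st.sample_baseline_marginal(rng)
        seq = st.generate_chords(grid, base, base, 0.0, 150.0, rng)
        S = st.bin_event_series(seq, grid)
        lam = 2.0 * grid.span
        for i, (b1, b2) in enumerate(st.LOCALIZED_PAIRS):
            p_pair = base.p[b1 - 1] + base.p[b2 - 1]
            expected = 1 - np.exp(-lam * p_pair)
            assert S[i].mean() == pytest.approx(expected, abs=0.02)

    def test_count_series_mean_is_per_bin_rate(self, grid, rng):
        base = st.MarginalDistribution(np.full(8, 0.125))
        seq = st.generate_chords(grid, base, base, 0.0, 150.0, rng)
        C = st.bin_count_series(seq, grid)
        assert C.mean() == pytest.approx(2.0 * grid.span / 8, rel=0.03)

    def test_incompatible_dt_rejected(self, grid):
        seq = st.ChordSequence([np.empty(0, dtype=int)] * 5)
        with pytest.raises(ValueError):
            st.bin_event_series(seq, grid, dt=0.007)


class TestTrialBatch:
    def test_default_batch_is_930_trials(self):
        trials = st.generate_trial_batch(0)
        assert len(trials) == 930
        sizes = {t.change.size for t in trials}
        assert sizes == {50, 80, 110, 140}

    def test_nonlocalized_pair_counts(self):
        pairs = st.nonlocalized_pairs()
        by_d = {d: sum(1 for a, b in pairs if b - a == d) for d in (2, 3, 5, 7)}
        assert by_d == {2: 6, 3: 5, 5: 3, 7: 1}

    def test_trial_invariants(self, small_batch):
        for ts in small_batch:
            assert ts.post.p.sum() == pytest.approx(1.0, abs=1e-12)
            assert 60 <= ts.level_db <= 80
            assert ts.max_duration == pytest.approx(ts.change.time + 2.0)

    def test_serialization_roundtrip(self, small_batch, grid):
        df = st.trials_to_frame(small_batch)
        back = st.trials_from_frame(df)
        for a, b in zip(small_batch, back):
            assert np.allclose(a.baseline.p, b.baseline.p)
            assert a.change == b.change
            assert a.seed == b.seed
            # identical regenerated stimulus
            sa = st.realize_trial(a, grid)
            sb = st.realize_trial(b, grid)
            assert all(np.array_equal(x, y) for x, y in zip(sa.chords, sb.chords))
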