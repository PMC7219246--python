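import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirslat.core import HBO, HBR, default_montage, slice_trials
from nirslat.mapping import (
    ConnectivityMatrix,
    DifferenceMatrix,
    difference_matrix,
    quartile_filter,
    rank_channels,
    select_pairs,
    window_average,
)
from nirslat.preprocess import bandpass_recording, baseline_correct
from tests.conftest import FS, make_trial


def brute_force_quartile(dh, chromophore, q=0.75):
    """Independent oracle for the sign + fourth-quartile filter.

    Walks every entry, keeps the correct sign, and computes the empirical
    CDF of each kept |value| by explicit counting over the kept set.
    """
    n = dh.shape[0]
    kept = []
    for i in range(n):
        for j in range(n):
            v = dh[i, j]
            if (chromophore == HBO and v > 0) or (chromophore == HBR and v < 0):
                kept.append((i, j, abs(v)))
    out = np.zeros_like(dh)
    m = len(kept)
    for i, j, v in kept:
        rank = sum(1 for _, _, w in kept if w <= v)
        if rank / m >= q:
            out[i, j] = v
    return out


class TestWindowAverage:
    def test_constant_value_returns_constant(self):
        t = make_trial({(1, HBO): 2.25}, channels=[1, 2])
        avgs = window_average(t)
        assert avgs.get(1, HBO) == pytest.approx(2.25)
        assert avgs.get(2, HBO) == 0.0

    def test_linear_ramp_averages_to_half(self):
        # ramp 0 -> 1 across exactly the [5, 20) window
        n = 273
        v = np.zeros(n)
        sl = slice(39, 156)
        m = sl.stop - sl.start  # 117 samples
        v[sl] = np.arange(m) / (m - 1)
        t = make_trial({(1, HBO): v}, channels=[1])
        assert window_average(t).get(1, HBO) == pytest.approx(0.5, abs=1 / (2 * m))

    def test_default_window_covers_117_samples(self):
        counter = np.arange(273, dtype=float)
        t = make_trial({(1, HBO): counter}, channels=[1])
        # mean of indices 39..155 inclusive
        assert window_average(t).get(1, HBO) == pytest.approx(np.mean(np.arange(39, 156)))

    def test_out_of_range_window_rejected(self):
        t = make_trial(channels=[1])
        with pytest.raises(ValueError):
            window_average(t, window=(30.0, 40.0))

    def test_empty_window_rejected(self):
        t = make_trial(channels=[1])
        with pytest.raises(ValueError):
            window_average(t, window=(10.0, 10.0))


class TestDifferenceMatrix:
    def _avgs(self, values):
        t = make_trial(
            {(ch, HBO): v for ch, v in values.items()}, channels=list(values)
        )
        return window_average(t)

    def test_pairwise_differences(self):
        dm = difference_matrix(self._avgs({1: 1.0, 2: 2.0, 3: 3.0}), HBO)
        assert dm.entry(1, 3) == pytest.approx(-2.0)
        assert dm.entry(3, 1) == pytest.approx(2.0)

    def test_identical_averages_give_zero_matrix(self):
        dm = difference_matrix(self._avgs({1: 5.0, 2: 5.0, 3: 5.0}), HBO)
        assert np.all(dm.matrix == 0)

    @settings(max_examples=50, deadline=None)
    @given(
        vals=st.lists(
            st.floats(min_value=-10, max_value=10), min_size=2, max_size=6
        )
    )
    def test_antisymmetry(self, vals):
        dm = difference_matrix(
            self._avgs({i + 1: v for i, v in enumerate(vals)}), HBO
        )
        np.testing.assert_allclose(dm.matrix + dm.matrix.T, 0, atol=1e-12)
        np.testing.assert_allclose(np.diag(dm.matrix), 0, atol=1e-12)


class TestQuartileFilter:
    def test_three_channel_case_against_oracle(self):
        # averages (0, 0.1, 0.3): kept positive HbO differences {0.1, 0.2, 0.3}
        # with empirical CDF ranks 1/3, 2/3, 1 -> only 0.3 at (3,1) survives
        t = make_trial({(2, HBO): 0.1, (3, HBO): 0.3}, channels=[1, 2, 3])
        dm = difference_matrix(window_average(t), HBO)
        cm = quartile_filter(dm)
        expected = brute_force_quartile(dm.matrix, HBO)
        np.testing.assert_allclose(cm.matrix, expected, atol=1e-12)
        assert cm.entry(3, 1) == pytest.approx(0.3)
        assert np.count_nonzero(cm.matrix) == 1

    def test_all_equal_kept_values_all_survive(self):
        dh = np.array([[0.0, 0.5, -0.5], [-0.5, 0.0, 0.5], [0.5, -0.5, 0.0]])
        dm = DifferenceMatrix(HBO, (1, 2, 3), dh)
        cm = quartile_filter(dm)
        assert np.count_nonzero(cm.matrix) == 3  # every positive entry, F = 1

    def test_hbr_with_all_positive_differences_is_zero(self):
        dh = np.array([[0.0, 1.0], [-1.0, 0.0]])
        dm = DifferenceMatrix(HBR, (1, 2), np.abs(dh) + np.eye(2) * 0)
        dm.matrix = np.array([[0.0, 2.0], [1.0, 0.0]])  # no negative entries
        with pytest.warns(UserWarning, match="sign filter"):
            cm = quartile_filter(dm)
        assert np.all(cm.matrix == 0)

    def test_invalid_quartile_rejected(self):
        dm = DifferenceMatrix(HBO, (1, 2), np.array([[0.0, 1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            quartile_filter(dm, q=1.5)

    @settings(max_examples=200, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        q=st.sampled_from([0.25, 0.5, 0.75, 0.9]),
        chrom=st.sampled_from([HBO, HBR]),
    )
    def test_matches_brute_force_oracle_on_random_matrices(self, seed, q, chrom):
        rng = np.random.default_rng(seed)
        h = rng.normal(size=5)
        dh = h[:, None] - h[None, :]
        dm = DifferenceMatrix(chrom, tuple(range(1, 6)), dh)
        cm = quartile_filter(dm, q=q)
        np.testing.assert_allclose(
            cm.matrix, brute_force_quartile(dh, chrom, q), atol=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_output_entries_subset_of_absolute_input(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.normal(size=6)
        dh = h[:, None] - h[None, :]
        dm = DifferenceMatrix(HBO, tuple(range(1, 7)), dh)
        cm = quartile_filter(dm)
        nz = cm.matrix[cm.matrix != 0]
        assert set(np.round(nz, 12)).issubset(set(np.round(np.abs(dh).ravel(), 12)))

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_surviving_fraction_bounded(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.normal(size=6)  # distinct values a.s. -> no ties
        dh = h[:, None] - h[None, :]
        dm = DifferenceMatrix(HBO, tuple(range(1, 7)), dh)
        cm = quartile_filter(dm, q=0.75)
        kept = (dh > 0).sum()
        assert np.count_nonzero(cm.matrix) <= np.ceil((1 - 0.75) * kept) + 1


def _rank_input(strengths_by_hand, montage):
    """Build labeled connectivity matrices with given per-channel strengths."""
    mats = []
    n = montage.n_channels
    channels = montage.channel_ids
    for hand, strengths in strengths_by_hand.items():
        m = np.zeros((n, n))
        for ch, s in strengths.items():
            m[channels.index(ch), :] = s / (2 * n)
            m[:, channels.index(ch)] += s / (2 * n)
        mats.append(
            ConnectivityMatrix(chromophore=HBO, channels=channels, matrix=m, hand=hand)
        )
    return mats


class TestRankChannels:
    def test_single_active_pair_ranks_first(self, montage):
        mats = _rank_input({"right": {2: 1.0}, "left": {12: 1.0}}, montage)
        ranking = rank_channels(mats, montage)
        assert ranking.pairs[0] == (2, 12)

    def test_all_zero_scores_tie_broken_by_channel_id(self, montage):
        mats = _rank_input({"right": {}, "left": {}}, montage)
        ranking = rank_channels(mats, montage)
        assert all(s == 0 for s in ranking.scores)
        assert ranking.pairs == list(montage.pairs)

    def test_requires_pair_map(self):
        from nirslat.core import Montage

        m = default_montage(4)
        unpaired = Montage(
            channel_ids=(1, 2, 3, 4),
            hemisphere={1: "L", 2: "L", 3: "R", 4: "R"},
            pair_map={},
        )
        mats = _rank_input({"right": {1: 1.0}}, m)
        with pytest.raises(ValueError, match="pair map"):
            rank_channels(mats, unpaired)

    def test_requires_hand_labels(self, montage):
        mats = _rank_input({"right": {2: 1.0}}, montage)
        mats[0].hand = None
        with pytest.raises(ValueError, match="hand"):
            rank_channels(mats, montage)

    def test_permutation_equivariance(self, montage):
        mats = _rank_input({"right": {2: 3.0, 7: 2.0}, "left": {12: 1.0}}, montage)
        base = rank_channels(mats, montage)
        # relabel channels by swapping the (2,12) and (3,13) pairs
        swap = {2: 3, 3: 2, 12: 13, 13: 12}
        perm = [swap.get(c, c) for c in montage.channel_ids]
        idx = [montage.channel_ids.index(c) for c in perm]
        mats2 = []
        for m in mats:
            mats2.append(
                ConnectivityMatrix(
                    chromophore=m.chromophore,
                    channels=montage.channel_ids,
                    matrix=m.matrix[np.ix_(idx, idx)],
                    hand=m.hand,
                )
            )
        permuted = rank_channels(mats2, montage)
        expected_first = (swap.get(base.pairs[0][0], base.pairs[0][0]),
                          swap.get(base.pairs[0][1], base.pairs[0][1]))
        assert permuted.pairs[0] == expected_first
        assert permuted.scores[0] == pytest.approx(base.scores[0])


class TestMatrixExport:
    def test_text_round_trip(self, tmp_path):
        dh = np.array([[0.0, 1.5, -0.25], [-1.5, 0.0, 2.0], [0.25, -2.0, 0.0]])
        cm = ConnectivityMatrix(HBO, (1, 2, 3), np.abs(dh))
        path = tmp_path / "matrix.tsv"
        from nirslat.mapping import load_matrix_text, save_matrix_text

        save_matrix_text(cm, path)
        channels, matrix = load_matrix_text(path)
        assert channels == (1, 2, 3)
        np.testing.assert_allclose(matrix, cm.matrix)

    def test_heatmap_written(self, tmp_path):
        from nirslat.mapping import plot_matrix

        cm = ConnectivityMatrix(HBO, (1, 2), np.array([[0.0, 1.0], [0.5, 0.0]]))
        path = tmp_path / "matrix.png"
        plot_matrix(cm, path)
        assert path.stat().st_size > 0


class TestSelectPairsEndToEnd:
    def test_recovers_injected_informative_pairs(self, noisy_exec_recording):
        rec = noisy_exec_recording
        trials = [
            baseline_correct(t) for t in slice_trials(bandpass_recording(rec))
        ]
        ranking = select_pairs(trials, rec.montage, top_m=3)
        assert set(ranking.selected) == {(2, 12), (7, 17), (8, 18)}

    def test_single_pair_activation_ranks_first(self):
        from nirslat.synth import NoiseParams, SynthParams, generate_session

        params = SynthParams(
            seed=3,
            informative_left=(2,),
            noise=NoiseParams(white_sigma=0.1),
        )
        rec = generate_session(params, "execution", ["right", "left"] * 5)
        trials = [
            baseline_correct(t) for t in slice_trials(bandpass_recording(rec))
        ]
        ranking = select_pairs(trials, rec.montage, top_m=1)
        assert ranking.pairs[0] == (2, 12)

    def test_scores_non_increasing(self, noisy_exec_recording):
        rec = noisy_exec_recording
        trials = [
            baseline_correct(t) for t in slice_trials(bandpass_recording(rec))
        ]
        ranking = select_pairs(trials, rec.montage)
        assert all(a >= b for a, b in zip(ranking.scores, ranking.scores[1:]))
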