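import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erpcode.encoding import (BITS_PER_SAMPLE, CorruptBitstreamError,
                              EmptyClassError, Bitstream, build_codebook,
                              build_feature_matrices, build_feature_matrix,
                              compression_feature, huffman_decode,
                              huffman_encode, quantize, trial_channel_feature)
from erpcode.preprocess import flag_artifact_trials
from erpcode.wavelet import dwt_decompose, hard_threshold


def optimal_prefix_bits(counts):
    """Exhaustive minimum total bits over all prefix codes (Kraft search)."""
    k = len(counts)
    if k == 1:
        return counts[0]
    best = None
    for lengths in itertools.product(range(1, k), repeat=k):
        if sum(2.0 ** -l for l in lengths) <= 1.0 + 1e-12:
            total = sum(c * l for c, l in zip(counts, lengths))
            best = total if best is None else min(best, total)
    return best


class TestQuantize:
    def _decomp(self, values):
        d = dwt_decompose(np.random.default_rng(0).standard_normal(150))
        t = hard_threshold(d, 0.0)
        t.coeffs = [np.asarray(values, dtype=float)] + \
            [np.zeros(1)] * (len(t.coeffs) - 1)
        return t

    def test_half_away_from_zero(self):
        q = quantize(self._decomp([1.4, -2.5, 0.49]))
        np.testing.assert_array_equal(q.symbols[:3], [1, -3, 0])

    def test_integers_unchanged(self):
        q = quantize(self._decomp([3.0, -7.0, 0.0]))
        np.testing.assert_array_equal(q.symbols[:3], [3, -7, 0])

    def test_error_bounded_by_half_step(self):
        d = hard_threshold(
            dwt_decompose(np.random.default_rng(1).standard_normal(150)), 0.0)
        q = quantize(d, step=0.5)
        err = np.abs(q.symbols * 0.5 - d.flatten())
        assert np.max(err) <= 0.25 + 1e-12

    def test_source_bits_convention(self):
        d = hard_threshold(dwt_decompose(np.zeros(150) + 1.0), 0.0)
        assert quantize(d).source_bits == 150 * BITS_PER_SAMPLE

    def test_non_finite_rejected(self):
        t = self._decomp([np.inf, 1.0])
        with pytest.raises(ValueError):
            quantize(t)


class TestHuffman:
    def test_worked_codebook(self):
        seq = [0, 0, 0, 0, 1, 1, 2, 3]
        cb = build_codebook(seq)
        assert cb.code_lengths == {0: 1, 1: 2, 2: 3, 3: 3}
        assert cb.l_avg == pytest.approx(1.75)

    def test_single_symbol_gets_one_bit(self):
        cb = build_codebook([7] * 10)
        assert cb.codewords == {7: "0"}
        assert cb.l_avg == 1.0

    def test_two_equiprobable_symbols(self):
        cb = build_codebook([0, 1, 0, 1])
        assert sorted(len(w) for w in cb.codewords.values()) == [1, 1]

    def test_prefix_free(self):
        rng = np.random.default_rng(2)
        seq = rng.integers(-20, 20, size=400)
        words = list(build_codebook(seq).codewords.values())
        for a, b in itertools.permutations(words, 2):
            assert not b.startswith(a)

    def test_worked_encode_and_inverse(self):
        seq = [0, 0, 0, 0, 1, 1, 2, 3]
        cb = build_codebook(seq)
        stream = huffman_encode(seq, cb)
        assert stream.n_bits == 14
        np.testing.assert_array_equal(huffman_decode(stream, cb), seq)

    def test_repeated_symbol_stream_length(self):
        cb = build_codebook([5] * 10)
        assert huffman_encode([5] * 10, cb).n_bits == 10

    def test_bits_per_symbol_equals_l_avg(self):
        rng = np.random.default_rng(3)
        seq = rng.integers(-5, 5, size=300)
        cb = build_codebook(seq)
        stream = huffman_encode(seq, cb)
        assert stream.n_bits / len(seq) == pytest.approx(cb.l_avg)

    def test_unknown_symbol_rejected(self):
        cb = build_codebook([1, 2, 2])
        with pytest.raises(KeyError):
            huffman_encode([3], cb)

    def test_truncated_stream_rejected(self):
        seq = [0, 0, 1, 2]
        cb = build_codebook(seq)
        stream = huffman_encode(seq, cb)
        with pytest.raises(CorruptBitstreamError):
            huffman_decode(Bitstream(stream.bits[:-1]), cb)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=1, max_size=300))
    def test_round_trip_identity(self, seq):
        cb = build_codebook(seq)
        np.testing.assert_array_equal(
            huffman_decode(huffman_encode(seq, cb), cb), seq)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(-10, 10), min_size=2, max_size=200))
    def test_entropy_bound(self, seq):
        cb = build_codebook(seq)
        if len(cb.symbols) > 1:
            assert cb.entropy <= cb.l_avg < cb.entropy + 1

    def test_matches_exhaustive_optimal_prefix_search(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            counts = rng.integers(1, 30, size=k)
            seq = np.repeat(np.arange(k), counts)
            cb = build_codebook(seq)
            total = huffman_encode(seq, cb).n_bits
            assert total == optimal_prefix_bits(list(counts))

    def test_deterministic_code_lengths(self):
        seq = [0, 1, 2, 3, 4, 4, 3, 2, 1, 0, 0, 1]
        lengths = [build_codebook(seq).code_lengths for _ in range(5)]
        assert all(l == lengths[0] for l in lengths)


class TestCompressionFeature:
    def test_worked_example(self):
        out = compression_feature(2400, Bitstream("0" * 600))
        assert out.cr == pytest.approx(4.0)
        assert out.f == pytest.approx(25.0)

    def test_incompressible_case(self):
        out = compression_feature(64, Bitstream("1" * 64))
        assert out.cr == 1.0 and out.f == 100.0

    def test_proportionality(self):
        a = compression_feature(1000, Bitstream("0" * 500))
        b = compression_feature(1000, Bitstream("0" * 250))
        assert b.cr == pytest.approx(2 * a.cr)
        assert b.f == pytest.approx(a.f / 2)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            compression_feature(100, Bitstream(""))


class TestFeatureMatrix:
    def test_shapes_per_class(self, small_dataset):
        epochs = small_dataset.to_epochset()
        flag_artifact_trials(epochs)
        mats = build_feature_matrices(epochs)
        assert mats["target"].values.shape == (6, 2)
        assert mats["standard"].values.shape == (14, 2)
        assert np.all(np.isfinite(mats["target"].values))
        assert np.all(mats["target"].values > 0)

    def test_identical_trials_identical_rows(self, small_dataset):
        epochs = small_dataset.to_epochset()
        base = epochs.trials[0]
        for t in epochs.trials:
            t.samples = base.samples.copy()
            t.label = "target"
        flag_artifact_trials(epochs)
        m = build_feature_matrix(epochs, "target")
        assert np.all(m.values == m.values[0])

    def test_flagged_trial_dropped(self, small_dataset):
        epochs = small_dataset.to_epochset()
        target_idx = [i for i, t in enumerate(epochs.trials)
                      if t.label == "target"]
        flag_artifact_trials(epochs)
        before = build_feature_matrix(epochs, "target")
        epochs.trials[target_idx[0]].flags["artifact"] = True
        after = build_feature_matrix(epochs, "target")
        assert after.values.shape[0] == before.values.shape[0] - 1
        np.testing.assert_allclose(after.values, before.values[1:])

    def test_all_flagged_class_rejected(self, small_dataset):
        epochs = small_dataset.to_epochset()
        for t in epochs.trials:
            t.flags["artifact"] = t.label == "target"
        with pytest.raises(EmptyClassError):
            build_feature_matrix(epochs, "target")

    def test_noisier_trials_compress_less(self):
        """Feature direction: adding stronger white noise to a fixed template
        raises the median F across seeds."""
        t = 10.0 * np.exp(-0.5 * ((np.arange(150) - 100) / 8.5) ** 2)
        rng = np.random.default_rng(6)
        medians = []
        for sd in (0.5, 2.0, 8.0):
            feats = [trial_channel_feature(t + sd * rng.standard_normal(150))
                     for _ in range(25)]
            medians.append(np.median(feats))
        assert medians[0] < medians[1] < medians[2]
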