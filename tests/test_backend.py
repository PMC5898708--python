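"""HMM backend: training, grammar decoding, score matrix, SRT extraction."""

import numpy as np
import pytest

import cimodel as cm
from cimodel.backend import ScoreMatrix


def _toy_features(rng, word, n_frames=30, dim=4):
    """Separable toy features: each word is a distinct mean vector."""
    mean = np.zeros(dim)
    mean[word % dim] = 5.0 + word
    return mean + 0.3 * rng.standard_normal((n_frames, dim))


def _toy_material(rng, vocabulary, n_per_word=4):
    out = []
    for w_idx, word in enumerate(vocabulary[0]):
        for _ in range(n_per_word):
            sil = 0.3 * rng.standard_normal((8, 4))
            x = np.concatenate([sil, _toy_features(rng, w_idx), sil])
            out.append((x, [word]))
    return out


@pytest.fixture(scope="module")
def toy_vocab():
    return [[f"w{i}" for i in range(5)]]


@pytest.fixture(scope="module")
def toy_models(toy_vocab):
    rng = np.random.default_rng(0)
    material = _toy_material(rng, toy_vocab)
    return cm.train_word_models(material, toy_vocab), material


class TestTraining:
    def test_deterministic(self, toy_vocab):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        m1 = cm.train_word_models(_toy_material(rng1, toy_vocab), toy_vocab)
        m2 = cm.train_word_models(_toy_material(rng2, toy_vocab), toy_vocab)
        for w in toy_vocab[0]:
            np.testing.assert_array_equal(m1.words[w].means, m2.words[w].means)
            np.testing.assert_array_equal(
                m1.words[w].variances, m2.words[w].variances
            )

    def test_model_count(self, toy_models, toy_vocab):
        models, _ = toy_models
        assert models.n_models == len(toy_vocab[0]) + 1  # + silence

    def test_distinct_word_means(self, toy_models, toy_vocab):
        models, _ = toy_models
        means = [models.words[w].means.mean(axis=0) for w in toy_vocab[0]]
        for i in range(len(means)):
            for j in range(i + 1, len(means)):
                assert np.linalg.norm(means[i] - means[j]) > 0.5

    def test_absent_word_reported(self, toy_vocab):
        rng = np.random.default_rng(1)
        material = [
            (x, t) for x, t in _toy_material(rng, toy_vocab) if t != ["w3"]
        ]
        with pytest.raises(ValueError, match="w3"):
            cm.train_word_models(material, toy_vocab)


class TestRecognition:
    def test_self_decode_high_accuracy(self, toy_models, toy_vocab):
        models, material = toy_models
        pct, decoded = cm.recognize_sentences(models, material, toy_vocab)
        assert pct > 90.0

    def test_output_has_one_word_per_slot(self, toy_models, toy_vocab):
        models, material = toy_models
        _, decoded = cm.recognize_sentences(models, material, toy_vocab)
        assert all(len(d) == len(toy_vocab) for d in decoded)
        assert all(w in toy_vocab[0] for d in decoded for w in d)

    def test_multislot_grammar(self):
        vocab = [[f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)]]
        rng = np.random.default_rng(2)
        material = []
        for i in range(3):
            for j in range(3):
                for _ in range(3):
                    sil = 0.3 * rng.standard_normal((6, 4))
                    x = np.concatenate(
                        [
                            sil,
                            _toy_features(rng, i),
                            _toy_features(rng, j + 3),
                            sil,
                        ]
                    )
                    material.append((x, [vocab[0][i], vocab[1][j]]))
        models = cm.train_word_models(material, vocab)
        pct, decoded = cm.recognize_sentences(models, material, vocab)
        assert pct > 90.0
        assert all(len(d) == 2 for d in decoded)

    def test_dimension_mismatch_rejected(self, toy_models, toy_vocab):
        models, _ = toy_models
        with pytest.raises(ValueError, match="dimensionality"):
            cm.recognize_sentences(
                models, [(np.zeros((10, 7)), ["w0"])], toy_vocab
            )


class TestEstimateSrt:
    def _matrix(self, envelope, grid=None):
        env = np.asarray(envelope, float)
        grid = np.asarray(
            grid if grid is not None else np.arange(len(env)) * 3.0 - 12.0
        )
        return ScoreMatrix(
            snr_grid_db=grid,
            scores_pct=env[None, :],
            word_counts=np.full((1, len(env)), 100),
        )

    def test_linear_interpolation(self):
        est = cm.estimate_srt(self._matrix([10, 20, 30, 40, 60, 80]))
        # crossing between -3 dB (40%) and 0 dB (60%) -> -1.5 dB
        assert est.srt_db == pytest.approx(-1.5)
        assert est.defined and not est.at_grid_floor

    def test_lowest_crossing_pair_used(self):
        # envelope dips back below criterion later; the first crossing counts
        est = cm.estimate_srt(self._matrix([20, 40, 60, 45, 70, 90]))
        assert est.srt_db == pytest.approx(-7.5)

    def test_never_reaches_criterion_undefined(self):
        est = cm.estimate_srt(self._matrix([5, 10, 20, 30, 40, 45]))
        assert not est.defined
        assert np.isnan(est.srt_db)

    def test_all_above_criterion_grid_floor(self):
        est = cm.estimate_srt(self._matrix([100, 100, 100, 100, 100, 100]))
        assert est.at_grid_floor
        assert est.srt_db == pytest.approx(-12.0)

    def test_unsorted_grid_rejected(self):
        m = self._matrix([10, 60, 80], grid=np.array([0.0, -3.0, 3.0]))
        with pytest.raises(ValueError):
            cm.estimate_srt(m)

    def test_envelope_uses_best_training_snr(self):
        scores = np.array([[10.0, 30.0, 70.0], [40.0, 60.0, 20.0]])
        m = ScoreMatrix(
            snr_grid_db=np.array([-3.0, 0.0, 3.0]),
            scores_pct=scores,
            word_counts=np.full((2, 3), 100),
        )
        np.testing.assert_allclose(m.envelope(), [40.0, 60.0, 70.0])
        est = cm.estimate_srt(m)
        assert est.srt_db == pytest.approx(-1.5)


class TestSNRProtocol:
    def test_default_grid(self):
        proto = cm.SNRProtocol()
        grid = np.asarray(proto.snr_grid_db)
        assert grid[0] == -12.0 and grid[-1] == 21.0 and len(grid) == 12
        np.testing.assert_allclose(np.diff(grid), 3.0)
        assert list(proto.train_repetitions) == list(range(7))
        assert proto.test_repetition == 7

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            cm.SNRProtocol(repetitions=1)
        with pytest.raises(ValueError):
            cm.SNRProtocol(snr_grid_db=(0.0, -3.0))
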