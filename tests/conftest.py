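import numpy as np
import pytest

import cimodel as cm


@pytest.fixture(scope="session")
def geometry():
    return cm.CochleaGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    return cm.CochleaGeometry(n_fibers=100)


@pytest.fixture(scope="session")
def single_slot_corpus():
    """1-slot x 10-word x 8-utterance corpus used across the backend tests."""
    return cm.synth_corpus(1, cm.CorpusSpec(n_slots=1, utterances_per_word=8))


@pytest.fixture(scope="session")
def desk_cfg():
    from cimodel.pipeline import desk_config

    return desk_config(seed=1)


@pytest.fixture(scope="session")
def clean_features(desk_cfg, single_slot_corpus, small_geometry):
    """Pre-rendered clean (no masker, no internal noise) sentence features:
    100 training and 500 held-out single-word sentences, balanced over the
    10-word vocabulary.  Shared by the recognizer sanity tests."""
    from cimodel.pipeline import audio_to_raw_ir

    corpus = single_slot_corpus
    profiles = cm.idealized_profiles(small_geometry, 9.0)
    rng = np.random.default_rng(7)

    def render(n, seed0):
        out = []
        for i in range(n):
            word = i % 10
            audio, transcript = corpus.make_sentence(
                [word], [int(rng.integers(0, 8))]
            )
            feats = audio_to_raw_ir(
                audio, desk_cfg, profiles, an_seed=seed0 + i, gain=15.0
            )
            out.append((feats, transcript))
        return out

    return {"train": render(100, 1000), "test": render(500, 50000)}
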