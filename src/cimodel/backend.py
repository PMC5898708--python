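"""Whole-word HMM recognizer backend and SRT extraction.

The backend mirrors an HTK-style matrix-sentence recognizer: one
left-to-right hidden Markov model per word (6 states, one diagonal
Gaussian per state) plus a 3-state silence model.  Training is embedded:
whole-sentence feature matrices are force-aligned against the chain
``silence + word_1 ... word_n + silence`` (flat-started by uniform
segmentation) and the state Gaussians and transition probabilities are
re-estimated from the alignment, iterated to convergence (segmental
k-means / Viterbi training).  Recognition decodes each sentence against
the closed grammar — a fixed number of word slots with the slot
vocabulary in parallel, framed by start and stop silence — so word
boundaries are found automatically and every decoded sentence has
exactly one word per slot.

The speech-reception threshold (SRT) is read off the score matrix of all
training x testing SNR combinations: for every test SNR the envelope
score over training SNRs is taken, and the 50% point is linearly
interpolated between the lowest adjacent test-SNR pair that brackets the
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

LOG_ZERO = -1e30


@dataclass(frozen=True)
class HMMParams:
    states_per_word: int = 6
    silence_states: int = 3
    n_iterations: int = 5
    var_floor_frac: float = 1e-3
    trans_floor: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.states_per_word < 1 or self.silence_states < 1:
            raise ValueError("state counts must be positive")


@dataclass
class WordModel:
    """Left-to-right chain: per-state diagonal Gaussian, self-loop and
    advance log probabilities."""

    name: str
    means: np.ndarray  # (S, D)
    variances: np.ndarray  # (S, D)
    log_self: np.ndarray  # (S,)
    log_adv: np.ndarray  # (S,)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]


@dataclass
class ModelSet:
    words: dict[str, WordModel]
    silence: WordModel
    params: HMMParams

    @property
    def n_models(self) -> int:
        return len(self.words) + 1


@dataclass(frozen=True)
class SNRProtocol:
    """SNR grid and repetition layout of the recognition protocol."""

    snr_grid_db: tuple = tuple(np.arange(-12, 22, 3.0))
    repetitions: int = 8
    n_sentences: int = 120
    words_per_sentence: int = 5

    def __post_init__(self) -> None:
        if self.repetitions < 2:
            raise ValueError("need at least 2 repetitions (train + test)")
        if list(self.snr_grid_db) != sorted(self.snr_grid_db):
            raise ValueError("SNR grid must be sorted ascending")

    @property
    def train_repetitions(self) -> range:
        return range(self.repetitions - 1)

    @property
    def test_repetition(self) -> int:
        return self.repetitions - 1


@dataclass
class ScoreMatrix:
    """Word-correct % for every training x testing SNR combination."""

    snr_grid_db: np.ndarray
    scores_pct: np.ndarray  # (n_train, n_test)
    word_counts: np.ndarray  # words scored per cell

    def envelope(self) -> np.ndarray:
        """Best score over training SNRs, per test SNR."""
        return self.scores_pct.max(axis=0)


@dataclass
class SRTEstimate:
    srt_db: float  # nan when undefined
    criterion_pct: float = 50.0
    defined: bool = True
    at_grid_floor: bool = False


# ---------------------------------------------------------------------------
# Gaussian emission log-likelihoods
# ---------------------------------------------------------------------------

def _stack_states(models: list[WordModel]) -> tuple[np.ndarray, np.ndarray]:
    means = np.concatenate([m.means for m in models])
    variances = np.concatenate([m.variances for m in models])
    return means, variances


def _loglik(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(T, n_states) diagonal-Gaussian log density."""
    D = X.shape[1]
    inv = 1.0 / variances
    const = D * np.log(2 * np.pi) + np.sum(np.log(variances), axis=1)
    quad = (
        (X**2) @ inv.T
        - 2.0 * X @ (means * inv).T
        + np.sum(means**2 * inv, axis=1)
    )
    return -0.5 * (const[None, :] + quad)


# ---------------------------------------------------------------------------
# Viterbi kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _viterbi_chain(logB, log_self, log_adv):
    """Forced alignment through a left-to-right chain (start in state 0,
    end in the last state).  Returns the state path."""
    T, S = logB.shape
    delta = np.full((T, S), LOG_ZERO)
    psi = np.zeros((T, S), dtype=np.int64)
    delta[0, 0] = logB[0, 0]
    for t in range(1, T):
        for s in range(S):
            best = delta[t - 1, s] + log_self[s]
            arg = s
            if s > 0:
                alt = delta[t - 1, s - 1] + log_adv[s - 1]
                if alt > best:
                    best = alt
                    arg = s - 1
            delta[t, s] = best + logB[t, s]
            psi[t, s] = arg
    path = np.zeros(T, dtype=np.int64)
    path[T - 1] = S - 1
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


@njit(cache=True)
def _viterbi_graph(logB, emis_idx, pred_ptr, pred_idx, pred_logp, start_node,
                   final_node):
    """Viterbi over an arbitrary DAG-with-self-loops decode graph.

    ``pred_ptr``/``pred_idx``/``pred_logp`` hold, CSR-style, the incoming
    arcs of every node.  Returns the best node path ending in
    ``final_node``.
    """
    T = logB.shape[0]
    N = emis_idx.shape[0]
    delta = np.full((T, N), LOG_ZERO)
    psi = np.full((T, N), -1, dtype=np.int64)
    delta[0, start_node] = logB[0, emis_idx[start_node]]
    for t in range(1, T):
        for n in range(N):
            best = LOG_ZERO
            arg = -1
            for j in range(pred_ptr[n], pred_ptr[n + 1]):
                p = pred_idx[j]
                v = delta[t - 1, p] + pred_logp[j]
                if v > best:
                    best = v
                    arg = p
            if arg >= 0:
                delta[t, n] = best + logB[t, emis_idx[n]]
                psi[t, n] = arg
    path = np.zeros(T, dtype=np.int64)
    path[T - 1] = final_node
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _chain_of(models: ModelSet, transcript: list[str]) -> list[tuple[str, int]]:
    """(model name, state) pairs of the alignment chain sil + words + sil."""
    chain = [("<sil>", s) for s in range(models.silence.n_states)]
    for w in transcript:
        chain += [(w, s) for s in range(models.words[w].n_states)]
    chain += [("<sil>", s) for s in range(models.silence.n_states)]
    return chain


def train_word_models(
    features: list[tuple[np.ndarray, list[str]]],
    vocabulary: list[list[str]],
    params: HMMParams = HMMParams(),
) -> ModelSet:
    """Embedded Viterbi training of whole-word models on sentence material.

    ``features`` holds (T x D feature matrix, slot-ordered transcript)
    pairs.  Every vocabulary word must occur in the training material;
    absent words are reported in the raised error.
    """
    all_words = [w for slot in vocabulary for w in slot]
    counts = {w: 0 for w in all_words}
    for _, transcript in features:
        for w in transcript:
            if w in counts:
                counts[w] += 1
    absent = sorted(w for w, c in counts.items() if c == 0)
    if absent:
        raise ValueError(f"no training material for words: {absent}")

    D = features[0][0].shape[1]
    pooled = np.concatenate([X for X, _ in features])
    g_mean, g_var = pooled.mean(axis=0), pooled.var(axis=0) + 1e-8
    var_floor = params.var_floor_frac * g_var

    def fresh(name: str, n_states: int) -> WordModel:
        return WordModel(
            name=name,
            means=np.tile(g_mean, (n_states, 1)),
            variances=np.tile(g_var, (n_states, 1)),
            log_self=np.full(n_states, np.log(0.5)),
            log_adv=np.full(n_states, np.log(0.5)),
        )

    models = ModelSet(
        words={w: fresh(w, params.states_per_word) for w in all_words},
        silence=fresh("<sil>", params.silence_states),
        params=params,
    )

    def accumulate(assignments) -> None:
        """Re-estimate Gaussians and transitions from frame->state maps."""
        sums = {}
        for (X, transcript), states in assignments:
            chain = _chain_of(models, transcript)
            for t, ci in enumerate(states):
                key = chain[ci]
                if key not in sums:
                    sums[key] = [0.0, np.zeros(D), np.zeros(D), 0, 0]
                acc = sums[key]
                acc[0] += 1.0
                acc[1] += X[t]
                acc[2] += X[t] ** 2
                if t + 1 < len(states):
                    if states[t + 1] == ci:
                        acc[3] += 1
                    else:
                        acc[4] += 1
        for (name, s), (n, sx, sxx, n_self, n_adv) in sums.items():
            model = models.silence if name == "<sil>" else models.words[name]
            mean = sx / n
            var = np.maximum(sxx / n - mean**2, var_floor)
            model.means[s] = mean
            model.variances[s] = var
            total = n_self + n_adv
            if total > 0:
                p_self = np.clip(
                    n_self / total, params.trans_floor, 1 - params.trans_floor
                )
                model.log_self[s] = np.log(p_self)
                model.log_adv[s] = np.log(1 - p_self)

    # flat start: uniform segmentation of every sentence over its chain
    uniform = []
    for X, transcript in features:
        chain_len = len(_chain_of(models, transcript))
        T = X.shape[0]
        states = np.minimum(
            (np.arange(T) * chain_len) // max(T, 1), chain_len - 1
        )
        uniform.append(((X, transcript), states))
    accumulate(uniform)

    for _ in range(params.n_iterations):
        aligned = []
        for X, transcript in features:
            chain = _chain_of(models, transcript)
            means = np.concatenate(
                [
                    (models.silence if n == "<sil>" else models.words[n]).means[
                        s : s + 1
                    ]
                    for n, s in chain
                ]
            )
            variances = np.concatenate(
                [
                    (models.silence if n == "<sil>" else models.words[n]).variances[
                        s : s + 1
                    ]
                    for n, s in chain
                ]
            )
            log_self = np.array(
                [
                    (models.silence if n == "<sil>" else models.words[n]).log_self[s]
                    for n, s in chain
                ]
            )
            log_adv = np.array(
                [
                    (models.silence if n == "<sil>" else models.words[n]).log_adv[s]
                    for n, s in chain
                ]
            )
            logB = _loglik(X, means, variances)
            path = _viterbi_chain(logB, log_self, log_adv)
            aligned.append(((X, transcript), path))
        accumulate(aligned)
    return models


# ---------------------------------------------------------------------------
# recognition
# ---------------------------------------------------------------------------

@dataclass
class _DecodeGraph:
    emis_means: np.ndarray
    emis_vars: np.ndarray
    emis_idx: np.ndarray
    pred_ptr: np.ndarray
    pred_idx: np.ndarray
    pred_logp: np.ndarray
    start_node: int
    final_node: int
    node_slot: np.ndarray  # -1 for silence nodes
    node_word: np.ndarray  # vocabulary index within the slot


def _build_graph(models: ModelSet, vocabulary: list[list[str]]) -> _DecodeGraph:
    """Compose silence + slot-parallel word chains + silence into one
    decode graph with CSR predecessor arcs."""
    unique = [models.silence] + [
        models.words[w] for slot in vocabulary for w in slot
    ]
    emis_means, emis_vars = _stack_states(unique)
    offsets = {}
    off = 0
    for m in unique:
        offsets[m.name] = off
        off += m.n_states

    nodes_emis, node_slot, node_word = [], [], []
    arcs: list[tuple[int, int, float]] = []  # (src, dst, logp)

    def add_chain(model: WordModel, slot: int, word: int) -> tuple[int, int]:
        first = len(nodes_emis)
        for s in range(model.n_states):
            nodes_emis.append(offsets[model.name] + s)
            node_slot.append(slot)
            node_word.append(word)
            n = len(nodes_emis) - 1
            arcs.append((n, n, float(model.log_self[s])))
            if s > 0:
                arcs.append((n - 1, n, float(model.log_adv[s - 1])))
        return first, len(nodes_emis) - 1

    sil_in_first, sil_in_last = add_chain(models.silence, -1, -1)
    prev_exits = [(sil_in_last, float(models.silence.log_adv[-1]))]
    for slot, words in enumerate(vocabulary):
        exits = []
        for w_idx, w in enumerate(words):
            model = models.words[w]
            first, last = add_chain(model, slot, w_idx)
            for src, logp in prev_exits:
                arcs.append((src, first, logp))
            exits.append((last, float(model.log_adv[-1])))
        prev_exits = exits
    sil_out_first, sil_out_last = add_chain(models.silence, -1, -1)
    for src, logp in prev_exits:
        arcs.append((src, sil_out_first, logp))

    n_nodes = len(nodes_emis)
    by_dst: list[list[tuple[int, float]]] = [[] for _ in range(n_nodes)]
    for src, dst, logp in arcs:
        by_dst[dst].append((src, logp))
    pred_ptr = np.zeros(n_nodes + 1, dtype=np.int64)
    pred_idx, pred_logp = [], []
    for n in range(n_nodes):
        for src, logp in by_dst[n]:
            pred_idx.append(src)
            pred_logp.append(logp)
        pred_ptr[n + 1] = len(pred_idx)
    return _DecodeGraph(
        emis_means=emis_means,
        emis_vars=emis_vars,
        emis_idx=np.array(nodes_emis, dtype=np.int64),
        pred_ptr=pred_ptr,
        pred_idx=np.array(pred_idx, dtype=np.int64),
        pred_logp=np.array(pred_logp),
        start_node=sil_in_first,
        final_node=sil_out_last,
        node_slot=np.array(node_slot, dtype=np.int64),
        node_word=np.array(node_word, dtype=np.int64),
    )


def _decode_sentence(
    graph: _DecodeGraph, X: np.ndarray, n_slots: int
) -> list[int]:
    """Best-path word index per slot for one sentence."""
    logB = _loglik(X, graph.emis_means, graph.emis_vars)
    path = _viterbi_graph(
        logB,
        graph.emis_idx,
        graph.pred_ptr,
        graph.pred_idx,
        graph.pred_logp,
        graph.start_node,
        graph.final_node,
    )
    out = [-1] * n_slots
    for n in path:
        s = graph.node_slot[n]
        if s >= 0 and out[s] < 0:
            out[s] = int(graph.node_word[n])
    return out


def recognize_sentences(
    models: ModelSet,
    sentences: list[tuple[np.ndarray, list[str]]],
    vocabulary: list[list[str]],
) -> tuple[float, list[list[str]]]:
    """Grammar-constrained decoding of whole sentences.

    Returns the word-correct percentage (a word counts as correct when it
    is recognized in its slot) and the decoded transcripts.
    """
    D_model = models.silence.means.shape[1]
    if sentences and sentences[0][0].shape[1] != D_model:
        raise ValueError("feature dimensionality does not match the models")
    graph = _build_graph(models, vocabulary)
    n_slots = len(vocabulary)
    word_index = [{w: i for i, w in enumerate(slot)} for slot in vocabulary]
    correct = total = 0
    decoded_all = []
    for X, transcript in sentences:
        decoded = _decode_sentence(graph, X, n_slots)
        decoded_all.append(
            [vocabulary[s][d] if d >= 0 else "" for s, d in enumerate(decoded)]
        )
        for s, w in enumerate(transcript):
            total += 1
            if decoded[s] == word_index[s].get(w, -2):
                correct += 1
    return (100.0 * correct / max(total, 1)), decoded_all


# ---------------------------------------------------------------------------
# score matrix and SRT
# ---------------------------------------------------------------------------

def run_snr_matrix(
    features_fn,
    vocabulary: list[list[str]],
    protocol: SNRProtocol,
    hmm_params: HMMParams = HMMParams(),
) -> ScoreMatrix:
    """Train at every SNR, test at every SNR, on held-out material.

    ``features_fn(snr_db, repetition)`` must return the sentence feature
    list for one repetition of the corpus at one SNR.  For each training
    SNR, models are trained on all training repetitions at that SNR and
    scored on the held-out repetition at every test SNR.
    """
    grid = np.asarray(protocol.snr_grid_db, dtype=float)
    n = len(grid)
    test_sets = {
        snr: features_fn(snr, protocol.test_repetition) for snr in grid
    }
    scores = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for i, snr_train in enumerate(grid):
        train = []
        for rep in protocol.train_repetitions:
            train.extend(features_fn(snr_train, rep))
        models = train_word_models(train, vocabulary, hmm_params)
        for j, snr_test in enumerate(grid):
            sentences = test_sets[snr_test]
            pct, _ = recognize_sentences(models, sentences, vocabulary)
            scores[i, j] = pct
            counts[i, j] = sum(len(t) for _, t in sentences)
    return ScoreMatrix(snr_grid_db=grid, scores_pct=scores, word_counts=counts)


def estimate_srt(matrix: ScoreMatrix, criterion_pct: float = 50.0) -> SRTEstimate:
    """SRT from the 50% iso-score line of the train x test score matrix.

    The envelope score (best training SNR per test SNR) is scanned from
    the lowest test SNR upward; the SRT is the linear interpolation at the
    criterion between the lowest adjacent pair bracketing it.  If the
    envelope never reaches the criterion the SRT is undefined; if it is
    already at criterion at the grid floor the SRT is the floor, flagged.
    """
    grid = np.asarray(matrix.snr_grid_db, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("SNR grid must be strictly ascending")
    env = matrix.envelope()
    if env[0] >= criterion_pct:
        return SRTEstimate(
            srt_db=float(grid[0]), criterion_pct=criterion_pct, at_grid_floor=True
        )
    for k in range(1, len(grid)):
        if env[k - 1] < criterion_pct <= env[k]:
            frac = (criterion_pct - env[k - 1]) / (env[k] - env[k - 1])
            return SRTEstimate(
                srt_db=float(grid[k - 1] + frac * (grid[k] - grid[k - 1])),
                criterion_pct=criterion_pct,
            )
    return SRTEstimate(srt_db=float("nan"), criterion_pct=criterion_pct, defined=False)
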