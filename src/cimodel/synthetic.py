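"""Synthetic study material: matrix-sentence corpus, speech-shaped noise,
EFI maps and participant tables.

The closed-vocabulary matrix-sentence protocol needs only three
properties from its speech material: a fixed slot structure with a small
closed vocabulary per slot, several acoustically distinct utterances per
word, and utterances of one word that resemble each other more than they
resemble other words.  The corpus generated here therefore uses harmonic
complex tokens — word-specific fundamental frequency and formant-like
spectral-envelope trajectories, perturbed per utterance in pitch,
duration and envelope — rather than recorded speech.  The noise
generator shapes Gaussian noise to the long-term average spectrum of the
corpus, emulating a stationary speech-shaped masker.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile
from scipy.stats import truncnorm

from .geometry import CochleaGeometry
from .spread import EFIMap


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSpec:
    sample_rate: int = 16000
    n_slots: int = 5
    words_per_slot: int = 10
    utterances_per_word: int = 8
    word_duration_s: float = 0.4
    rms: float = 0.05

    def __post_init__(self) -> None:
        if self.words_per_slot < 2 or self.n_slots < 1 or self.utterances_per_word < 2:
            raise ValueError("corpus spec counts out of range")
        if self.sample_rate < 8000:
            raise ValueError("sample_rate must be at least 8 kHz")


@dataclass
class Utterance:
    signal: np.ndarray
    word: str
    slot: int
    word_index: int
    utterance_index: int


@dataclass
class Corpus:
    """Closed-vocabulary multi-slot word corpus."""

    sample_rate: int
    n_slots: int
    vocabulary: list[list[str]]  # per slot
    utterances: list[Utterance]
    spec: CorpusSpec

    def words_in_slot(self, slot: int) -> list[str]:
        return self.vocabulary[slot]

    def utterances_of(self, slot: int, word_index: int) -> list[Utterance]:
        return [
            u for u in self.utterances if u.slot == slot and u.word_index == word_index
        ]

    @property
    def corpus_rms(self) -> float:
        cat = np.concatenate([u.signal for u in self.utterances])
        return float(np.sqrt(np.mean(cat**2)))

    def long_term_spectrum(self, nperseg: int = 512) -> tuple[np.ndarray, np.ndarray]:
        cat = np.concatenate([u.signal for u in self.utterances])
        return sps.welch(cat, fs=self.sample_rate, nperseg=nperseg)

    def make_sentence(
        self,
        word_indices: list[int],
        utt_indices: list[int],
        lead_s: float = 0.1,
        gap_s: float = 0.03,
    ) -> tuple[np.ndarray, list[str]]:
        """Concatenate one utterance per slot with leading/trailing silence.

        Returns the waveform and the slot-ordered transcript.
        """
        if len(word_indices) != self.n_slots or len(utt_indices) != self.n_slots:
            raise ValueError("need one word and utterance index per slot")
        lead = np.zeros(int(lead_s * self.sample_rate))
        gap = np.zeros(int(gap_s * self.sample_rate))
        pieces, transcript = [lead], []
        for s, (wi, ui) in enumerate(zip(word_indices, utt_indices)):
            utts = self.utterances_of(s, wi)
            u = utts[ui % len(utts)]
            pieces.append(u.signal)
            transcript.append(u.word)
            pieces.append(gap if s < self.n_slots - 1 else lead)
        return np.concatenate(pieces), transcript

    def write(self, directory: str) -> None:
        """Write WAV files plus a tab-delimited manifest."""
        os.makedirs(directory, exist_ok=True)
        rows = []
        for u in self.utterances:
            name = f"s{u.slot}_w{u.word_index:02d}_u{u.utterance_index:02d}.wav"
            wavfile.write(
                os.path.join(directory, name),
                self.sample_rate,
                (np.clip(u.signal, -1, 1) * 32767).astype(np.int16),
            )
            rows.append({"path": name, "word": u.word, "slot": u.slot})
        pd.DataFrame(rows).to_csv(
            os.path.join(directory, "manifest.tsv"), sep="\t", index=False
        )


def _word_token(
    spec: CorpusSpec,
    word_rng: np.random.Generator,
    utt_rng: np.random.Generator,
) -> np.ndarray:
    """One utterance: harmonic complex with a word-specific envelope
    trajectory plus per-utterance pitch/duration/envelope jitter."""
    fs = spec.sample_rate
    f0 = word_rng.uniform(90.0, 240.0)
    # two formant-like envelope peaks with word-specific trajectories
    f1 = word_rng.uniform(300.0, 900.0, size=2)  # start, end
    f2 = word_rng.uniform(1200.0, 3200.0, size=2)
    bw1, bw2 = word_rng.uniform(80.0, 150.0), word_rng.uniform(150.0, 300.0)
    tilt_db_oct = word_rng.uniform(-9.0, -3.0)

    f0 *= 1.0 + 0.02 * utt_rng.standard_normal()
    dur = spec.word_duration_s * (1.0 + 0.05 * utt_rng.standard_normal())
    dur = float(np.clip(dur, 0.25 * spec.word_duration_s, 2.0 * spec.word_duration_s))
    f1 = f1 * (1.0 + 0.03 * utt_rng.standard_normal(2))
    f2 = f2 * (1.0 + 0.03 * utt_rng.standard_normal(2))

    n = int(dur * fs)
    t = np.arange(n) / fs
    frac = t / dur
    n_harm = int(min(6000.0, fs / 2 - 200) // f0)
    k = np.arange(1, n_harm + 1)[:, None]
    fk = k * f0  # (n_harm, 1)
    c1 = f1[0] + (f1[1] - f1[0]) * frac  # (n,)
    c2 = f2[0] + (f2[1] - f2[0]) * frac
    env = (
        np.exp(-0.5 * ((fk - c1) / bw1) ** 2)
        + 0.7 * np.exp(-0.5 * ((fk - c2) / bw2) ** 2)
        + 0.01
    )
    env *= (fk / f0) ** (tilt_db_oct / 6.0)  # spectral tilt
    phases = utt_rng.uniform(0, 2 * np.pi, size=(n_harm, 1))
    sig = np.sum(env * np.sin(2 * np.pi * fk * t[None, :] + phases), axis=0)
    ramp = int(0.02 * fs)
    window = np.ones(n)
    window[:ramp] = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp) / ramp)
    window[-ramp:] = window[:ramp][::-1]
    sig *= window
    sig *= spec.rms / max(np.sqrt(np.mean(sig**2)), 1e-12)
    return sig


def synth_corpus(seed: int, spec: CorpusSpec = CorpusSpec()) -> Corpus:
    """Deterministically generate the synthetic matrix corpus."""
    vocabulary = [
        [f"s{s}w{w:02d}" for w in range(spec.words_per_slot)]
        for s in range(spec.n_slots)
    ]
    utterances = []
    for s in range(spec.n_slots):
        for w in range(spec.words_per_slot):
            _, *utt_ss = np.random.SeedSequence(
                [int(seed), 1, s, w]
            ).spawn(1 + spec.utterances_per_word)
            for u in range(spec.utterances_per_word):
                # word-level draws are replayed identically per utterance
                token = _word_token(
                    spec,
                    np.random.default_rng(np.random.SeedSequence([int(seed), 1, s, w])),
                    np.random.default_rng(utt_ss[u]),
                )
                utterances.append(
                    Utterance(
                        signal=token,
                        word=vocabulary[s][w],
                        slot=s,
                        word_index=w,
                        utterance_index=u,
                    )
                )
    return Corpus(
        sample_rate=spec.sample_rate,
        n_slots=spec.n_slots,
        vocabulary=vocabulary,
        utterances=utterances,
        spec=spec,
    )


def synth_noise(corpus: Corpus, duration_s: float, seed: int) -> np.ndarray:
    """Stationary Gaussian noise shaped to the corpus long-term spectrum,
    RMS-matched to the corpus."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not corpus.utterances:
        raise ValueError("corpus has no utterances")
    fs = corpus.sample_rate
    freqs, psd = corpus.long_term_spectrum()
    n = int(duration_s * fs)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA0]))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f_fft = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.interp(f_fft, freqs, np.sqrt(np.maximum(psd, 0.0)))
    noise = np.fft.irfft(spec * shape, n=n)
    noise *= corpus.corpus_rms / np.sqrt(np.mean(noise**2))
    return noise


# ---------------------------------------------------------------------------
# EFI maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticEFISpec:
    """Exponential-decay EFI map with wider apical than basal spread.

    The decay length is interpolated linearly from ``lambda_apical_mm`` at
    electrode 1 to ``lambda_basal_mm`` at the last electrode; diagonal
    entries are inflated by an electrode-impedance term so the fitting
    code's diagonal-exclusion rule is exercised.
    """

    n_electrodes: int = 22
    lambda_apical_mm: float = 4.0
    lambda_basal_mm: float = 2.0
    peak_kohm: float = 2.2
    offset_kohm: float = 0.2
    noise_cv: float = 0.0
    contact_impedance_kohm: float = 5.0

    def __post_init__(self) -> None:
        if self.lambda_apical_mm <= 0 or self.lambda_basal_mm <= 0:
            raise ValueError("decay lengths must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not self.peak_kohm > self.offset_kohm >= 0:
            raise ValueError("need peak > offset >= 0")


def synth_efi(
    spec: SyntheticEFISpec,
    geometry: CochleaGeometry | None = None,
    seed: int = 0,
) -> EFIMap:
    """Generate a synthetic intracochlear potential map."""
    if geometry is None:
        geometry = CochleaGeometry(n_electrodes=spec.n_electrodes)
    if geometry.n_electrodes != spec.n_electrodes:
        raise ValueError("geometry electrode count does not match spec")
    xs = geometry.electrode_positions_mm
    frac = np.arange(spec.n_electrodes) / max(spec.n_electrodes - 1, 1)
    lam = spec.lambda_apical_mm + frac * (spec.lambda_basal_mm - spec.lambda_apical_mm)
    amp = spec.peak_kohm - spec.offset_kohm
    d = np.abs(xs[None, :] - xs[:, None])
    m = amp * np.exp(-d / lam[:, None]) + spec.offset_kohm
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEF1]))
    if spec.noise_cv > 0:
        m = m * (1.0 + spec.noise_cv * rng.standard_normal(m.shape))
        m = np.maximum(m, 0.0)
    # contact impedance dominates the on-diagonal recording
    np.fill_diagonal(m, m.max(axis=1) + spec.contact_impedance_kohm)
    return EFIMap(matrix_kohm=m, electrode_positions_mm=xs)


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

HEARING_AID_CATEGORIES = ("none", "one_side", "both_sides")


def synth_participants(n: int, seed: int) -> pd.DataFrame:
    """Synthetic participant table with the statistical structure of a
    matrix-test CI cohort.

    TRT ~ N(49, 9^2) truncated to [20, 80]; anamnesis fields sampled so the
    auditory-performance score spans roughly [-30, +6] %; measured SRT is a
    fixed linear function of TRT (slope -0.1 dB per TRT %, intercept such
    that the cohort mean is near 2.9 dB) plus 1.5 dB Gaussian noise, making
    the TRT-SRT correlation negative by construction.
    """
    if n < 3:
        raise ValueError("need at least 3 participants")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A]))
    a, b = (20.0 - 49.0) / 9.0, (80.0 - 49.0) / 9.0
    trt = truncnorm.rvs(a, b, loc=49.0, scale=9.0, size=n, random_state=rng)
    dur_mhl = rng.uniform(0.0, 40.0, size=n)
    dur_shl = rng.uniform(0.0, 30.0, size=n)
    ha_use = rng.choice(HEARING_AID_CATEGORIES, size=n)
    b1 = rng.uniform(-5.0, 5.0, size=n)
    b2 = rng.uniform(-3.0, 3.0, size=n)
    delta_s = np.array(
        [{"none": -0.83, "one_side": -0.64, "both_sides": -0.45}[h] for h in ha_use]
    )
    ap = dur_mhl * (-0.23) + dur_shl * delta_s + b1 + b2
    srt = 7.8 - 0.1 * trt + rng.normal(0.0, 1.5, size=n)
    return pd.DataFrame(
        {
            "id": [f"{i + 1:03d}" for i in range(n)],
            "trt": np.round(trt, 1),
            "dur_mhl_years": np.round(dur_mhl, 1),
            "dur_shl_years": np.round(dur_shl, 1),
            "hearing_aid_use": ha_use,
            "b1": np.round(b1, 1),
            "b2": np.round(b2, 1),
            "ap": np.round(ap, 1),
            "measured_srt": np.round(srt, 1),
        }
    )
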