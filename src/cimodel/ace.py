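"""ACE-style n-of-m coding: audio in, electrodogram out.

The advanced combination encoder (ACE) strategy performs a short-time
spectral analysis, reduces the spectrum to 22 channel envelopes, keeps the
``n_maxima`` largest envelopes per frame, compresses them with a
logarithmic loudness-growth function and maps the result onto the
threshold-to-comfort current range of the corresponding electrode.
Channel 1 carries the lowest frequencies and stimulates the most apical
electrode.  Pulses of the selected channels are interleaved within each
frame so that no two electrodes are stimulated simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ACEParams:
    """Parameters of the n-of-m coding strategy.

    The loudness-growth function maps the envelope range
    ``[base_level, saturation_level]`` logarithmically (steepness ``rho``)
    onto ``[current_at_threshold_ua, current_at_comfort_ua]``; envelopes at
    or below base level produce no pulse.
    """

    sample_rate: int = 16000
    n_channels: int = 22
    n_maxima: int = 8
    channel_rate_pps: float = 900.0
    phase_width_s: float = 25e-6
    inter_phase_gap_s: float = 8e-6
    analysis_window: int = 128
    fmin_hz: float = 188.0
    fmax_hz: float = 7938.0
    base_level: float = 1e-3
    saturation_level: float = 0.3
    compression_steepness: float = 416.2
    current_at_threshold_ua: float = 100.0
    current_at_comfort_ua: float = 500.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_maxima <= self.n_channels:
            raise ValueError("need 1 <= n_maxima <= n_channels")
        if self.saturation_level <= self.base_level:
            raise ValueError("saturation_level must exceed base_level")
        if self.current_at_comfort_ua <= self.current_at_threshold_ua:
            raise ValueError("comfort current must exceed threshold current")

    @property
    def hop(self) -> int:
        """Analysis hop in samples; sets the per-channel pulse rate."""
        return max(1, int(round(self.sample_rate / self.channel_rate_pps)))


@dataclass
class Electrodogram:
    """Pulse sequence on the electrode array.

    ``electrodes`` are 0-based (0 = most apical), ``times_s`` strictly
    increasing across the whole array (interleaved stimulation), currents
    in microampere.
    """

    electrodes: np.ndarray
    times_s: np.ndarray
    currents_ua: np.ndarray
    n_electrodes: int
    duration_s: float

    def __post_init__(self) -> None:
        self.electrodes = np.asarray(self.electrodes, dtype=np.int64)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.currents_ua = np.asarray(self.currents_ua, dtype=float)
        if not (len(self.electrodes) == len(self.times_s) == len(self.currents_ua)):
            raise ValueError("ragged electrodogram arrays")

    @property
    def n_pulses(self) -> int:
        return len(self.times_s)

    def pulses_on(self, electrode: int) -> np.ndarray:
        """Pulse times (s) on one electrode."""
        return self.times_s[self.electrodes == electrode]

    def to_table(self) -> np.ndarray:
        """(n_pulses, 3) array: electrode index 1-based, time s, current uA."""
        return np.column_stack(
            [self.electrodes + 1, self.times_s, self.currents_ua]
        )

    @classmethod
    def from_table(
        cls, table: np.ndarray, n_electrodes: int = 22, duration_s: float | None = None
    ) -> "Electrodogram":
        table = np.asarray(table, dtype=float).reshape(-1, 3)
        dur = duration_s if duration_s is not None else (
            float(table[:, 1].max()) if len(table) else 0.0
        )
        return cls(
            electrodes=table[:, 0].astype(np.int64) - 1,
            times_s=table[:, 1],
            currents_ua=table[:, 2],
            n_electrodes=n_electrodes,
            duration_s=dur,
        )


def mix_at_snr(
    speech: np.ndarray,
    noise: np.ndarray,
    snr_db: float,
    offset_seed: int,
    return_components: bool = False,
):
    """Add a random noise passage to the speech at a target SNR.

    A segment of ``noise`` (chosen from ``offset_seed``) is scaled so that
    ``20 log10(RMS_speech / RMS_noise) = snr_db`` and added to the
    unscaled speech.  Different seeds give different temporal passages of
    the same noise.
    """
    speech = np.asarray(speech, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if len(noise) < len(speech):
        raise ValueError("noise must be at least as long as the speech")
    rng = np.random.default_rng(offset_seed)
    start = int(rng.integers(0, len(noise) - len(speech) + 1))
    segment = noise[start : start + len(speech)]
    rms_s = float(np.sqrt(np.mean(speech**2)))
    rms_n = float(np.sqrt(np.mean(segment**2)))
    if rms_s == 0 or rms_n == 0:
        raise ValueError("speech and noise must be non-silent")
    gain = rms_s / (rms_n * 10.0 ** (snr_db / 20.0))
    scaled = gain * segment
    mixed = speech + scaled
    if return_components:
        return mixed, speech, scaled
    return mixed


def _allocate_bins(params: ACEParams) -> list[np.ndarray]:
    """Assign FFT bins to channels: monotone, each channel >= 1 bin,
    boundaries as close to geometric spacing over [fmin, fmax] as the bin
    grid allows (narrow low channels, wide high channels)."""
    nfft = params.analysis_window
    freqs = np.fft.rfftfreq(nfft, d=1.0 / params.sample_rate)
    usable = np.nonzero((freqs >= params.fmin_hz) & (freqs <= params.fmax_hz))[0]
    n_bins, n_ch = len(usable), params.n_channels
    if n_bins < n_ch:
        raise ValueError("not enough FFT bins for the requested channels")
    f_lo, f_hi = freqs[usable[0]], freqs[usable[-1]]
    ideal = f_lo * (f_hi / f_lo) ** (np.arange(1, n_ch) / n_ch)
    bounds = [0]
    for i, f in enumerate(ideal):
        b = int(np.searchsorted(freqs[usable], f))
        b = max(b, bounds[-1] + 1)  # at least one bin per channel
        b = min(b, n_bins - (n_ch - 1 - i))  # leave room for the rest
        bounds.append(b)
    bounds.append(n_bins)
    return [usable[bounds[i] : bounds[i + 1]] for i in range(n_ch)]


def channel_center_frequencies(params: ACEParams) -> np.ndarray:
    """Centre frequency (Hz) of each analysis channel, ascending."""
    freqs = np.fft.rfftfreq(params.analysis_window, d=1.0 / params.sample_rate)
    return np.array([float(np.mean(freqs[b])) for b in _allocate_bins(params)])


def channel_envelopes(audio: np.ndarray, params: ACEParams) -> np.ndarray:
    """Short-time channel envelopes, shape (n_frames, n_channels).

    Hann-windowed FFT of ``analysis_window`` samples every ``hop`` samples;
    the envelope of a channel is the root of the summed bin powers,
    normalized to full-scale amplitude 1.0.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono")
    nwin, hop = params.analysis_window, params.hop
    if len(audio) < nwin:
        audio = np.pad(audio, (0, nwin - len(audio)))
    n_frames = 1 + (len(audio) - nwin) // hop
    window = np.hanning(nwin)
    idx = np.arange(nwin)[None, :] + hop * np.arange(n_frames)[:, None]
    spec = np.fft.rfft(audio[idx] * window, axis=1)
    power = np.abs(spec) ** 2 / (np.sum(window) / 2.0) ** 2
    bins = _allocate_bins(params)
    env = np.empty((n_frames, params.n_channels))
    for c, b in enumerate(bins):
        env[:, c] = np.sqrt(power[:, b].sum(axis=1))
    return env


def loudness_growth(envelope: np.ndarray, params: ACEParams) -> np.ndarray:
    """Map envelopes to stimulation currents (uA) through the logarithmic
    loudness-growth function; envelopes <= base level map to 0 (no pulse)."""
    rho = params.compression_steepness
    u = (envelope - params.base_level) / (params.saturation_level - params.base_level)
    u = np.clip(u, 0.0, 1.0)
    mag = np.log1p(rho * u) / np.log1p(rho)
    current = params.current_at_threshold_ua + mag * (
        params.current_at_comfort_ua - params.current_at_threshold_ua
    )
    return np.where(envelope > params.base_level, current, 0.0)


def ace_encode(audio: np.ndarray, params: ACEParams = ACEParams()) -> Electrodogram:
    """Encode mono audio into an interleaved n-of-m pulse pattern.

    Per analysis frame the ``n_maxima`` largest channel envelopes are
    selected, compressed and emitted as one pulse each, interleaved at
    equal sub-frame offsets in base-to-apex order.
    """
    env = channel_envelopes(audio, params)
    currents = loudness_growth(env, params)
    n_frames = env.shape[0]
    frame_dur = params.hop / params.sample_rate
    electrodes, times, amps = [], [], []
    for k in range(n_frames):
        order = np.argsort(env[k])[::-1][: params.n_maxima]
        # keep only channels that actually exceed base level
        sel = sorted(int(c) for c in order if currents[k, c] > 0)
        slot_dt = frame_dur / params.n_maxima
        # base-to-apex: high-frequency channels first within the frame
        for j, c in enumerate(reversed(sel)):
            electrodes.append(c)  # channel c -> electrode c (apical = low freq)
            times.append(k * frame_dur + j * slot_dt)
            amps.append(currents[k, c])
    duration = max(len(audio) / params.sample_rate, n_frames * frame_dur)
    return Electrodogram(
        electrodes=np.array(electrodes, dtype=np.int64),
        times_s=np.array(times),
        currents_ua=np.array(amps),
        n_electrodes=params.n_channels,
        duration_s=duration,
    )
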