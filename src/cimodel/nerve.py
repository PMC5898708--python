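"""Stochastic leaky integrate-and-fire model of the electrically
stimulated auditory nerve.

Each fiber integrates the spatially spread stimulation current with a
membrane leak; a spike is emitted when the membrane state crosses a
stochastically perturbed threshold.  The stochastic elements are

* threshold perturbation (relative spread): a Gaussian multiplier on the
  threshold, drawn once per inter-spike interval, which makes the
  single-pulse firing probability a sigmoid of current with coefficient
  of variation approximately equal to ``relative_spread``;
* membrane noise: a small Gaussian perturbation of the membrane state,
  modelled as an Ornstein-Uhlenbeck-like component with the membrane
  time constant; for speed its increments are injected in 16-step blocks
  (160 us at the default 10 us step) with the block variance matched so
  the stationary membrane-noise standard deviation is exact — much finer
  than the membrane integration it perturbs;
* absolute refractoriness: a per-fiber dead time drawn from a truncated
  normal distribution;
* relative refractoriness: an exponentially decaying threshold elevation
  after the absolute dead time;
* latency and jitter: the recorded spike time is the crossing time plus a
  fixed conduction latency plus Gaussian jitter.

All randomness is drawn from one seeded generator before the simulation
kernel runs, so identical seeds produce identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_BLOCK_SHIFT = 4  # membrane-noise increment every 2**4 time steps
_BLOCK = 1 << _BLOCK_SHIFT


@dataclass(frozen=True)
class ANParams:
    """Leaky integrate-and-fire fiber parameters.

    ``threshold_current_ua`` is the membrane-state level (uA-equivalent)
    that triggers a spike; with 25 us pulses and a 0.5 ms membrane time
    constant the membrane reaches about 5% of the instantaneous pulse
    current, so a 10 uA threshold places single-pulse thresholds around
    200 uA at the peak of the spread profile — inside the 100-500 uA
    threshold-to-comfort range of the coding strategy.
    """

    membrane_tau_ms: float = 0.5
    threshold_current_ua: float = 10.0
    relative_spread: float = 0.06
    absolute_refractory_mean_ms: float = 0.7
    absolute_refractory_sd_ms: float = 0.1
    relative_refractory_tau_ms: float = 1.3
    relative_refractory_strength: float = 5.0
    latency_mean_ms: float = 0.45
    jitter_sd_ms: float = 0.1
    membrane_noise_sd_ua: float | None = None  # default: relative_spread * threshold / 3
    time_step_s: float = 10e-6

    def __post_init__(self) -> None:
        if min(
            self.membrane_tau_ms,
            self.relative_refractory_tau_ms,
            self.time_step_s,
        ) <= 0:
            raise ValueError("time constants must be positive")
        if self.threshold_current_ua <= 0:
            raise ValueError("threshold must be positive")

    @property
    def membrane_noise_sd(self) -> float:
        if self.membrane_noise_sd_ua is not None:
            return self.membrane_noise_sd_ua
        return self.relative_spread * self.threshold_current_ua / 3.0


@dataclass
class SpikeRaster:
    """Sorted spike times per fiber, with the per-fiber dead times used."""

    spike_times: list[np.ndarray]
    fiber_positions_mm: np.ndarray
    duration_s: float
    absolute_refractory_s: np.ndarray

    @property
    def n_fibers(self) -> int:
        return len(self.spike_times)

    @property
    def total_spikes(self) -> int:
        return sum(len(t) for t in self.spike_times)

    def to_events(self) -> np.ndarray:
        """(n_events, 2) array of (fiber index, spike time s), time-sorted."""
        if self.total_spikes == 0:
            return np.empty((0, 2))
        rows = np.concatenate(
            [
                np.column_stack([np.full(len(t), f, dtype=float), t])
                for f, t in enumerate(self.spike_times)
                if len(t)
            ]
        )
        return rows[np.argsort(rows[:, 1], kind="stable")]


@njit(cache=True)
def _lif_population(
    drive,
    alpha,
    theta,
    noise_blocks,
    thr_mults,
    abs_steps,
    rel_decay,
    elev0,
    out_steps,
    out_counts,
):
    """Deterministic LIF kernel; all random numbers are pre-drawn.

    Per fiber: membrane ``v`` relaxes towards the drive with factor
    ``alpha`` per step, picks up a pre-drawn noise increment at every
    16-step block boundary, and spikes when it exceeds
    ``theta * thr_mult * (1 + elev)`` outside the absolute dead time,
    where ``elev`` is the relative-refractory elevation decaying by
    ``rel_decay`` per step.
    """
    n_fibers, n_steps = drive.shape
    noise_on = noise_blocks.shape[1] > 0
    for f in range(n_fibers):
        v = 0.0
        elev = 0.0
        next_ok = 0
        used = 0
        thr = theta * thr_mults[f, used]
        count = 0
        cap = out_steps.shape[1]
        for s in range(n_steps):
            elev *= rel_decay
            if s < next_ok:
                continue  # membrane clamped at rest during the dead time
            v = alpha * v + (1.0 - alpha) * drive[f, s]
            if noise_on and (s & (_BLOCK - 1)) == 0:
                v += noise_blocks[f, s >> _BLOCK_SHIFT]
            if v >= thr * (1.0 + elev):
                if count < cap:
                    out_steps[f, count] = s
                    count += 1
                v = 0.0
                next_ok = s + abs_steps[f]
                elev = elev0[f]
                if used + 1 < thr_mults.shape[1]:
                    used += 1
                thr = theta * thr_mults[f, used]
        out_counts[f] = count


def simulate_population(
    excitation: np.ndarray,
    params: ANParams,
    seed: int,
    fiber_positions_mm: np.ndarray | None = None,
) -> SpikeRaster:
    """Run the LIF population on a (n_fibers x n_steps) drive matrix.

    The drive is sampled at ``params.time_step_s``.  Spike times are the
    threshold-crossing times plus conduction latency and Gaussian jitter;
    after jitter, spike times are re-sorted and nudged so the per-fiber
    absolute refractory separation is preserved exactly.
    """
    excitation = np.asarray(excitation, dtype=float)
    if excitation.ndim != 2:
        raise ValueError("excitation must be (n_fibers, n_steps)")
    if not np.all(np.isfinite(excitation)):
        raise ValueError("excitation contains non-finite values")
    n_fibers, n_steps = excitation.shape
    dt = params.time_step_s
    alpha = float(np.exp(-dt / (params.membrane_tau_ms * 1e-3)))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xAF]))
    # per-fiber dead times: truncated normal, strictly positive
    t_abs = np.empty(n_fibers)
    for f in range(n_fibers):
        x = -1.0
        while x <= 0:
            x = rng.normal(
                params.absolute_refractory_mean_ms, params.absolute_refractory_sd_ms
            )
        t_abs[f] = x * 1e-3
    abs_steps = np.maximum((t_abs / dt).astype(np.int64), 1)

    cap = max(4, int(np.ceil(n_steps * dt / max(t_abs.min(), 1e-4))) + 2)
    # threshold multiplier per inter-spike interval, pre-drawn
    if params.relative_spread > 0:
        thr_mults = np.maximum(
            1.0 + params.relative_spread * rng.standard_normal((n_fibers, cap + 1)),
            0.1,
        )
    else:
        thr_mults = np.ones((n_fibers, cap + 1))
    # membrane-noise increments, block variance matched to the stationary
    # membrane-noise standard deviation
    noise_sd = params.membrane_noise_sd
    if noise_sd > 0:
        n_blocks = (n_steps >> _BLOCK_SHIFT) + 1
        sd_block = noise_sd * float(np.sqrt(1.0 - alpha ** (2 * _BLOCK)))
        noise_blocks = sd_block * rng.standard_normal((n_fibers, n_blocks))
    else:
        noise_blocks = np.zeros((n_fibers, 0))

    rel_decay = float(np.exp(-dt / (params.relative_refractory_tau_ms * 1e-3)))
    # elevation set at the spike so it decays to the nominal strength by
    # the end of the absolute dead time
    elev0 = params.relative_refractory_strength * np.exp(
        t_abs / (params.relative_refractory_tau_ms * 1e-3)
    )

    out_steps = np.zeros((n_fibers, cap), dtype=np.int64)
    counts = np.zeros(n_fibers, dtype=np.int64)
    _lif_population(
        excitation,
        alpha,
        params.threshold_current_ua,
        noise_blocks,
        thr_mults,
        abs_steps,
        rel_decay,
        elev0,
        out_steps,
        counts,
    )

    latency = params.latency_mean_ms * 1e-3
    jitter = params.jitter_sd_ms * 1e-3
    spike_times: list[np.ndarray] = []
    for f in range(n_fibers):
        t = out_steps[f, : counts[f]] * dt + latency
        if jitter > 0 and len(t):
            t = t + jitter * rng.standard_normal(len(t))
        t = np.sort(np.maximum(t, 0.0))
        # enforce the refractory separation that jitter may have violated
        for i in range(1, len(t)):
            if t[i] < t[i - 1] + t_abs[f]:
                t[i] = t[i - 1] + t_abs[f]
        spike_times.append(t)

    if fiber_positions_mm is None:
        fiber_positions_mm = np.arange(n_fibers, dtype=float)
    duration = n_steps * dt + latency + 5 * jitter
    return SpikeRaster(
        spike_times=spike_times,
        fiber_positions_mm=np.asarray(fiber_positions_mm, float),
        duration_s=duration,
        absolute_refractory_s=t_abs,
    )
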