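"""Internal representation: place-grouped, temporally integrated nerve
activity with forward masking and multiplicative internal noise.

Fibers are collected into 46 contiguous place groups: 22 groups bounded
by the arithmetic midpoints between neighbouring electrodes, plus 12
apical and 12 basal beyond-array groups of 0.75 mm width (the residual
0.25 mm at each end of the 35 mm cochlea is merged into the terminal
groups).  Per-group spike counts in 2 ms frames are smoothed by a leaky
integrator and reduced by a subtractive forward-masking trace, producing
a spectrogram-like matrix of 46 rows at a 500 Hz frame rate whose
amplitudes are calibrated to the 0-50 range.  Internal noise — an
independent Gaussian multiplier with mean 1 on every place-time bin — is
applied before classification and is the model's stand-in for limited
cognitive performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CochleaGeometry
from .nerve import SpikeRaster

FRAME_RATE_HZ = 500.0


@dataclass(frozen=True)
class Grouping:
    """Partition of the cochlear axis into place groups."""

    edges_mm: np.ndarray  # length n_groups + 1, ascending, [0, L]
    group_electrode: np.ndarray  # electrode index per group, -1 beyond array

    @property
    def n_groups(self) -> int:
        return len(self.edges_mm) - 1

    def widths(self) -> np.ndarray:
        return np.diff(self.edges_mm)

    def group_of(self, positions_mm: np.ndarray) -> np.ndarray:
        """Group index of each position; positions at the upper boundary
        belong to the last group."""
        g = np.searchsorted(self.edges_mm, positions_mm, side="right") - 1
        return np.clip(g, 0, self.n_groups - 1)


def build_grouping(
    geometry: CochleaGeometry, expected_groups: int | None = 46
) -> Grouping:
    """Build the place grouping for the standard 22-electrode geometry.

    Raises if the construction does not yield ``expected_groups`` groups
    (pass ``None`` to accept whatever the geometry produces).
    """
    xs = geometry.electrode_positions_mm
    pitch = geometry.electrode_pitch_mm
    # electrode groups: midpoints between neighbours, half a pitch outside
    # the edge electrodes
    inner = (xs[:-1] + xs[1:]) / 2.0
    lo = xs[0] - pitch / 2.0
    hi = xs[-1] + pitch / 2.0
    # beyond-array groups of constant width = pitch; the residual shorter
    # than a full pitch at each cochlear end is merged into the terminal
    # group
    n_apical = int(np.floor(lo / pitch + 1e-9))
    apical_edges = lo - pitch * np.arange(1, n_apical)
    n_basal = int(np.floor((geometry.length_mm - hi) / pitch + 1e-9))
    basal_edges = hi + pitch * np.arange(1, n_basal)
    edges = np.concatenate(
        [[0.0], apical_edges[::-1], [lo], inner, [hi], basal_edges,
         [geometry.length_mm]]
    )
    n_groups = len(edges) - 1
    if expected_groups is not None and n_groups != expected_groups:
        raise ValueError(
            f"geometry yields {n_groups} groups, expected {expected_groups}"
        )
    electrode = np.full(n_groups, -1, dtype=np.int64)
    electrode[n_apical : n_apical + geometry.n_electrodes] = np.arange(
        geometry.n_electrodes
    )
    return Grouping(edges_mm=edges, group_electrode=electrode)


@dataclass(frozen=True)
class IntegrationParams:
    """Temporal integration and forward masking of grouped spike counts.

    ``integration_tau_ms`` is the leaky-integrator smoothing constant,
    ``masking_tau_ms`` the decay of the masker trace accumulated from past
    output, ``masking_strength`` the subtractive weight of that trace, and
    ``gain`` the calibrated scale factor that pins the representation onto
    the 0-50 amplitude range.
    """

    integration_tau_ms: float = 10.0
    masking_tau_ms: float = 100.0
    masking_strength: float = 0.5
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.integration_tau_ms <= 0 or self.masking_tau_ms <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.masking_strength <= 1.0:
            raise ValueError("masking_strength must be in [0, 1]")


@dataclass
class InternalRepresentation:
    """46-row place x time matrix at 500 Hz frame rate."""

    matrix: np.ndarray  # (n_groups, n_frames)
    frame_rate_hz: float = FRAME_RATE_HZ

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def frames(self) -> np.ndarray:
        """(n_frames, n_groups) feature view for the recognizer."""
        return self.matrix.T


def integrate_spikes(
    raster: SpikeRaster,
    grouping: Grouping,
    params: IntegrationParams = IntegrationParams(),
    n_frames: int | None = None,
) -> InternalRepresentation:
    """Temporal integration of grouped spike trains into the IR.

    Per group, the spike counts ``x_k`` in 2 ms frames are first reduced
    by a divisive forward-masking stage,
    ``x'_k = x_k / (1 + s m_k)`` with the masker trace
    ``m_k = max(g m_{k-1}, x_{k-1})`` (decaying peak hold of the preceding
    activity, ``s`` the masking strength), then smoothed along time with a
    leaky integrator (``y_k = b y_{k-1} + (1-b) x'_k``) and multiplied by
    the calibrated gain.  The divisive form suppresses the response to a
    sound that follows recent activity more strongly than the decaying
    integrator remnant of that activity, without deleting low-count
    structure the way a subtractive floor would.
    """
    if raster.duration_s <= 0:
        raise ValueError("raster duration must be positive")
    frame_s = 1.0 / FRAME_RATE_HZ
    if n_frames is None:
        n_frames = max(1, int(np.ceil(raster.duration_s / frame_s)))
    counts = np.zeros((grouping.n_groups, n_frames))
    groups = grouping.group_of(raster.fiber_positions_mm)
    for f, times in enumerate(raster.spike_times):
        if len(times) == 0:
            continue
        k = np.minimum((times / frame_s).astype(np.int64), n_frames - 1)
        np.add.at(counts[groups[f]], k, 1.0)

    b = float(np.exp(-frame_s / (params.integration_tau_ms * 1e-3)))
    g = float(np.exp(-frame_s / (params.masking_tau_ms * 1e-3)))
    out = np.empty_like(counts)
    masker = np.zeros(grouping.n_groups)
    acc = np.zeros(grouping.n_groups)
    for k in range(n_frames):
        if k > 0:
            masker = np.maximum(g * masker, counts[:, k - 1])
        masked = counts[:, k] / (1.0 + params.masking_strength * masker)
        acc = b * acc + (1.0 - b) * masked
        out[:, k] = params.gain * acc
    return InternalRepresentation(matrix=out)


def apply_internal_noise(
    ir: InternalRepresentation, sigma: float, seed: int
) -> InternalRepresentation:
    """Multiply every place-time bin by an independent Gaussian with mean 1
    and standard deviation ``sigma`` (no clipping)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return InternalRepresentation(ir.matrix.copy(), ir.frame_rate_hz)
    rng = np.random.default_rng(seed)
    noise = rng.normal(1.0, sigma, size=ir.matrix.shape)
    return InternalRepresentation(ir.matrix * noise, ir.frame_rate_hz)


def calibrate_gain(raw_irs: list[np.ndarray], target: float = 50.0) -> float:
    """Gain that puts the 99th percentile of the pooled raw (gain = 1)
    IR amplitudes at ``target``.

    ``raw_irs`` should cover at least ~10 s of representative material at
    the reference presentation level.
    """
    pooled = np.concatenate([np.asarray(m).ravel() for m in raw_irs])
    p99 = float(np.percentile(pooled, 99.0))
    if p99 <= 0:
        raise ValueError("calibration material produced a silent representation")
    return target / p99
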