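"""Electric-field spatial spread along the cochlear axis.

Each intracochlear electrode excites the auditory nerve through a spatial
weight profile over the 35 mm axis.  Two pathways produce such profiles:

* idealized, homogeneous arrays: a symmetric double-sided exponential
  ``exp(-|x - x_e| / lambda)`` with a single width parameter ``lambda``
  shared by all electrodes;
* individualized arrays: per-electrode profiles fitted to an electrical
  field imaging (EFI) map — single-sided exponentials with vertical
  offsets fitted to each side of the off-diagonal recordings, a linear
  interpolation across +-0.75 mm around the stimulating contact (whose
  own recording is impedance-dominated and excluded), and exponential
  extrapolation beyond the array.

The full-width-half-maximum (FWHM) of a profile — width of the region
where the curve exceeds half of its absolute maximum, referenced to 0 —
summarizes its spread in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

import numpy as np
from scipy.optimize import OptimizeWarning, brentq, curve_fit

from .geometry import CochleaGeometry

if TYPE_CHECKING:  # pragma: no cover
    from .ace import Electrodogram


@dataclass
class EFIMap:
    """Intracochlear potential map: stimulating x recording electrode, kOhm.

    Row ``e`` holds the voltages recorded on all contacts while stimulating
    electrode ``e``, normalized by the stimulation current.  Diagonal
    entries are dominated by the electrode-tissue impedance and are
    excluded from profile fitting.
    """

    matrix_kohm: np.ndarray
    electrode_positions_mm: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix_kohm, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("EFI map must be a square matrix")
        if not np.all(np.isfinite(m)):
            raise ValueError("EFI map contains non-finite entries")
        if np.any(m < 0):
            raise ValueError("EFI map entries must be non-negative")
        if len(self.electrode_positions_mm) != m.shape[0]:
            raise ValueError("positions do not match map size")
        self.matrix_kohm = m
        self.electrode_positions_mm = np.asarray(self.electrode_positions_mm, float)

    @property
    def n_electrodes(self) -> int:
        return self.matrix_kohm.shape[0]


def read_efi(path) -> EFIMap:
    """Read an EFI map from delimited text.

    The first line is a header ``# unit=ohm`` or ``# unit=kohm``; values in
    ohm are converted to kOhm.  Electrode positions default to the standard
    22-contact geometry.
    """
    with open(path) as fh:
        first = fh.readline().strip()
    unit = "kohm"
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "unit=" in first:
            unit = first.split("unit=")[1].strip().lower()
    m = np.loadtxt(path, skiprows=skip, delimiter="\t")
    if unit in ("ohm", "Ω".lower()):
        m = m / 1000.0
    elif unit != "kohm":
        raise ValueError(f"unknown EFI unit {unit!r}")
    geom = CochleaGeometry(n_electrodes=m.shape[0])
    return EFIMap(m, geom.electrode_positions_mm)


def write_efi(path, efi: EFIMap, unit: str = "kohm") -> None:
    m = efi.matrix_kohm * (1000.0 if unit == "ohm" else 1.0)
    header = f"unit={unit}"
    np.savetxt(path, m, delimiter="\t", header=header)


@dataclass
class SpreadProfile:
    """One electrode's spatial weight curve: two fitted exponential sides
    joined by a linear segment across the interpolation region.

    Each side evaluates as ``A * exp(-|x - peak| / lam) + c``; inside
    ``peak +- interp_halfwidth`` the profile is the straight line between
    the two side values at the region edges.  ``interp_halfwidth = 0``
    yields the idealized double-sided exponential.
    """

    electrode: int
    peak_position_mm: float
    apical_amplitude: float
    apical_lambda_mm: float
    apical_offset: float
    basal_amplitude: float
    basal_lambda_mm: float
    basal_offset: float
    interp_halfwidth_mm: float = 0.0
    mirrored_side: Optional[str] = None  # side filled in from the other one
    degenerate: bool = False
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.apical_lambda_mm <= 0 or self.basal_lambda_mm <= 0:
            raise ValueError("decay lengths must be positive")
        if self.apical_amplitude < 0 or self.basal_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")

    def _side_value(self, x: np.ndarray, apical: bool) -> np.ndarray:
        d = np.abs(x - self.peak_position_mm)
        if apical:
            a, lam, c = self.apical_amplitude, self.apical_lambda_mm, self.apical_offset
        else:
            a, lam, c = self.basal_amplitude, self.basal_lambda_mm, self.basal_offset
        return a * np.exp(-d / lam) + max(c, 0.0)

    def __call__(self, x) -> np.ndarray:
        """Evaluate the composed profile at positions ``x`` (mm)."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.where(
            x < self.peak_position_mm,
            self._side_value(x, apical=True),
            self._side_value(x, apical=False),
        )
        h = self.interp_halfwidth_mm
        if h > 0:
            lo, hi = self.peak_position_mm - h, self.peak_position_mm + h
            va = self._side_value(np.array(lo), apical=True)
            vb = self._side_value(np.array(hi), apical=False)
            inside = (x >= lo) & (x <= hi)
            t = (x[inside] - lo) / (2 * h)
            out[inside] = va + t * (vb - va)
        return float(out[0]) if scalar else out

    @property
    def apex_value(self) -> float:
        """Value at the composed-profile apex (tent maximum)."""
        h = self.interp_halfwidth_mm
        if h == 0:
            return float(self(self.peak_position_mm))
        return float(
            max(
                self._side_value(np.array(self.peak_position_mm - h), True),
                self._side_value(np.array(self.peak_position_mm + h), False),
            )
        )


@dataclass
class SpreadProfileSet:
    """One spread profile per electrode, evaluable anywhere on the axis."""

    profiles: list[SpreadProfile]
    geometry: CochleaGeometry = field(default_factory=CochleaGeometry)

    def __post_init__(self) -> None:
        if len(self.profiles) != self.geometry.n_electrodes:
            raise ValueError("one profile per electrode required")

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, i: int) -> SpreadProfile:
        return self.profiles[i]

    def weight_matrix(self, positions_mm: Optional[np.ndarray] = None) -> np.ndarray:
        """Peak-normalized weights, shape (n_electrodes, n_positions).

        Each profile is divided by its apex value so the idealized and the
        EFI-fitted pathways drive the nerve model on the same scale.
        """
        if positions_mm is None:
            positions_mm = self.geometry.fiber_positions_mm
        w = np.empty((len(self.profiles), len(positions_mm)))
        for e, p in enumerate(self.profiles):
            apex = p.apex_value
            if apex <= 0:
                raise ValueError(f"profile {e} has non-positive apex")
            w[e] = p(positions_mm) / apex
        return w


def idealized_profiles(
    geometry: CochleaGeometry, lambda_mm: float
) -> SpreadProfileSet:
    """Homogeneous array: symmetric double-sided exponential of width
    ``lambda_mm`` (distance from the peak to 1/e of the maximum) on every
    electrode, unit peak, zero offsets."""
    if lambda_mm <= 0:
        raise ValueError("lambda_mm must be positive")
    profiles = [
        SpreadProfile(
            electrode=e,
            peak_position_mm=float(x_e),
            apical_amplitude=1.0,
            apical_lambda_mm=lambda_mm,
            apical_offset=0.0,
            basal_amplitude=1.0,
            basal_lambda_mm=lambda_mm,
            basal_offset=0.0,
            interp_halfwidth_mm=0.0,
        )
        for e, x_e in enumerate(geometry.electrode_positions_mm)
    ]
    return SpreadProfileSet(profiles, geometry)


def _exp_model(d: np.ndarray, a: float, lam: float, c: float) -> np.ndarray:
    return a * np.exp(-d / lam) + c


def _fit_side(d: np.ndarray, v: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Fit ``v = A exp(-d/lam) + c`` by nonlinear least squares.

    Returns (A, lam, c, residual_rms, degenerate).  Initialized from a
    log-linear regression of ``v - min(v)`` against distance.
    """
    c0 = float(v.min())
    y = v - c0
    pos = y > 1e-12 * max(v.max(), 1.0)
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(d[pos], np.log(y[pos]), 1)
        lam0 = -1.0 / slope if slope < 0 else 2.0
        a0 = float(np.exp(intercept))
    else:
        lam0, a0 = 2.0, 0.0
    lam0 = float(np.clip(lam0, 1e-2, 1e3))
    if a0 <= 0 or not np.isfinite(a0):
        # (near-)constant side: the offset absorbs everything
        c_fit = float(v.mean())
        rms = float(np.sqrt(np.mean((v - c_fit) ** 2)))
        return 0.0, lam0, c_fit, rms, True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _exp_model,
                d,
                v,
                p0=[a0, lam0, c0],
                bounds=([0.0, 1e-6, 0.0], [np.inf, 1e4, np.inf]),
                maxfev=20000,
            )
    except RuntimeError:
        c_fit = float(v.mean())
        rms = float(np.sqrt(np.mean((v - c_fit) ** 2)))
        return 0.0, lam0, c_fit, rms, True
    a, lam, c = (float(p) for p in popt)
    rms = float(np.sqrt(np.mean((_exp_model(d, a, lam, c) - v) ** 2)))
    degenerate = a <= 1e-9 * max(v.max(), 1.0)
    return a, lam, c, rms, degenerate


def fit_efi_profiles(efi: EFIMap, geometry: CochleaGeometry) -> SpreadProfileSet:
    """Fit per-electrode spread profiles to an EFI map.

    For every stimulating electrode the off-diagonal recordings apical and
    basal of the contact are fitted separately with an exponential plus
    vertical offset.  Edge electrodes with fewer than 3 recordings on one
    side get that side mirrored from the other and are flagged.  The
    returned profiles interpolate linearly across +-0.75 mm around the
    contact and extrapolate the fitted exponentials beyond the array.
    """
    if efi.n_electrodes != geometry.n_electrodes:
        raise ValueError("EFI map size does not match geometry")
    xs = efi.electrode_positions_mm
    half = geometry.electrode_pitch_mm  # +-0.75 mm interpolation region
    profiles = []
    for e in range(efi.n_electrodes):
        x_e = xs[e]
        row = efi.matrix_kohm[e]
        sides = {}
        rms_parts = []
        for name, mask in (("apical", xs < x_e), ("basal", xs > x_e)):
            mask = mask & (np.arange(len(xs)) != e)
            if mask.sum() >= 3:
                d = np.abs(xs[mask] - x_e)
                a, lam, c, rms, degen = _fit_side(d, row[mask])
                sides[name] = (a, lam, c, rms, degen)
                rms_parts.append(rms)
        mirrored = None
        if "apical" not in sides and "basal" not in sides:
            raise ValueError(f"electrode {e}: no usable side to fit")
        if "apical" not in sides:
            sides["apical"] = sides["basal"]
            mirrored = "apical"
        if "basal" not in sides:
            sides["basal"] = sides["apical"]
            mirrored = "basal"
        (aa, la, ca, _, dga) = sides["apical"]
        (ab, lb, cb, _, dgb) = sides["basal"]
        profiles.append(
            SpreadProfile(
                electrode=e,
                peak_position_mm=float(x_e),
                apical_amplitude=aa,
                apical_lambda_mm=la,
                apical_offset=ca,
                basal_amplitude=ab,
                basal_lambda_mm=lb,
                basal_offset=cb,
                interp_halfwidth_mm=half,
                mirrored_side=mirrored,
                degenerate=dga and dgb,
                residual_rms=float(np.mean(rms_parts)) if rms_parts else 0.0,
            )
        )
    return SpreadProfileSet(profiles, geometry)


def profile_fwhm(
    profile: SpreadProfile, geometry: CochleaGeometry
) -> tuple[float, bool]:
    """Full width at half maximum of the composed profile, in mm.

    The reference level is half of the absolute maximum of the curve
    (offsets included, referenced to 0).  A side that never falls below
    half maximum within the cochlea is clipped at the domain boundary;
    the returned flag is True when either side was clipped.

    Returns
    -------
    (fwhm_mm, clipped)
    """
    lo_dom, hi_dom = 0.0, geometry.length_mm
    grid = np.linspace(lo_dom, hi_dom, 2001)
    # the apex (peak or interpolation-region edge) rarely falls on the
    # grid; include those points so the maximum is exact
    h = profile.interp_halfwidth_mm
    apex_pts = [profile.peak_position_mm - h, profile.peak_position_mm,
                profile.peak_position_mm + h]
    extra = [x for x in apex_pts if lo_dom < x < hi_dom]
    grid = np.unique(np.concatenate([grid, extra])) if extra else grid
    vals = profile(grid)
    vmax = float(vals.max())
    if vmax <= 0:
        raise ValueError("profile maximum must be positive")
    half = vmax / 2.0
    i_peak = int(np.argmax(vals))

    def crossing(lo_i: int, hi_i: int, ascending: bool) -> tuple[float, bool]:
        seg = vals[lo_i : hi_i + 1]
        below = seg < half
        if not below.any():
            return (lo_dom if ascending else hi_dom), True
        if ascending:
            # last below-half point before the peak
            j = lo_i + int(np.nonzero(below)[0][-1])
            a, b = grid[j], grid[j + 1]
        else:
            j = lo_i + int(np.nonzero(below)[0][0])
            a, b = grid[j - 1], grid[j]
        x = brentq(lambda x: float(profile(x)) - half, a, b, xtol=1e-12)
        return float(x), False

    x_lo, clip_lo = crossing(0, i_peak, ascending=True) if i_peak > 0 else (lo_dom, vals[0] >= half)
    x_hi, clip_hi = (
        crossing(i_peak, len(grid) - 1, ascending=False)
        if i_peak < len(grid) - 1
        else (hi_dom, vals[-1] >= half)
    )
    return x_hi - x_lo, bool(clip_lo or clip_hi)


def spread_excitation(
    electrodogram: "Electrodogram",
    profiles: SpreadProfileSet,
    geometry: CochleaGeometry,
    dt_s: float = 10e-6,
    pulse_width_s: float = 25e-6,
) -> np.ndarray:
    """Project an electrodogram through the spread profiles onto the fibers.

    Every pulse of current ``I`` on electrode ``e`` contributes
    ``I * w_e(x_i)`` of drive to fiber ``i`` for the duration of its
    cathodic phase; overlapping contributions add linearly.  The result is
    a dense (n_fibers x n_steps) drive matrix on the nerve-model time grid.
    """
    if profiles.geometry.n_electrodes != geometry.n_electrodes:
        raise ValueError("profile set does not match geometry")
    w = profiles.weight_matrix(geometry.fiber_positions_mm)
    n_steps = int(np.ceil(electrodogram.duration_s / dt_s)) + 1
    n_pulse = max(1, int(round(pulse_width_s / dt_s)))
    step = (electrodogram.times_s / dt_s).astype(np.int64)
    # per-electrode current time series, then one matrix product onto fibers
    series = np.zeros((geometry.n_electrodes, n_steps + n_pulse))
    for k in range(n_pulse):
        np.add.at(
            series, (electrodogram.electrodes, step + k), electrodogram.currents_ua
        )
    return w.T @ series[:, :n_steps]
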