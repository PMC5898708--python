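"""One-dimensional cochlear geometry shared by all model stages.

The cochlea is modelled as a straight 35 mm axis. A 22-contact electrode
array with 0.75 mm pitch sits centred on that axis (electrode 1 is the most
apical contact), and auditory-nerve fibers are spread uniformly along the
full length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CochleaGeometry:
    """Positions of electrodes and nerve fibers on the 1-D cochlear axis.

    Parameters
    ----------
    length_mm:
        Total length of the modelled cochlea in mm.
    n_electrodes:
        Number of intracochlear electrode contacts.
    electrode_pitch_mm:
        Centre-to-centre contact spacing in mm. The array is centred on the
        axis, so electrode 1 (apical) sits at
        ``(length - (n_electrodes - 1) * pitch) / 2``.
    n_fibers:
        Number of modelled auditory-nerve fibers, uniformly distributed over
        ``[0, length_mm]``.
    """

    length_mm: float = 35.0
    n_electrodes: int = 22
    electrode_pitch_mm: float = 0.75
    n_fibers: int = 1000

    electrode_positions_mm: np.ndarray = field(init=False, repr=False)
    fiber_positions_mm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.n_electrodes < 2 or self.n_fibers < 1:
            raise ValueError("invalid geometry parameters")
        span = (self.n_electrodes - 1) * self.electrode_pitch_mm
        if span >= self.length_mm:
            raise ValueError("electrode array does not fit in the cochlea")
        start = (self.length_mm - span) / 2.0
        electrodes = start + self.electrode_pitch_mm * np.arange(self.n_electrodes)
        # uniform fiber grid, cell-centred so no fiber sits exactly on 0 or L
        fibers = (np.arange(self.n_fibers) + 0.5) * (self.length_mm / self.n_fibers)
        object.__setattr__(self, "electrode_positions_mm", electrodes)
        object.__setattr__(self, "fiber_positions_mm", fibers)

    def with_fibers(self, n_fibers: int) -> "CochleaGeometry":
        """Same array layout with a different fiber count (for scaled-down runs)."""
        return CochleaGeometry(
            length_mm=self.length_mm,
            n_electrodes=self.n_electrodes,
            electrode_pitch_mm=self.electrode_pitch_mm,
            n_fibers=n_fibers,
        )


DEFAULT_GEOMETRY = CochleaGeometry()
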