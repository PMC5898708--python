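"""The published 14-participant CI cohort.

Printed per-participant values: text-reception threshold (TRT, % tolerated
sentence coverage), auditory-performance score (AP, %), the three derived
internal-noise standard deviations, and the measured speech-reception
threshold (SRT, dB SNR) in stationary noise.  These numbers are study data
reproduced here so the individualization arithmetic can be validated and
re-run without external files.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # id,   trt,   ap, sigma_trt, sigma_trt_ap, sigma_ap, srt
    ("08", 44.9, -17.6, 0.205, 0.211, 0.216, 2.7),
    ("12", 62.7, -15.8, 0.150, 0.180, 0.211, 2.0),
    ("30", 41.6, 5.4, 0.215, 0.183, 0.150, 6.2),
    ("31", 60.7, -5.8, 0.156, 0.169, 0.182, 0.8),
    ("32", 30.4, 0.7, 0.250, 0.207, 0.164, 6.2),
    ("41", 38.4, -17.0, 0.225, 0.220, 0.214, 4.5),
    ("44", 50.3, -2.6, 0.188, 0.181, 0.173, 4.0),
    ("46", 49.8, 2.6, 0.190, 0.174, 0.158, 2.9),
    ("48", 54.5, -0.7, 0.175, 0.171, 0.168, -0.1),
    ("50", 49.5, -14.8, 0.191, 0.199, 0.208, 1.6),
    ("60", 55.1, -29.5, 0.174, 0.212, 0.250, -0.1),
    ("61", 52.7, 2.2, 0.181, 0.170, 0.159, 1.7),
    ("62", 56.1, -5.0, 0.170, 0.175, 0.180, 4.4),
    ("63", 38.9, -17.0, 0.223, 0.219, 0.214, 3.9),
]

#: Per-participant printed values (no average row).
PUBLISHED_COHORT = pd.DataFrame(
    _ROWS,
    columns=["id", "trt", "ap", "sigma_trt", "sigma_trt_ap", "sigma_ap", "srt"],
)

#: Printed cohort-average row.
PUBLISHED_AVERAGES = {
    "trt": 49.0,
    "ap": -8.2,
    "sigma_trt": 0.193,
    "sigma_trt_ap": 0.191,
    "sigma_ap": 0.190,
    "srt": 2.9,
}

#: Mean spread FWHM (mm) printed in the running text (the full per-
#: participant FWHM set lives in a supplementary data file that is not
#: part of this repository).
PUBLISHED_FWHM_MEAN = {"46": 5.1, "61": 9.8}
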