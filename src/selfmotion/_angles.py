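"""Azimuth conventions and wrapped-angle arithmetic.

Convention used throughout the package: azimuth in degrees, 0 deg is
straight ahead, positive angles to the listener's left (counterclockwise
seen from above), wrapped to (-180, 180].
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def ang_diff_deg(a, b):
    """Shortest signed arc a - b in degrees, in (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
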