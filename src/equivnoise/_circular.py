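"""Circular/axial angle arithmetic in degrees.

Motion directions live on a 360-degree circle, orientations on a
180-degree axial domain.  All helpers take the domain period explicitly so
the same code serves both: mapping an axial angle onto ``2*pi*v/period``
radians is the usual angle-doubling trick.
"""

from __future__ import annotations

import numpy as np

MOTION_PERIOD = 360.0
ORIENTATION_PERIOD = 180.0


def wrap(values, period: float):
    """Wrap angles into ``[0, period)``."""
    return np.mod(values, period)


def signed_offset(values, period: float):
    """Signed deviation from the reference (0 deg), in ``[-period/2, period/2)``."""
    return np.mod(np.asarray(values, dtype=float) + period / 2.0, period) - period / 2.0


def circular_mean_offset(values, period: float, axis=-1):
    """Signed offset of the circular mean from the reference direction.

    Values are mapped to the unit circle (one full cycle == ``period``),
    averaged as vectors, and the resultant angle is mapped back to degrees in
    ``(-period/2, period/2]``.  For axial data (period 180) this is exactly
    the double-angle mean.
    """
    ang = np.asarray(values, dtype=float) * (2.0 * np.pi / period)
    s = np.mean(np.sin(ang), axis=axis)
    c = np.mean(np.cos(ang), axis=axis)
    mean_ang = np.arctan2(s, c)  # (-pi, pi]
    return mean_ang * period / (2.0 * np.pi)
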