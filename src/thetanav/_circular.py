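"""Minimal circular-statistics helpers.

Angles are in radians throughout.  ``wrap`` maps to (-pi, pi], which is the
convention used for reconstruction errors; positions on the route circle
live in [0, 2*pi).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    a = np.mod(np.asarray(angle, dtype=float), TWO_PI)
    a = np.where(a > np.pi, a - TWO_PI, a)
    if np.ndim(angle) == 0:
        return float(a)
    return a


def wrap_positive(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to [0, 2*pi)."""
    a = np.mod(np.asarray(angle, dtype=float), TWO_PI)
    if np.ndim(angle) == 0:
        return float(a)
    return a


def circ_dist(a, b):
    """Signed circular distance a - b, wrapped to (-pi, pi]."""
    return wrap(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def resultant_length(angles, axis=None) -> float | np.ndarray:
    """Mean resultant length R in [0, 1]; 1 means perfect concentration."""
    z = np.exp(1j * np.asarray(angles, dtype=float))
    return np.abs(np.mean(z, axis=axis))


def circ_mean(angles, axis=None):
    """Circular mean direction (angle of the resultant vector)."""
    z = np.exp(1j * np.asarray(angles, dtype=float))
    return np.angle(np.mean(z, axis=axis))
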