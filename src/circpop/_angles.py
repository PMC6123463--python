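"""Circular-angle helpers shared across modules.

Internal convention: radians everywhere; user-facing I/O in degrees.
Angles wrap to [0, 2pi); signed differences wrap to (-pi, pi].
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angle(s) to [0, 2pi)."""
    return np.mod(a, TWO_PI)


def wrap_diff(a):
    """Wrap signed angular difference(s) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), TWO_PI)


def circ_dist(a, b):
    """Shorter-arc absolute distance between angles, in [0, pi]."""
    return np.abs(wrap_diff(np.asarray(a) - np.asarray(b)))


def deg2rad(d):
    return np.deg2rad(d)


def rad2deg(r):
    return np.rad2deg(r)
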