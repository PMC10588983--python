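"""Angle conventions used throughout the package.

All headings and bearings are in degrees, counterclockwise-positive, with
0° along the +x axis of the arena frame.  Wrapped angles live in
(-180, 180]; the wrap point is mapped to +180 so that "facing the arena
center" is unambiguously ±180° relative to an outward (upwind) bearing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "circdist_deg", "unit_vector"]


def wrap_deg(angle_deg):
    """Wrap angles (scalar or array) into the interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = (a + 180.0) % 360.0 - 180.0
    # modular arithmetic maps odd multiples of 180 to -180; fold to +180
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0:
        return float(wrapped)
    return wrapped


def circdist_deg(a_deg, b_deg):
    """Absolute circular distance between two angles, in [0, 180]."""
    return np.abs(wrap_deg(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)))


def unit_vector(angle_deg):
    """Unit vector(s) for heading angle(s); returns shape (..., 2)."""
    rad = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([np.cos(rad), np.sin(rad)], axis=-1)
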