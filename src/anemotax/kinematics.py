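"""Per-frame derived quantities for a single tracked fly.

The quantities the navigation metrics are built from:

* ``r_mm`` — radial distance from the arena center (the suction hole);
* ``norm_index`` — the area-normalized radial index (r / R)².  The area of
  a radial bin grows as r², so equal-width bins are not equal-area;
  squaring the normalized radius makes uniform occupancy of the disk give
  a flat distribution with mean 1/2 (and RMS of r/R equal to 1/√2).
* ``alpha_deg`` — signed angle between the body heading and the local
  upwind direction, in (-180, 180]; 0 = facing upwind, ±180 = facing the
  arena center when the wind blows inward.
* ``dtheta_deg`` / ``ang_vel_dps`` — wrapped per-frame heading change
  (CCW positive) and its unsigned rate;
* ``fwd_speed_mm_s`` — displacement projected onto the body axis (may be
  negative when backing); ``speed_mm_s`` is the unprojected translational
  speed.

Differentiated series use forward first differences with no smoothing;
the first frame of a backward-looking series and the last frame of a
forward-looking one are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import unit_vector, wrap_deg
from .arena import ArenaConfig
from .trackio import FlyTrack

__all__ = [
    "KinematicsSeries",
    "compute_kinematics",
    "radial_index",
    "angle_to_upwind",
    "heading_kinematics",
    "forward_speed",
]


@dataclass
class KinematicsSeries:
    """Per-frame derived series for one fly (NaN where undefined)."""

    t_s: np.ndarray
    r_mm: np.ndarray
    norm_index: np.ndarray
    alpha_deg: np.ndarray
    cos_alpha: np.ndarray
    dtheta_deg: np.ndarray
    ang_vel_dps: np.ndarray
    fwd_speed_mm_s: np.ndarray
    speed_mm_s: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.t_s)


def radial_index(track: FlyTrack, cfg: ArenaConfig) -> tuple[np.ndarray, np.ndarray]:
    """Radial distance and area-normalized index (r/R)² per frame."""
    r = np.hypot(track.x_mm, track.y_mm)
    return r, (r / cfg.radius_mm) ** 2


def angle_to_upwind(track: FlyTrack, cfg: ArenaConfig) -> np.ndarray:
    """Signed angle from body heading to the local upwind bearing.

    With inward airflow (periphery -> central suction) the upwind bearing
    at (x, y) is the outward radial direction atan2(y, x); with reversed
    flow it is the inward radial direction.  alpha = wrap(bearing −
    heading), CCW positive.  Undefined (NaN) at the exact center, where
    the radial bearing is ambiguous, and everywhere when wind is off.
    """
    n = len(track)
    if cfg.wind_mode == "off":
        return np.full(n, np.nan)
    bearing = np.degrees(np.arctan2(track.y_mm, track.x_mm))
    if cfg.wind_mode == "reversed":
        bearing = bearing + 180.0
    alpha = wrap_deg(bearing - track.heading_deg)
    at_center = np.hypot(track.x_mm, track.y_mm) == 0.0
    alpha = np.where(at_center, np.nan, alpha)
    return alpha


def heading_kinematics(track: FlyTrack, cfg: ArenaConfig) -> tuple[np.ndarray, np.ndarray]:
    """Wrapped per-frame heading change and unsigned angular speed.

    ``dtheta[k] = wrap(heading[k] − heading[k−1])``; the first frame is NaN.
    """
    n = len(track)
    dtheta = np.full(n, np.nan)
    if n >= 2:
        dtheta[1:] = wrap_deg(np.diff(track.heading_deg))
    return dtheta, np.abs(dtheta) * cfg.frame_rate_hz


def forward_speed(track: FlyTrack, cfg: ArenaConfig) -> tuple[np.ndarray, np.ndarray]:
    """Projected forward speed and total translational speed (mm/s).

    ``fwd[k]`` projects the frame k -> k+1 displacement onto the heading at
    frame k; the last frame is NaN.
    """
    n = len(track)
    fwd = np.full(n, np.nan)
    total = np.full(n, np.nan)
    if n >= 2:
        disp = np.diff(track.xy, axis=0)
        u = unit_vector(track.heading_deg[:-1])
        fwd[:-1] = np.einsum("ij,ij->i", disp, u) * cfg.frame_rate_hz
        total[:-1] = np.hypot(disp[:, 0], disp[:, 1]) * cfg.frame_rate_hz
    return fwd, total


def compute_kinematics(track: FlyTrack, cfg: ArenaConfig) -> KinematicsSeries:
    """All per-frame derived series for one track."""
    r, norm_index = radial_index(track, cfg)
    alpha = angle_to_upwind(track, cfg)
    dtheta, ang_vel = heading_kinematics(track, cfg)
    fwd, total = forward_speed(track, cfg)
    return KinematicsSeries(
        t_s=track.t_s,
        r_mm=r,
        norm_index=norm_index,
        alpha_deg=alpha,
        cos_alpha=np.cos(np.deg2rad(alpha)),
        dtheta_deg=dtheta,
        ang_vel_dps=ang_vel,
        fwd_speed_mm_s=fwd,
        speed_mm_s=total,
        valid=track.valid.copy(),
    )
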