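"""Trajectory-exclusion rules and analysis gates.

Three rules gate which frames and flies enter the metrics:

* tracking-error filter — a single-frame position step of more than 5 mm
  or a wrapped heading change of more than 180° cannot be real walking and
  marks the surrounding data invalid;
* edge gate — onset-response analyses only use flies at least 3 mm from
  the arena wall, where turning is unconstrained;
* orientation gate — the canonical turning statistic is computed on flies
  initially oriented 90-150° away from upwind (either side), where a
  directed turn is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import wrap_deg
from .arena import ArenaConfig
from .trackio import FlyTrack, TrackSet

__all__ = [
    "FilterReport",
    "flag_tracking_errors",
    "apply_tracking_error_filter",
    "edge_gate",
    "orientation_gate",
    "MAX_JUMP_MM",
    "MAX_TURN_DEG",
    "MIN_WALL_MM",
]

MAX_JUMP_MM = 5.0
MAX_TURN_DEG = 180.0
MIN_WALL_MM = 3.0

#: numerical guard so a heading change of exactly max_turn_deg triggers the
#: rule even when wrapping rounds it a few ulp short of the threshold
TURN_EPS_DEG = 1e-9


@dataclass
class FilterReport:
    """Audit record of what the exclusion rules removed."""

    n_input_frames: int = 0
    n_excluded_error: int = 0
    n_excluded_edge: int = 0
    n_gated_orientation: int = 0
    per_track: dict[str, list[str]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input_frames": self.n_input_frames,
            "n_excluded_error": self.n_excluded_error,
            "n_excluded_edge": self.n_excluded_edge,
            "n_gated_orientation": self.n_gated_orientation,
            "per_track": self.per_track,
        }


def artifact_steps(track: FlyTrack, max_jump_mm: float = MAX_JUMP_MM,
                   max_turn_deg: float = MAX_TURN_DEG) -> np.ndarray:
    """Indices k such that the step from frame k to k+1 is a tracking error.

    A step is an error if the displacement exceeds ``max_jump_mm`` or the
    wrapped heading change reaches ``max_turn_deg`` or more.  A change of
    exactly 180° is sign-ambiguous after wrapping and is treated as an
    artifact trigger.
    """
    if len(track) < 2:
        return np.empty(0, dtype=int)
    dx = np.diff(track.x_mm)
    dy = np.diff(track.y_mm)
    step = np.hypot(dx, dy)
    dh = np.abs(wrap_deg(np.diff(track.heading_deg)))
    bad = (step > max_jump_mm) | (dh >= max_turn_deg - TURN_EPS_DEG)
    return np.flatnonzero(bad)


def flag_tracking_errors(
    track: FlyTrack,
    max_jump_mm: float = MAX_JUMP_MM,
    max_turn_deg: float = MAX_TURN_DEG,
    windows: list[tuple[float, float]] | None = None,
    frame_rate_hz: float | None = None,
) -> FlyTrack:
    """Mark tracking-error frames (and their analysis window) invalid.

    With ``windows=None`` only the two frames bounding each bad step are
    invalidated.  If ``windows`` (list of half-open [start_s, end_s) spans)
    is given, any window containing a bad step is invalidated wholesale —
    the exclusion unit used when a rule says a *trajectory* is excluded
    from an analysis window.

    Returns a copy of the track with updated ``valid`` flags.  Idempotent:
    artifact detection depends only on positions/headings, which are never
    modified.
    """
    out = track.copy()
    bad_steps = artifact_steps(track, max_jump_mm, max_turn_deg)
    if bad_steps.size == 0:
        return out
    out.valid[bad_steps] = False
    out.valid[bad_steps + 1] = False
    if windows:
        if frame_rate_hz is None:
            raise ValueError("frame_rate_hz is required when windows are given")
        bad_t = track.t_s[bad_steps + 1]
        for start_s, end_s in windows:
            if np.any((bad_t >= start_s) & (bad_t < end_s)) or np.any(
                (track.t_s[bad_steps] >= start_s) & (track.t_s[bad_steps] < end_s)
            ):
                in_win = (out.t_s >= start_s) & (out.t_s < end_s)
                out.valid[in_win] = False
    return out


def apply_tracking_error_filter(
    ts: TrackSet,
    max_jump_mm: float = MAX_JUMP_MM,
    max_turn_deg: float = MAX_TURN_DEG,
    windows: list[tuple[float, float]] | None = None,
) -> tuple[TrackSet, FilterReport]:
    """Run :func:`flag_tracking_errors` over a whole TrackSet with a report."""
    report = FilterReport()
    filtered = []
    for tr in ts.tracks:
        report.n_input_frames += len(tr)
        new = flag_tracking_errors(tr, max_jump_mm, max_turn_deg, windows, ts.cfg.frame_rate_hz)
        n_removed = int(np.sum(tr.valid & ~new.valid))
        report.n_excluded_error += n_removed
        if n_removed:
            report.per_track.setdefault(f"{tr.movie_id}/{tr.fly_id}", []).append(
                f"tracking error: {n_removed} frames excluded"
            )
        filtered.append(new)
    return (
        TrackSet(tracks=filtered, cfg=ts.cfg, schedule=ts.schedule, provenance=dict(ts.provenance)),
        report,
    )


def edge_gate(
    track: FlyTrack, t0_s: float, cfg: ArenaConfig, min_wall_mm: float = MIN_WALL_MM
) -> bool:
    """True iff the fly is at least ``min_wall_mm`` from the arena wall at t0.

    Inclusive (``>=``): a fly exactly 3 mm from the wall passes.
    """
    k = track.frame_at(t0_s, cfg.frame_rate_hz)
    r = float(np.hypot(track.x_mm[k], track.y_mm[k]))
    return cfg.radius_mm - r >= min_wall_mm


def orientation_gate(alpha0_deg: float, lo_deg: float = 90.0, hi_deg: float = 150.0) -> bool:
    """True iff the initial angle to upwind lies in the two-sided gate band.

    The band is ``lo <= |alpha0| <= hi`` (default 90-150°), i.e. the fly
    starts roughly broadside-to-downwind so that a turn toward upwind has a
    well-defined direction.
    """
    return lo_deg <= abs(wrap_deg(alpha0_deg)) <= hi_deg
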