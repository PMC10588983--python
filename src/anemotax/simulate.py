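"""Agent-based generator of synthetic arena walking trajectories.

The generator is a correlated random walk on the disk with three
stimulus-coupled behaviors layered on top, emulating the statistical
structure of real recordings in the four-quadrant arena:

* a startle — a transient, largely non-directional burst of turning in
  the first ~10 frames (333 ms) after stimulus onset, present even in
  control genotypes;
* orientation-dependent steering during the stimulus — a turn bias of
  ``upwind_turn_gain * sin(alpha)`` degrees per frame (zero facing up- or
  downwind, maximal broadside) and a forward-speed modulation of
  ``speed_mod_gain * cos(alpha)``;
* post-offset attraction back to the location where the stimulus ended,
  producing elevated return probability after offset.

The functional forms (sin/cos in the upwind angle) are modeling choices:
the minimal smooth forms with the right symmetry, not claims about fly
neural control.  With all gains zero the model is an isotropic correlated
random walk whose long-run occupancy approaches uniformity over the disk.

Trajectories are fully reproducible: identical (params, cfg, schedule)
and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .angles import wrap_deg
from .arena import ArenaConfig, EpochSchedule, effective_onset
from .trackio import FlyTrack, TrackSet

__all__ = ["SimParams", "simulate", "inject_artifacts", "uniform_positions"]

STARTLE_WINDOW_FRAMES = 10
RETURN_PHASE_S = 15.0


@dataclass(frozen=True)
class SimParams:
    """Generator parameters (study-condition defaults).

    Defaults describe a control-like group: ~20 flies filmed for 60 s,
    walking at ~10 mm/s with moderate heading noise, startling at stimulus
    onset but with no directed wind response (all directional gains zero).
    Set ``upwind_turn_gain``/``speed_mod_gain``/``return_gain`` positive to
    emulate lines with memory- or activation-driven anemotaxis.
    """

    n_flies: int = 20
    duration_s: float = 60.0
    base_speed_mm_s: float = 10.0
    base_speed_sd_mm_s: float = 3.0
    heading_noise_deg: float = 6.0  # per-frame turn SD
    upwind_turn_gain: float = 0.0  # deg/frame per unit sin(alpha), during stimulus
    speed_mod_gain: float = 0.0  # mm/s per unit cos(alpha), during stimulus
    startle_gain_deg: float = 15.0  # extra |turn| scale during the startle window
    startle_window_frames: int = STARTLE_WINDOW_FRAMES
    startle_upwind_bias: float = 0.0  # 0 = non-directional, 1 = fully toward upwind
    return_gain: float = 0.0  # deg/frame per unit sin(angle to offset location)
    return_phase_s: float = RETURN_PHASE_S
    wall_mode: str = "turn_away"  # or "reflect"
    artifact_rate: float = 0.0  # expected tracking artifacts per fly per minute
    seed: int = 0

    def __post_init__(self):
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if self.wall_mode not in ("turn_away", "reflect"):
            raise ValueError(f"unknown wall_mode {self.wall_mode!r}")
        for name in ("upwind_turn_gain", "speed_mod_gain", "startle_gain_deg", "return_gain"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def uniform_positions(n: int, cfg: ArenaConfig, seed: int) -> np.ndarray:
    """n points area-uniform over the arena disk, shape (n, 2).

    Sampling r = R·√u with u uniform gives the area-uniform radial law
    under which the mean of (r/R)² is 1/2 and the RMS of r/R is 1/√2 —
    the null against which upwind displacement is interpreted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    r = cfg.radius_mm * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _stimulus_state(t_s: float, events) -> tuple[bool, int, float | None]:
    """(in_stimulus, frames_since_onset_or_-1, most_recent_offset_time)."""
    in_stim = False
    since = -1
    last_offset = None
    for ev, onset in events:
        offset = onset + ev.duration_s
        if onset <= t_s < offset:
            in_stim = True
            since = t_s - onset
        if t_s >= offset:
            last_offset = offset if last_offset is None else max(last_offset, offset)
    return in_stim, since, last_offset


def simulate(
    params: SimParams,
    cfg: ArenaConfig,
    schedule: EpochSchedule,
    movie_id: str = "sim",
) -> TrackSet:
    """Generate one movie's worth of trajectories.

    Discrete-time update at the configured frame rate; flies start
    area-uniform over the disk with uniform headings.  Wind-referenced
    terms (upwind turn bias, speed modulation, startle directionality)
    follow ``cfg.wind_mode`` and are inactive when wind is off; the
    startle burst and post-offset homing act regardless of wind.
    """
    schedule = effective_onset(schedule, cfg)
    events = [(ev, ev.effective_onset_s) for ev in schedule.events]
    fps = cfg.frame_rate_hz
    dt = 1.0 / fps
    n_frames = int(round(params.duration_s * fps))
    n = params.n_flies
    rng = np.random.default_rng(params.seed)

    pos = uniform_positions(n, cfg, int(rng.integers(2**31)))
    heading = rng.uniform(-180.0, 180.0, n)
    heading[heading == -180.0] = 180.0
    base_speed = np.maximum(0.5, rng.normal(params.base_speed_mm_s, params.base_speed_sd_mm_s, n))

    xs = np.empty((n_frames, n))
    ys = np.empty((n_frames, n))
    hs = np.empty((n_frames, n))
    home: np.ndarray | None = None  # per-fly position at the last stimulus offset
    home_offset_t: float | None = None
    wind_on = cfg.wind_mode in ("inward", "reversed")

    for k in range(n_frames):
        t = k * dt
        xs[k] = pos[:, 0]
        ys[k] = pos[:, 1]
        hs[k] = heading

        in_stim, since_onset, last_offset = _stimulus_state(t, events)
        if last_offset is not None and home_offset_t != last_offset:
            # stimulus just ended: remember where each fly was
            home = pos.copy()
            home_offset_t = last_offset

        r = np.hypot(pos[:, 0], pos[:, 1])
        if wind_on:
            bearing = np.degrees(np.arctan2(pos[:, 1], pos[:, 0]))
            if cfg.wind_mode == "reversed":
                bearing = bearing + 180.0
            alpha = wrap_deg(bearing - heading)
            alpha = np.where(r == 0.0, 0.0, alpha)
            sin_a = np.sin(np.deg2rad(alpha))
            cos_a = np.cos(np.deg2rad(alpha))
        else:
            sin_a = np.zeros(n)
            cos_a = np.zeros(n)

        dh = rng.normal(0.0, params.heading_noise_deg, n)
        speed = base_speed.copy()
        if in_stim:
            dh += params.upwind_turn_gain * sin_a
            speed = speed + params.speed_mod_gain * cos_a
            if since_onset < params.startle_window_frames * dt - 1e-9:
                mag = params.startle_gain_deg * np.abs(rng.standard_normal(n))
                toward = np.sign(sin_a)
                toward[toward == 0.0] = 1.0
                rand_dir = rng.choice([-1.0, 1.0], n)
                use_toward = rng.random(n) < params.startle_upwind_bias
                direction = np.where(wind_on & use_toward, toward, rand_dir)
                dh += mag * direction
        if (
            params.return_gain != 0.0
            and home is not None
            and not in_stim
            and t < home_offset_t + params.return_phase_s
        ):
            to_home = home - pos
            d_home = np.hypot(to_home[:, 0], to_home[:, 1])
            home_bearing = np.degrees(np.arctan2(to_home[:, 1], to_home[:, 0]))
            err = np.sin(np.deg2rad(wrap_deg(home_bearing - heading)))
            dh += params.return_gain * np.where(d_home > 1.0, err, 0.0)

        heading = wrap_deg(heading + dh)
        step = (np.maximum(0.0, speed) * dt)[:, None] * np.column_stack(
            [np.cos(np.deg2rad(heading)), np.sin(np.deg2rad(heading))]
        )
        new = pos + step
        r_new = np.hypot(new[:, 0], new[:, 1])
        hit = r_new > cfg.radius_mm
        if np.any(hit):
            nx = pos[hit, 0] / np.maximum(r[hit], 1e-9)
            ny = pos[hit, 1] / np.maximum(r[hit], 1e-9)
            vx = step[hit, 0]
            vy = step[hit, 1]
            vdotn = vx * nx + vy * ny
            rx = vx - 2.0 * vdotn * nx  # specular reflection off the tangent
            ry = vy - 2.0 * vdotn * ny
            heading_hit = np.degrees(np.arctan2(ry, rx))
            heading[hit] = wrap_deg(heading_hit)
            if params.wall_mode == "reflect":
                new[hit, 0] = pos[hit, 0] + rx
                new[hit, 1] = pos[hit, 1] + ry
                # clamp any point still marginally outside
                r_ref = np.hypot(new[hit, 0], new[hit, 1])
                over = r_ref > cfg.radius_mm
                if np.any(over):
                    idx = np.flatnonzero(hit)[over]
                    scale = cfg.radius_mm / r_ref[over]
                    new[idx, 0] *= scale
                    new[idx, 1] *= scale
            else:  # turn_away: stop at the wall this frame, walk off next frame
                new[hit] = pos[hit]
        pos = new

    t_s = np.arange(n_frames) / fps
    tracks = [
        FlyTrack(
            movie_id=movie_id,
            fly_id=f"fly{i:03d}",
            t_s=t_s,
            x_mm=xs[:, i],
            y_mm=ys[:, i],
            heading_deg=hs[:, i],
        )
        for i in range(n)
    ]
    return TrackSet(
        tracks=tracks,
        cfg=cfg,
        schedule=schedule,
        provenance={"simulated": True, "seed": params.seed, "params": params.__dict__.copy()},
    )


def inject_artifacts(ts: TrackSet, params: SimParams, seed: int | None = None) -> TrackSet:
    """Insert tracking artifacts (position jumps and heading flips).

    Artifact frames are Poisson-sampled at ``params.artifact_rate`` per
    fly per minute.  A position jump displaces a single frame by 6-9 mm
    toward the arena center (so it stays in bounds); a heading flip adds
    180° to a single frame — the signature of a tracker body-axis swap.
    Ground-truth artifact frames are recorded in the returned TrackSet's
    ``provenance["artifact_frames"]`` keyed by ``movie_id/fly_id``.
    """
    rng = np.random.default_rng(params.seed + 104729 if seed is None else seed)
    if params.artifact_rate == 0.0:
        return ts
    truth: dict[str, list[int]] = {}
    new_tracks = []
    for tr in ts.tracks:
        tr = tr.copy()
        minutes = (len(tr) / ts.cfg.frame_rate_hz) / 60.0
        n_art = int(rng.poisson(params.artifact_rate * minutes))
        n_art = min(n_art, max(0, (len(tr) - 4) // 4))
        if n_art > 0:
            # keep artifacts isolated so each produces its own bad steps
            frames = rng.choice(np.arange(2, len(tr) - 2, 2), size=n_art, replace=False)
            frames = np.sort(frames)
            for k in frames:
                if rng.random() < 0.5:
                    r = np.hypot(tr.x_mm[k], tr.y_mm[k])
                    jump = rng.uniform(6.0, 9.0)
                    if r > 1e-6:
                        ux, uy = -tr.x_mm[k] / r, -tr.y_mm[k] / r
                    else:
                        ux, uy = 1.0, 0.0
                    tr.x_mm[k] += jump * ux
                    tr.y_mm[k] += jump * uy
                else:
                    # body-axis flip: 180 deg off the previous frame's heading
                    tr.heading_deg[k] = wrap_deg(tr.heading_deg[k - 1] + 180.0)
            truth[f"{tr.movie_id}/{tr.fly_id}"] = [int(k) for k in frames]
        new_tracks.append(tr)
    prov = dict(ts.provenance)
    prov["artifact_frames"] = truth
    return TrackSet(tracks=new_tracks, cfg=ts.cfg, schedule=ts.schedule, provenance=prov)
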