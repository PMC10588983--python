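"""Population-level navigation metrics.

These are the headline statistics of the assay:

* upwind displacement — change of the population mean area-normalized
  radial index (r/R)² relative to its value at stimulus onset;
* mean cosine of the upwind angle — a population orientation index, +1
  when every fly faces upwind, −1 when every fly faces the center;
* cumulative turn at onset — summed wrapped heading change over the first
  10 frames (333 ms) of a stimulus, optionally folded by the sign of the
  initial upwind angle so positive means "toward upwind";
* orientation-binned onset response — any per-fly onset metric smoothed
  against initial upwind angle with a ±30° circular window;
* return probability — fraction of flies that leave their reference
  position by more than 10 mm and come back to within 3 mm within 15 s;
* quadrant preference index and reciprocal averaging for binary odor (or
  LED-quadrant) choice.

Population means are computed per movie first and then across movies by
default (each movie is one replicate); per-fly pooling is available for
trajectory-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import circdist_deg, wrap_deg
from .arena import StimulusEvent
from .filters import MIN_WALL_MM, edge_gate
from .kinematics import compute_kinematics
from .trackio import FlyTrack, TrackSet

__all__ = [
    "ReturnProfile",
    "PreferenceResult",
    "OnsetResponseCurve",
    "upwind_displacement",
    "mean_cos_upwind",
    "cumulative_turn",
    "onset_turn_metrics",
    "binned_onset_response",
    "return_probability",
    "fly_returns",
    "quadrant_of",
    "preference_index",
    "reciprocal_average",
    "learning_rate",
    "AWAY_MM",
    "BACK_MM",
    "RETURN_WINDOW_S",
    "ONSET_WINDOW_FRAMES",
]

AWAY_MM = 10.0
BACK_MM = 3.0
RETURN_WINDOW_S = 15.0
ONSET_WINDOW_FRAMES = 10
BIN_HALFWIDTH_DEG = 30.0


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ReturnProfile:
    """Return probability as a function of the reference time time0."""

    time0_s: np.ndarray
    p_return: np.ndarray
    n_flies: np.ndarray
    away_mm: float = AWAY_MM
    back_mm: float = BACK_MM
    window_s: float = RETURN_WINDOW_S


@dataclass
class PreferenceResult:
    """Quadrant preference index averaged over a test window.

    ``pi`` is signed toward the designated odor-one quadrant pair and lies
    in [−1, 1]; ``pi_t`` is the per-frame series it averages.
    """

    pi: float
    window_s: tuple[float, float]
    pi_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    reciprocal_mean: float | None = None


@dataclass
class OnsetResponseCurve:
    """A per-fly onset metric smoothed against initial angle to upwind."""

    initial_angle_grid_deg: np.ndarray
    metric_mean: np.ndarray
    metric_sem: np.ndarray
    n_per_bin: np.ndarray
    bin_halfwidth_deg: float = BIN_HALFWIDTH_DEG


# ---------------------------------------------------------------------------
# upwind displacement and orientation index


def _norm_index_matrix(tracks: list[FlyTrack], cfg) -> np.ndarray:
    """(n_flies, n_frames) matrix of (r/R)², NaN at invalid frames."""
    n_frames = min(len(tr) for tr in tracks)
    out = np.full((len(tracks), n_frames), np.nan)
    for i, tr in enumerate(tracks):
        k = compute_kinematics(tr, cfg)
        vals = k.norm_index[:n_frames].copy()
        vals[~tr.valid[:n_frames]] = np.nan
        out[i] = vals
    return out


def upwind_displacement(
    ts: TrackSet,
    epoch: StimulusEvent,
    at_s: float | None = None,
    per_fly: bool = False,
):
    """Onset-subtracted population mean of the radial index (r/R)².

    Per movie, Δ(t) = mean over valid flies of (r/R)²(t) minus the same
    mean at the effective stimulus onset; positive Δ means net movement
    upwind (outward).  Returns ``(t_s, delta)`` where ``delta`` has one
    row per movie (or per fly if ``per_fly``).  With ``at_s`` given, also
    returns the per-row endpoint Δ(onset + at_s).

    Raises
    ------
    ValueError
        If no fly has a valid frame at the onset.
    """
    onset = epoch.effective_onset_s
    if onset is None:
        raise ValueError("epoch has no effective onset; resolve the schedule first")
    k_on = ts.cfg.time_to_frame(onset)
    rows = []
    t_ref = None
    groups = [[tr] for tr in ts.tracks] if per_fly else list(ts.by_movie().values())
    for tracks in groups:
        mat = _norm_index_matrix(tracks, ts.cfg)
        if k_on >= mat.shape[1] or np.all(np.isnan(mat[:, k_on])):
            raise ValueError("no valid flies at stimulus onset")
        series = np.nanmean(mat, axis=0)
        rows.append(series - series[k_on])
        if t_ref is None or len(t_ref) > mat.shape[1]:
            t_ref = tracks[0].t_s[: mat.shape[1]]
    n = min(len(r) for r in rows)
    delta = np.vstack([r[:n] for r in rows])
    t_s = t_ref[:n]
    if at_s is None:
        return t_s, delta
    k_end = ts.cfg.time_to_frame(onset + at_s)
    if k_end >= n:
        raise ValueError(f"at_s={at_s} s extends past the recording")
    return t_s, delta, delta[:, k_end]


def mean_cos_upwind(ts: TrackSet, epoch: StimulusEvent | None = None, per_fly: bool = False):
    """Per-frame mean of cos(angle to upwind) over valid flies.

    Returns ``(t_rel_s, series)`` with one row per movie (or fly); times
    are relative to the epoch's effective onset when one is given.
    """
    if ts.cfg.wind_mode == "off":
        raise ValueError("upwind angle is undefined with wind_mode='off'")
    groups = [[tr] for tr in ts.tracks] if per_fly else list(ts.by_movie().values())
    rows = []
    t_ref = None
    for tracks in groups:
        n_frames = min(len(tr) for tr in tracks)
        mat = np.full((len(tracks), n_frames), np.nan)
        for i, tr in enumerate(tracks):
            k = compute_kinematics(tr, ts.cfg)
            vals = k.cos_alpha[:n_frames].copy()
            vals[~tr.valid[:n_frames]] = np.nan
            mat[i] = vals
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmean(mat, axis=0))
        if t_ref is None or len(t_ref) > n_frames:
            t_ref = tracks[0].t_s[:n_frames]
    n = min(len(r) for r in rows)
    t = t_ref[:n]
    if epoch is not None and epoch.effective_onset_s is not None:
        t = t - epoch.effective_onset_s
    return t, np.vstack([r[:n] for r in rows])


# ---------------------------------------------------------------------------
# onset turning statistics


def cumulative_turn(
    track: FlyTrack,
    t0_s: float,
    cfg,
    n_frames: int = ONSET_WINDOW_FRAMES,
) -> dict[str, float]:
    """Summed wrapped heading change over ``n_frames`` steps from t0.

    ``signed_deg`` is the plain CCW-positive sum; ``toward_upwind_deg``
    folds it by the sign of the angle to upwind at t0, so positive values
    mean net rotation toward the upwind bearing regardless of which side
    the fly started on.  A fly exactly facing upwind at onset (alpha = 0)
    has no defined "toward" direction and folds to 0.

    Raises
    ------
    ValueError
        If fewer than ``n_frames`` consecutive valid frames follow t0.
    """
    k0 = track.frame_at(t0_s, cfg.frame_rate_hz)
    k1 = k0 + n_frames
    if k1 >= len(track) or not np.all(track.valid[k0 : k1 + 1]):
        raise ValueError(f"need {n_frames} consecutive valid frames from t0={t0_s} s")
    steps = wrap_deg(np.diff(track.heading_deg[k0 : k1 + 1]))
    signed = float(np.sum(steps))
    kin = compute_kinematics(track, cfg)
    alpha0 = kin.alpha_deg[k0]
    if np.isnan(alpha0):
        raise ValueError("angle to upwind undefined at t0 (wind off or fly at center)")
    toward = signed * float(np.sign(alpha0))
    return {"signed_deg": signed, "toward_upwind_deg": toward, "alpha0_deg": float(alpha0)}


def onset_turn_metrics(
    ts: TrackSet,
    epoch: StimulusEvent,
    n_frames: int = ONSET_WINDOW_FRAMES,
    min_wall_mm: float = MIN_WALL_MM,
    apply_edge_gate: bool = True,
) -> list[dict[str, float]]:
    """Per-fly onset metrics (turn and forward speed) at an epoch onset.

    Applies the edge gate at onset and skips flies with too few valid
    frames; each returned record carries the fly's initial angle to
    upwind, signed and folded cumulative turns, and the mean projected
    forward speed over the onset window.
    """
    onset = epoch.effective_onset_s
    if onset is None:
        raise ValueError("epoch has no effective onset; resolve the schedule first")
    out = []
    for tr in ts.tracks:
        try:
            k0 = tr.frame_at(onset, ts.cfg.frame_rate_hz)
        except IndexError:
            continue
        if apply_edge_gate and not edge_gate(tr, onset, ts.cfg, min_wall_mm):
            continue
        try:
            rec = cumulative_turn(tr, onset, ts.cfg, n_frames)
        except ValueError:
            continue
        kin = compute_kinematics(tr, ts.cfg)
        fwd = kin.fwd_speed_mm_s[k0 : k0 + n_frames]
        rec["fwd_speed_mm_s"] = float(np.nanmean(fwd))
        rec["movie_id"] = tr.movie_id
        rec["fly_id"] = tr.fly_id
        out.append(rec)
    return out


def binned_onset_response(
    records: list[dict[str, float]],
    metric: str = "signed_deg",
    halfwidth_deg: float = BIN_HALFWIDTH_DEG,
    grid_step_deg: float = 10.0,
) -> OnsetResponseCurve:
    """Smooth per-fly onset metrics against initial angle to upwind.

    For each grid angle a in (−180, 180], averages ``metric`` over flies
    whose initial alpha lies within ``halfwidth_deg`` of a (circular
    distance, inclusive).  Empty bins yield NaN mean/SEM and count 0.
    """
    grid = np.arange(-180.0 + grid_step_deg, 180.0 + grid_step_deg / 2, grid_step_deg)
    alphas = np.array([r["alpha0_deg"] for r in records]) if records else np.empty(0)
    values = np.array([r[metric] for r in records]) if records else np.empty(0)
    mean = np.full(len(grid), np.nan)
    sem = np.full(len(grid), np.nan)
    counts = np.zeros(len(grid), dtype=int)
    for i, a in enumerate(grid):
        sel = circdist_deg(alphas, a) <= halfwidth_deg
        n = int(np.sum(sel))
        counts[i] = n
        if n:
            mean[i] = float(np.mean(values[sel]))
            if n > 1:
                sem[i] = float(np.std(values[sel], ddof=1) / np.sqrt(n))
    return OnsetResponseCurve(
        initial_angle_grid_deg=grid,
        metric_mean=mean,
        metric_sem=sem,
        n_per_bin=counts,
        bin_halfwidth_deg=halfwidth_deg,
    )


_METRIC_KEYS = {
    "cumulative_turn": "signed_deg",
    "cumulative_turn_toward_upwind": "toward_upwind_deg",
    "forward_speed": "fwd_speed_mm_s",
}


def onset_response_curve(
    ts: TrackSet,
    epoch: StimulusEvent,
    metric: str = "cumulative_turn",
    halfwidth_deg: float = BIN_HALFWIDTH_DEG,
    n_frames: int = ONSET_WINDOW_FRAMES,
    **kwargs,
) -> OnsetResponseCurve:
    """End-to-end orientation-binned onset response for a TrackSet.

    ``metric`` is one of ``cumulative_turn`` (signed),
    ``cumulative_turn_toward_upwind`` (folded) or ``forward_speed``.
    """
    if metric not in _METRIC_KEYS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_KEYS)}")
    records = onset_turn_metrics(ts, epoch, n_frames=n_frames, **kwargs)
    return binned_onset_response(records, _METRIC_KEYS[metric], halfwidth_deg)


# ---------------------------------------------------------------------------
# return probability


def fly_returns(
    track: FlyTrack,
    k0: int,
    window_frames: int,
    away_mm: float = AWAY_MM,
    back_mm: float = BACK_MM,
) -> bool:
    """Did the fly leave p(k0) by > ``away_mm`` and come back within the window?

    Both the excursion and the re-entry (distance <= ``back_mm``) must
    happen within the ``window_frames`` frames after k0, excursion first.
    """
    p0 = track.xy[k0]
    seg = track.xy[k0 + 1 : k0 + 1 + window_frames]
    if len(seg) == 0:
        return False
    d = np.hypot(seg[:, 0] - p0[0], seg[:, 1] - p0[1])
    out = d > away_mm
    if not out.any():
        return False
    first_out = int(np.argmax(out))
    return bool(np.any(d[first_out + 1 :] <= back_mm))


def return_probability(
    ts: TrackSet,
    away_mm: float = AWAY_MM,
    back_mm: float = BACK_MM,
    window_s: float = RETURN_WINDOW_S,
    grid_step_frames: int = 1,
) -> ReturnProfile:
    """Fraction of flies revisiting their time0 position, per time0.

    time0 runs on the frame grid over [0, movie_length − window] (0-45 s
    for a 60-s movie with the default 15-s window); a fly counts as
    returning at time0 if it moves more than ``away_mm`` from its time0
    position and later comes back to within ``back_mm`` of it, both within
    ``window_s``.  Flies whose time0 frame is invalid are excluded from
    that time0's denominator.
    """
    fps = ts.cfg.frame_rate_hz
    wf = int(round(window_s * fps))
    n_frames = min(len(tr) for tr in ts.tracks) if ts.tracks else 0
    last_k0 = n_frames - 1 - wf
    if last_k0 < 0:
        raise ValueError(f"window of {window_s} s longer than the {n_frames / fps:.1f}-s movie")
    k0s = np.arange(0, last_k0 + 1, grid_step_frames)
    returned = np.zeros(len(k0s))
    counted = np.zeros(len(k0s))
    for tr in ts.tracks:
        xy = tr.xy
        for j, k0 in enumerate(k0s):
            if not tr.valid[k0]:
                continue
            counted[j] += 1
            seg = xy[k0 + 1 : k0 + 1 + wf]
            d = np.hypot(seg[:, 0] - xy[k0, 0], seg[:, 1] - xy[k0, 1])
            out = d > away_mm
            if out.any() and np.any(d[int(np.argmax(out)) + 1 :] <= back_mm):
                returned[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(counted > 0, returned / np.maximum(counted, 1), np.nan)
    return ReturnProfile(
        time0_s=k0s / fps,
        p_return=p,
        n_flies=counted.astype(int),
        away_mm=away_mm,
        back_mm=back_mm,
        window_s=window_s,
    )


# ---------------------------------------------------------------------------
# quadrant preference


def quadrant_of(x_mm, y_mm) -> np.ndarray:
    """Quadrant index 0-3, counterclockwise from the sector centered on +x.

    Quadrants are the four 90° sectors delimited by the arena diagonals:
    sector 0 spans polar angles [−45°, 45°), sector 1 [45°, 135°), etc.
    """
    ang = np.degrees(np.arctan2(np.asarray(y_mm, dtype=float), np.asarray(x_mm, dtype=float)))
    return (np.floor((ang + 45.0) / 90.0).astype(int)) % 4


def preference_index(
    ts: TrackSet,
    odor_one_quadrants: tuple[int, int] = (0, 2),
    test_window_s: tuple[float, float] | None = None,
) -> PreferenceResult:
    """Quadrant preference index over a test window.

    Per frame, PI(t) = (N in the odor-one diagonal pair − N in the other
    pair) / N_total over flies with valid positions; the result is the
    mean of PI(t) over the window (default: the final 30 s of the
    recording, the standard test read-out).  The same computation serves
    LED-quadrant preference.
    """
    if set(odor_one_quadrants) not in ({0, 2}, {1, 3}):
        raise ValueError("odor_one_quadrants must be a diagonal pair: (0,2) or (1,3)")
    n_frames = min(len(tr) for tr in ts.tracks)
    t = ts.tracks[0].t_s[:n_frames]
    if test_window_s is None:
        test_window_s = (max(0.0, t[-1] - 30.0 + ts.cfg.frame_dt_s), t[-1] + ts.cfg.frame_dt_s)
    in_one = np.zeros(n_frames)
    total = np.zeros(n_frames)
    for tr in ts.tracks:
        q = quadrant_of(tr.x_mm[:n_frames], tr.y_mm[:n_frames])
        v = tr.valid[:n_frames]
        in_one += v & np.isin(q, odor_one_quadrants)
        total += v
    if not np.any(total > 0):
        raise ValueError("no valid flies in any frame")
    with np.errstate(invalid="ignore"):
        pi_t = np.where(total > 0, (2 * in_one - total) / np.maximum(total, 1), np.nan)
    sel = (t >= test_window_s[0]) & (t < test_window_s[1])
    if not sel.any():
        raise ValueError("test window contains no frames")
    return PreferenceResult(
        pi=float(np.nanmean(pi_t[sel])),
        window_s=(float(test_window_s[0]), float(test_window_s[1])),
        pi_t=pi_t,
        t_s=t,
    )


def reciprocal_average(pi_a: PreferenceResult, pi_b: PreferenceResult) -> PreferenceResult:
    """Average reciprocal experiments, expressed toward the trained odor.

    ``pi_a`` comes from the experiment where the trained (CS+) odor fills
    the designated odor-one quadrants; ``pi_b`` from the reciprocal
    experiment with odor roles swapped, *still signed toward the same
    physical quadrant pair*.  The CS+-aligned mean is (pi_a − pi_b) / 2,
    which cancels any static position bias common to both runs.
    """
    if pi_a.window_s != pi_b.window_s:
        raise ValueError(f"mismatched test windows: {pi_a.window_s} vs {pi_b.window_s}")
    mean = (pi_a.pi - pi_b.pi) / 2.0
    return PreferenceResult(pi=mean, window_s=pi_a.window_s, reciprocal_mean=mean)


def learning_rate(resp_after_1: float, resp_peak_9x: float) -> float:
    """Response after a single training over the peak response after 9x.

    Undefined for a zero peak response.
    """
    if resp_peak_9x == 0:
        raise ZeroDivisionError("peak response is zero; learning rate undefined")
    return resp_after_1 / resp_peak_9x
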