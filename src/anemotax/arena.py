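"""Arena geometry, time-axis conventions, and stimulus-schedule bookkeeping.

The rig is a circular four-quadrant olfactometer: air enters through four
peripheral arms and is pulled out through a central suction hole, so the
local wind direction at any point is radial.  ``ArenaConfig`` captures the
geometry and flow configuration; ``EpochSchedule`` holds valve/LED events
and their *effective* onsets (odor reaches the flies ~3.5 s after the
solenoid valves switch, light is instantaneous).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import yaml

__all__ = [
    "ArenaConfig",
    "StimulusEvent",
    "EpochSchedule",
    "ConfigError",
    "validate_config",
    "frames_to_ms",
    "annulus_area_ratio",
    "effective_onset",
    "load_config",
]

WindMode = Literal["inward", "reversed", "off"]
EventKind = Literal["odor_PA", "odor_EL", "LED"]

#: event kinds that incur the odor-delivery latency (light does not)
ODOR_KINDS = ("odor_PA", "odor_EL")


class ConfigError(ValueError):
    """Raised when an arena or schedule configuration violates an invariant."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry, frame rate and airflow configuration of the circular arena.

    Parameters
    ----------
    radius_mm
        Arena radius in mm (default 50).
    frame_rate_hz
        Video frame rate (default 30 fps).
    wind_mode
        ``"inward"``: air flows from the periphery to the central suction
        hole, so *upwind* is radially outward.  ``"reversed"``: flow
        direction flipped, upwind is toward the center.  ``"off"``: no
        airflow; wind-referenced angles are undefined.
    arm_flow_ml_min
        Input flow rate of each of the four arms (mL/min).
    suction_flow_ml_min
        Rate at which air is pulled from the central hole (mL/min); must
        balance the summed arm inflow.
    odor_onset_latency_s
        Delay between solenoid-valve switch and odor reaching the arena.
    quadrant_odor
        Optional map quadrant index (0-3, counterclockwise from the sector
        centered on +x) -> odor label.
    """

    radius_mm: float = 50.0
    frame_rate_hz: float = 30.0
    wind_mode: WindMode = "inward"
    arm_flow_ml_min: tuple[float, float, float, float] = (100.0, 100.0, 100.0, 100.0)
    suction_flow_ml_min: float = 400.0
    odor_onset_latency_s: float = 3.5
    quadrant_odor: dict[int, str] = field(default_factory=dict)

    @property
    def total_inflow_ml_min(self) -> float:
        return float(sum(self.arm_flow_ml_min))

    @property
    def frame_dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def time_to_frame(self, t_s: float) -> int:
        """Nearest frame index for a continuous time in seconds."""
        return int(round(t_s * self.frame_rate_hz))


@dataclass(frozen=True)
class StimulusEvent:
    """One valve or LED event.

    ``valve_on_s`` is when the hardware switches; ``effective_onset_s`` is
    when the stimulus reaches the flies (filled by :func:`effective_onset`).
    Epochs are half-open: a frame at time t belongs to the event iff
    ``effective_onset_s <= t < effective_onset_s + duration_s``.
    """

    kind: EventKind
    valve_on_s: float
    duration_s: float
    effective_onset_s: float | None = None

    @property
    def effective_offset_s(self) -> float:
        if self.effective_onset_s is None:
            raise ValueError("effective onset not resolved; call effective_onset()")
        return self.effective_onset_s + self.duration_s


@dataclass(frozen=True)
class EpochSchedule:
    """Ordered list of stimulus events for one movie."""

    events: tuple[StimulusEvent, ...] = ()

    def __post_init__(self):
        by_kind: dict[str, list[StimulusEvent]] = {}
        for ev in self.events:
            by_kind.setdefault(ev.kind, []).append(ev)
        for kind, evs in by_kind.items():
            evs = sorted(evs, key=lambda e: e.valve_on_s)
            for a, b in zip(evs, evs[1:]):
                if a.valve_on_s + a.duration_s > b.valve_on_s:
                    raise ConfigError(f"overlapping {kind} events at {a.valve_on_s} s")

    def of_kind(self, kind: str) -> tuple[StimulusEvent, ...]:
        return tuple(ev for ev in self.events if ev.kind == kind)

    @property
    def first(self) -> StimulusEvent:
        if not self.events:
            raise ValueError("empty schedule")
        return self.events[0]


def validate_config(cfg: ArenaConfig) -> ArenaConfig:
    """Check all ``ArenaConfig`` invariants; return the config unchanged.

    The mass-balance rule requires the central suction rate to equal the
    summed arm inflow (400 = 4 x 100 mL/min on the default rig; a rig with
    airflow off trivially balances at 0).

    Raises
    ------
    ConfigError
        Naming the violated invariant.
    """
    if cfg.radius_mm <= 0:
        raise ConfigError(f"radius_mm must be > 0, got {cfg.radius_mm}")
    if cfg.frame_rate_hz <= 0:
        raise ConfigError(f"frame_rate_hz must be > 0, got {cfg.frame_rate_hz}")
    if len(cfg.arm_flow_ml_min) != 4:
        raise ConfigError("arm_flow_ml_min must list exactly 4 arm rates")
    if any(rate < 0 for rate in cfg.arm_flow_ml_min):
        raise ConfigError("arm flow rates must be non-negative")
    total = cfg.total_inflow_ml_min
    if abs(total - cfg.suction_flow_ml_min) > 1e-9:
        raise ConfigError(
            f"flow imbalance: arms supply {total} mL/min but suction pulls "
            f"{cfg.suction_flow_ml_min} mL/min"
        )
    if cfg.odor_onset_latency_s < 0:
        raise ConfigError("odor_onset_latency_s must be >= 0")
    if cfg.wind_mode not in ("inward", "reversed", "off"):
        raise ConfigError(f"unknown wind_mode {cfg.wind_mode!r}")
    return cfg


def frames_to_ms(n_frames: int, frame_rate_hz: float) -> int:
    """Duration of ``n_frames`` at ``frame_rate_hz``, in integer milliseconds.

    The canonical onset-response window of 10 frames at 30 fps is 333 ms.
    """
    if frame_rate_hz <= 0:
        raise ValueError(f"frame_rate_hz must be > 0, got {frame_rate_hz}")
    if n_frames < 0:
        raise ValueError(f"n_frames must be >= 0, got {n_frames}")
    return int(round(1000.0 * n_frames / frame_rate_hz))


def annulus_area_ratio(lo1: float, hi1: float, lo2: float, hi2: float) -> float:
    """Ratio of the areas of two annuli, (hi1²-lo1²)/(hi2²-lo2²).

    Area grows with r², so equal-width radial bins are not equal-area: in a
    50-mm arena the outer 40-50 mm ring is nine times the area of the inner
    0-10 mm disk.  This motivates the area-normalized radial index
    (r/R)² used by the kinematics stage.
    """
    for lo, hi in ((lo1, hi1), (lo2, hi2)):
        if not (0 <= lo < hi):
            raise ValueError(f"need 0 <= lo < hi, got ({lo}, {hi})")
    return (hi1**2 - lo1**2) / (hi2**2 - lo2**2)


def effective_onset(schedule: EpochSchedule, cfg: ArenaConfig) -> EpochSchedule:
    """Resolve each event's effective onset.

    Odor events are delayed by ``cfg.odor_onset_latency_s`` after the valve
    switch (tubing dead volume plus arena fill time); LED events are taken
    to act instantaneously.
    """
    resolved = tuple(
        replace(
            ev,
            effective_onset_s=ev.valve_on_s
            + (cfg.odor_onset_latency_s if ev.kind in ODOR_KINDS else 0.0),
        )
        for ev in schedule.events
    )
    return EpochSchedule(events=resolved)


def load_config(path: str | Path) -> tuple[ArenaConfig, EpochSchedule]:
    """Load an ``ArenaConfig`` + ``EpochSchedule`` from a YAML or JSON file.

    Expected layout::

        arena:
          radius_mm: 50
          frame_rate_hz: 30
          wind_mode: inward
          arm_flow_ml_min: [100, 100, 100, 100]
          suction_flow_ml_min: 400
          odor_onset_latency_s: 3.5
          quadrant_odor: {0: PA, 1: EL, 2: PA, 3: EL}
        schedule:
          - {kind: odor_PA, valve_on_s: 30.0, duration_s: 10.0}

    Units are fixed: mm, s, mL/min, Hz.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    arena = data.get("arena", {})
    if "arm_flow_ml_min" in arena:
        arena["arm_flow_ml_min"] = tuple(arena["arm_flow_ml_min"])
    if "quadrant_odor" in arena:
        arena["quadrant_odor"] = {int(k): str(v) for k, v in arena["quadrant_odor"].items()}
    cfg = validate_config(ArenaConfig(**arena))
    events = tuple(StimulusEvent(**ev) for ev in data.get("schedule", []))
    schedule = effective_onset(EpochSchedule(events=events), cfg)
    return cfg, schedule
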