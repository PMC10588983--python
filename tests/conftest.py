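import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import anemotax as ax

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg():
    return ax.validate_config(ax.ArenaConfig())


@pytest.fixture(scope="session")
def led_schedule(cfg):
    """10-s LED stimulation starting at 20 s of a 60-s movie."""
    sched = ax.EpochSchedule(events=(ax.StimulusEvent("LED", 20.0, 10.0),))
    return ax.effective_onset(sched, cfg)


@pytest.fixture(scope="session")
def odor_schedule(cfg):
    """10-s odor pulse: valve at 20 s, effective onset 23.5 s."""
    sched = ax.EpochSchedule(events=(ax.StimulusEvent("odor_PA", 20.0, 10.0),))
    return ax.effective_onset(sched, cfg)


@pytest.fixture(scope="session")
def null_trackset(cfg, led_schedule):
    """Control-like simulated movie: startle only, no directed gains."""
    params = ax.SimParams(n_flies=20, duration_s=60.0, seed=11)
    return ax.simulate(params, cfg, led_schedule, movie_id="null")


@pytest.fixture(scope="session")
def upwind_trackset(cfg, led_schedule):
    """Simulated movie with a strong upwind turn bias during the stimulus."""
    params = ax.SimParams(n_flies=20, duration_s=60.0, upwind_turn_gain=3.0, seed=7)
    return ax.simulate(params, cfg, led_schedule, movie_id="upwind")


def make_track(x, y, heading, fps=30.0, movie_id="m", fly_id="f"):
    """Hand-built FlyTrack from coordinate lists."""
    n = len(x)
    return ax.FlyTrack(
        movie_id=movie_id,
        fly_id=fly_id,
        t_s=np.arange(n) / fps,
        x_mm=np.asarray(x, dtype=float),
        y_mm=np.asarray(y, dtype=float),
        heading_deg=np.asarray(heading, dtype=float),
    )


def rotate_trackset(ts, phi_deg):
    """Rotate every position and heading by a common angle."""
    from anemotax.angles import wrap_deg

    phi = np.deg2rad(phi_deg)
    c, s = np.cos(phi), np.sin(phi)

    def rot(tr):
        new = tr.copy()
        new.x_mm = c * tr.x_mm - s * tr.y_mm
        new.y_mm = s * tr.x_mm + c * tr.y_mm
        new.heading_deg = wrap_deg(tr.heading_deg + phi_deg)
        return new

    return ts.map_tracks(rot)
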