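"""Data model and file I/O for tracked fly trajectories.

The canonical on-disk format is a plain delimited table, one row per fly
per frame, with columns ``movie_id, fly_id, frame, x_mm, y_mm,
heading_deg``.  Coordinates are arena-centered (origin at the suction
hole); frames are 0-based and the time of frame k is k / frame_rate.
Both comma- and tab-delimited files (LF or CRLF) are accepted on read;
writes are comma-delimited UTF-8.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import wrap_deg
from .arena import ArenaConfig, EpochSchedule

__all__ = ["FlyTrack", "TrackSet", "SchemaError", "read_tracks", "write_tracks", "recenter_and_scale"]

REQUIRED_COLUMNS = ("movie_id", "fly_id", "frame", "x_mm", "y_mm", "heading_deg")

#: how far outside the nominal radius a tracked point may sit (mm) before
#: it is treated as a coordinate error rather than wall contact
DEFAULT_WALL_TOLERANCE_MM = 0.5


class SchemaError(ValueError):
    """Raised when a trajectory table does not match the expected schema."""


@dataclass
class FlyTrack:
    """Per-frame position and heading of a single fly in one movie.

    ``heading_deg`` is the body orientation, counterclockwise-positive,
    0° along +x, wrapped to (-180, 180].  ``valid`` flags frames usable for
    analysis; quality filters clear flags, they never delete rows.
    """

    movie_id: str
    fly_id: str
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    heading_deg: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.heading_deg = wrap_deg(np.asarray(self.heading_deg, dtype=float))
        n = len(self.t_s)
        if not (len(self.x_mm) == len(self.y_mm) == len(self.heading_deg) == n):
            raise ValueError("all per-frame series must have equal length")
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError(f"t_s must be strictly increasing (fly {self.fly_id})")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != n:
                raise ValueError("valid flags must match series length")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def xy(self) -> np.ndarray:
        """Positions as an (n, 2) array."""
        return np.column_stack([self.x_mm, self.y_mm])

    def frame_at(self, t_s: float, frame_rate_hz: float) -> int:
        idx = int(round(t_s * frame_rate_hz))
        if not (0 <= idx < len(self)):
            raise IndexError(f"time {t_s} s is outside the recording")
        return idx

    def copy(self) -> "FlyTrack":
        return FlyTrack(
            movie_id=self.movie_id,
            fly_id=self.fly_id,
            t_s=self.t_s.copy(),
            x_mm=self.x_mm.copy(),
            y_mm=self.y_mm.copy(),
            heading_deg=self.heading_deg.copy(),
            valid=self.valid.copy(),
        )


@dataclass
class TrackSet:
    """All tracks of one or more movies sharing a config and schedule."""

    tracks: list[FlyTrack]
    cfg: ArenaConfig
    schedule: EpochSchedule = field(default_factory=EpochSchedule)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        tol = self.provenance.get("wall_tolerance_mm", DEFAULT_WALL_TOLERANCE_MM)
        limit = self.cfg.radius_mm + tol
        for tr in self.tracks:
            r = np.hypot(tr.x_mm, tr.y_mm)
            bad = r > limit
            if np.any(bad):
                k = int(np.argmax(bad))
                raise ValueError(
                    f"fly {tr.fly_id} (movie {tr.movie_id}) at r={r[k]:.2f} mm "
                    f"exceeds arena radius {self.cfg.radius_mm} mm + {tol} mm tolerance"
                )

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def movie_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for tr in self.tracks:
            seen.setdefault(tr.movie_id)
        return list(seen)

    def by_movie(self) -> dict[str, list[FlyTrack]]:
        out: dict[str, list[FlyTrack]] = {}
        for tr in self.tracks:
            out.setdefault(tr.movie_id, []).append(tr)
        return out

    def map_tracks(self, fn) -> "TrackSet":
        """Return a new TrackSet with ``fn`` applied to each track."""
        return TrackSet(
            tracks=[fn(tr) for tr in self.tracks],
            cfg=self.cfg,
            schedule=self.schedule,
            provenance=dict(self.provenance),
        )


def _to_frame(ts: TrackSet) -> pd.DataFrame:
    rows = []
    for tr in ts.tracks:
        frames = np.rint(tr.t_s * ts.cfg.frame_rate_hz).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "movie_id": tr.movie_id,
                    "fly_id": tr.fly_id,
                    "frame": frames,
                    "x_mm": tr.x_mm,
                    "y_mm": tr.y_mm,
                    "heading_deg": tr.heading_deg,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=REQUIRED_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def read_tracks(
    path: str | Path | io.IOBase,
    cfg: ArenaConfig,
    schedule: EpochSchedule | None = None,
    wall_tolerance_mm: float = DEFAULT_WALL_TOLERANCE_MM,
) -> TrackSet:
    """Read a trajectory table (CSV or TSV) into a :class:`TrackSet`.

    All frames start valid; run the quality filters to clear flags.

    Raises
    ------
    SchemaError
        On a missing column, duplicate (movie, fly, frame) rows, or
        non-monotone frame numbers within a fly.
    ValueError
        For coordinates beyond the arena radius plus tolerance.
    """
    # keep id columns literal: "null"/"NA" are legitimate movie or fly labels
    df = pd.read_csv(path, sep=None, engine="python", keep_default_na=False, na_values=[])
    for col in ("movie_id", "fly_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    for col in ("frame", "x_mm", "y_mm", "heading_deg"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.duplicated(subset=["movie_id", "fly_id", "frame"]).any():
        dup = df[df.duplicated(subset=["movie_id", "fly_id", "frame"])].iloc[0]
        raise SchemaError(
            f"duplicate row for movie {dup['movie_id']!r}, fly {dup['fly_id']!r}, "
            f"frame {dup['frame']}"
        )
    tracks = []
    for (movie_id, fly_id), grp in df.groupby(["movie_id", "fly_id"], sort=True):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise SchemaError(f"non-monotone frames for fly {fly_id!r} in movie {movie_id!r}")
        tracks.append(
            FlyTrack(
                movie_id=str(movie_id),
                fly_id=str(fly_id),
                t_s=frames / cfg.frame_rate_hz,
                x_mm=grp["x_mm"].to_numpy(),
                y_mm=grp["y_mm"].to_numpy(),
                heading_deg=grp["heading_deg"].to_numpy(),
            )
        )
    return TrackSet(
        tracks=tracks,
        cfg=cfg,
        schedule=schedule or EpochSchedule(),
        provenance={"wall_tolerance_mm": wall_tolerance_mm},
    )


def write_tracks(ts: TrackSet, path: str | Path) -> Path:
    """Write the canonical comma-delimited trajectory table.

    Coordinates and headings are formatted with 6 decimal places, so a
    read/write round trip preserves them to <= 1e-6 mm / deg and a re-write
    of a read file is byte-stable.
    """
    path = Path(path)
    _to_frame(ts).to_csv(path, index=False, float_format="%.6f")
    return path


def recenter_and_scale(
    raw: pd.DataFrame,
    center_px: tuple[float, float],
    mm_per_px: float,
    cfg: ArenaConfig,
    x_col: str = "x_px",
    y_col: str = "y_px",
) -> TrackSet:
    """Adapt tracker output in pixel coordinates to arena-centered mm.

    ``raw`` needs columns movie_id, fly_id, frame, ``x_col``, ``y_col`` and
    heading_deg; positions are translated so ``center_px`` maps to (0, 0)
    and scaled by ``mm_per_px``.  Headings pass through unchanged (the
    transform is a uniform scaling, which preserves angles).
    """
    if mm_per_px <= 0:
        raise ValueError(f"mm_per_px must be > 0, got {mm_per_px}")
    df = raw.copy()
    df["x_mm"] = (df[x_col] - center_px[0]) * mm_per_px
    df["y_mm"] = (df[y_col] - center_px[1]) * mm_per_px
    buf = io.StringIO()
    df[list(REQUIRED_COLUMNS)].to_csv(buf, index=False)
    buf.seek(0)
    return read_tracks(buf, cfg)
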