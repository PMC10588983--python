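"""Optogenetic activation-screen summary matrix.

For each driver line the screen reduces a movie (or set of movies) to five
behavioral parameters in 2-s time bins spanning the period before, during
and after a 10-s LED stimulation:

* upwind displacement (onset-subtracted mean (r/R)²),
* mean cos(angle to upwind),
* angular velocity (deg/s),
* forward walking speed (mm/s),
* return probability, evaluated at each bin's time0 values.

Each (parameter, bin) cell is then standardized across driver lines,
z = (value − mean) / SD with the sample (n−1) standard deviation, so a
line's z-score says how unusual its behavior is relative to the screened
population (which includes the empty-driver control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import StimulusEvent
from .kinematics import compute_kinematics
from .metrics import return_probability, upwind_displacement
from .trackio import TrackSet

__all__ = ["ScreenMatrix", "PARAMETERS", "parameter_timecourses", "zscore_matrix", "rank_hits"]

PARAMETERS = (
    "upwind_displacement",
    "cos_upwind",
    "angular_velocity",
    "forward_speed",
    "p_return",
)

BIN_WIDTH_S = 2.0
N_PRE_BINS = 2
N_POST_BINS = 5


@dataclass
class ScreenMatrix:
    """Raw and standardized line × parameter × bin screen values."""

    lines: list[str]
    parameters: tuple[str, ...]
    bin_labels: list[str]
    bin_edges_s: np.ndarray  # relative to stimulus onset
    raw: np.ndarray  # (lines, parameters, bins)
    z: np.ndarray
    cell_mean: np.ndarray  # (parameters, bins)
    cell_sd: np.ndarray
    zero_spread: np.ndarray  # bool (parameters, bins)
    metadata: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, line in enumerate(self.lines):
            for j, par in enumerate(self.parameters):
                for k, lab in enumerate(self.bin_labels):
                    rows.append(
                        {
                            "line": line,
                            "parameter": par,
                            "bin": lab,
                            "bin_start_s": self.bin_edges_s[k],
                            "raw": self.raw[i, j, k],
                            "z": self.z[i, j, k],
                        }
                    )
        return pd.DataFrame(rows)


def _bin_edges(epoch: StimulusEvent, n_pre: int, n_post: int) -> np.ndarray:
    """2-s bin start times relative to onset: n_pre before, during, n_post after."""
    n_during = int(round(epoch.duration_s / BIN_WIDTH_S))
    start = -n_pre * BIN_WIDTH_S
    return start + BIN_WIDTH_S * np.arange(n_pre + n_during + n_post)


def parameter_timecourses(
    ts: TrackSet,
    epoch: StimulusEvent | None = None,
    n_pre_bins: int = N_PRE_BINS,
    n_post_bins: int = N_POST_BINS,
) -> pd.DataFrame:
    """Five behavioral parameters in 2-s bins for one driver line.

    Returns a DataFrame indexed by parameter with one column per bin
    (labels ``T1 ... Tn``, stimulation-period bins flagged in the attrs).
    Bin values are means of per-frame quantities over the bin; return
    probability is the mean of the per-time0 profile over time0 in the bin.
    """
    if epoch is None:
        epoch = ts.schedule.first
    onset = epoch.effective_onset_s
    if onset is None:
        raise ValueError("epoch has no effective onset; resolve the schedule first")
    edges_rel = _bin_edges(epoch, n_pre_bins, n_post_bins)
    fps = ts.cfg.frame_rate_hz
    n_frames = min(len(tr) for tr in ts.tracks)
    movie_len_s = n_frames / fps
    if onset + edges_rel[-1] + BIN_WIDTH_S > movie_len_s + 1e-9:
        raise ValueError("movie too short for the requested binning span")
    if onset + edges_rel[0] < -1e-9:
        raise ValueError("movie starts after the first pre-stimulus bin")

    t_s, delta = upwind_displacement(ts, epoch)
    delta_pop = np.nanmean(delta, axis=0)

    n_flies = len(ts.tracks)
    cosa = np.full((n_flies, n_frames), np.nan)
    angv = np.full((n_flies, n_frames), np.nan)
    fwd = np.full((n_flies, n_frames), np.nan)
    for i, tr in enumerate(ts.tracks):
        k = compute_kinematics(tr, ts.cfg)
        m = tr.valid[:n_frames]
        cosa[i, m] = k.cos_alpha[:n_frames][m]
        angv[i, m] = k.ang_vel_dps[:n_frames][m]
        fwd[i, m] = k.fwd_speed_mm_s[:n_frames][m]

    profile = return_probability(ts)

    values = np.full((len(PARAMETERS), len(edges_rel)), np.nan)
    for k_bin, rel in enumerate(edges_rel):
        lo, hi = onset + rel, onset + rel + BIN_WIDTH_S
        frames = (np.arange(n_frames) / fps >= lo) & (np.arange(n_frames) / fps < hi)
        frames_d = frames[: len(delta_pop)]
        with np.errstate(invalid="ignore"):
            values[0, k_bin] = np.nanmean(delta_pop[frames_d])
            values[1, k_bin] = np.nanmean(cosa[:, frames])
            values[2, k_bin] = np.nanmean(angv[:, frames])
            values[3, k_bin] = np.nanmean(fwd[:, frames])
        sel = (profile.time0_s >= lo) & (profile.time0_s < hi)
        if sel.any():
            values[4, k_bin] = np.nanmean(profile.p_return[sel])

    labels = [f"T{k + 1}" for k in range(len(edges_rel))]
    df = pd.DataFrame(values, index=list(PARAMETERS), columns=labels)
    df.attrs["bin_edges_rel_s"] = [float(e) for e in edges_rel]
    df.attrs["during_bins"] = [
        lab for lab, rel in zip(labels, edges_rel) if 0 <= rel < epoch.duration_s
    ]
    return df


def zscore_matrix(raw_by_line: dict[str, pd.DataFrame]) -> ScreenMatrix:
    """Standardize per-line parameter × bin tables across lines.

    z = (value − mean) / SD per (parameter, bin) cell, with the sample
    (n−1) SD across driver lines.  Cells with zero spread get z = 0 and
    are flagged.  Requires at least two lines.
    """
    lines = list(raw_by_line)
    if len(lines) < 2:
        raise ValueError("z-scores need >= 2 driver lines; report raw values instead")
    first = raw_by_line[lines[0]]
    params = tuple(first.index)
    bins = list(first.columns)
    raw = np.stack([raw_by_line[line].to_numpy() for line in lines])
    mean = np.nanmean(raw, axis=0)
    sd = np.nanstd(raw, axis=0, ddof=1)
    zero_spread = ~(sd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - mean) / np.where(zero_spread, 1.0, sd)
    z = np.where(np.broadcast_to(zero_spread, z.shape), 0.0, z)
    edges = first.attrs.get("bin_edges_rel_s", np.full(len(bins), np.nan))
    return ScreenMatrix(
        lines=lines,
        parameters=params,
        bin_labels=bins,
        bin_edges_s=np.asarray(edges),
        raw=raw,
        z=z,
        cell_mean=mean,
        cell_sd=sd,
        zero_spread=zero_spread,
        metadata={
            "standardization": "across driver lines, per (parameter, bin)",
            "sd": "sample (ddof=1)",
            "during_bins": first.attrs.get("during_bins", []),
        },
    )


def rank_hits(
    m: ScreenMatrix,
    parameter: str,
    bin_set: list[str] | None = None,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Order lines by mean z over the chosen bins of one parameter.

    Lines with mean z above ``threshold`` are flagged as hits; ranking is
    descriptive (no multiplicity correction).  Ties keep input order.
    """
    if parameter not in m.parameters:
        raise KeyError(f"unknown parameter {parameter!r}")
    if bin_set is None:
        bin_set = m.metadata.get("during_bins") or m.bin_labels
    missing = [b for b in bin_set if b not in m.bin_labels]
    if missing:
        raise KeyError(f"unknown bin(s): {missing}")
    j = m.parameters.index(parameter)
    cols = [m.bin_labels.index(b) for b in bin_set]
    score = np.nanmean(m.z[:, j, :][:, cols], axis=1)
    order = np.argsort(-score, kind="stable")
    return pd.DataFrame(
        {
            "line": [m.lines[i] for i in order],
            "mean_z": score[order],
            "hit": score[order] > threshold,
        }
    )
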