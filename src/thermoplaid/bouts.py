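"""Swim-bout detection and kinematics from tail-angle traces.

Larval zebrafish swim in discrete ~100-200 ms bouts separated by stationary
interbout intervals.  Bouts are delineated from the cumulative tail-bend
angle: the "swim vigor" (standard deviation of the tail angle in a trailing
10-frame window at 250 Hz) crosses an empirical threshold of 0.1 rad/frame at
bout start and falls back below it at bout end.  Per-bout kinematics
(displacement, turn angle) are computed from 5-frame averages flanking the
bout, and analysis is restricted to bouts starting at least 4 mm away from
the arena wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Trajectory

DEFAULT_VIGOR_WINDOW = 10
DEFAULT_VIGOR_THRESHOLD = 0.1  # rad/frame
KINEMATIC_FLANK = 5  # frames averaged before start / after end


@dataclass
class BoutEvent:
    """A single swim bout, frames half-open ``[start_frame, end_frame)`` at 250 Hz."""

    start_frame: int
    end_frame: int
    displacement_mm: float = math.nan
    turn_angle_deg: float = math.nan
    interbout_interval_s: float = math.nan
    kinematics_valid: bool = False

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError(
                f"bout must span at least one frame, got [{self.start_frame}, {self.end_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def swim_vigor(tail_angle: np.ndarray, window: int = DEFAULT_VIGOR_WINDOW) -> np.ndarray:
    """Trailing-window standard deviation of the tail angle (rad/frame).

    The window is causal: frame ``f`` summarizes frames ``[f - window + 1, f]``.
    The first ``window - 1`` frames use the partial window that is available.
    Population SD (ddof=0) is used throughout.
    """
    tail_angle = np.asarray(tail_angle, dtype=float)
    if window < 2:
        raise ValueError("vigor window must be at least 2 frames")
    if tail_angle.size < window:
        raise ValueError("trace shorter than the vigor window")
    vig = (
        pd.Series(tail_angle)
        .rolling(window, min_periods=1)
        .std(ddof=0)
        .to_numpy()
    )
    # rolling var can return tiny negative values on constant stretches
    return np.nan_to_num(np.maximum(vig, 0.0))


def detect_bouts(vigor: np.ndarray, threshold: float = DEFAULT_VIGOR_THRESHOLD) -> list[BoutEvent]:
    """Threshold the vigor trace into non-overlapping bout events.

    A bout opens at each upward crossing (vigor moving above ``threshold``)
    and closes when the vigor falls back below it; a bout still open at the
    end of the trace is closed at the final frame.
    """
    vigor = np.asarray(vigor, dtype=float)
    above = vigor > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    return [BoutEvent(int(s), int(e)) for s, e in zip(starts, ends)]


def _mean_heading(headings: np.ndarray) -> float:
    """Circular mean via the mean resultant vector, radians."""
    return float(np.arctan2(np.mean(np.sin(headings)), np.mean(np.cos(headings))))


def bout_kinematics(traj: "Trajectory", bout: BoutEvent) -> BoutEvent:
    """Fill displacement and turn angle from 5-frame flanking averages.

    Displacement is the Euclidean distance between the mean centroid position
    in the five frames before bout start and in the five frames after bout
    end.  The turn angle is the difference of mean-vector headings over the
    same windows, mapped to the smallest angle in [0, 180] degrees.  Bouts too
    close to the trace boundary keep NaN kinematics and are flagged invalid.
    """
    n = traj.x.size
    s, e = bout.start_frame, bout.end_frame
    if s - KINEMATIC_FLANK < 0 or e + KINEMATIC_FLANK > n:
        return replace(bout, kinematics_valid=False)
    pre = slice(s - KINEMATIC_FLANK, s)
    post = slice(e, e + KINEMATIC_FLANK)
    dx = traj.x[post].mean() - traj.x[pre].mean()
    dy = traj.y[post].mean() - traj.y[pre].mean()
    disp = float(np.hypot(dx, dy))
    dh = _mean_heading(traj.heading[post]) - _mean_heading(traj.heading[pre])
    turn = abs(math.remainder(dh, 2 * math.pi))  # smallest angle
    return replace(
        bout,
        displacement_mm=disp,
        turn_angle_deg=math.degrees(turn),
        kinematics_valid=True,
    )


def annotate_interbout_intervals(
    bouts: Sequence[BoutEvent], frame_rate: float = 250.0
) -> list[BoutEvent]:
    """Set each bout's interbout interval (previous end -> current start, s)."""
    out = []
    for i, b in enumerate(bouts):
        if i == 0:
            out.append(replace(b, interbout_interval_s=math.nan))
        else:
            ibi = (b.start_frame - bouts[i - 1].end_frame) / frame_rate
            out.append(replace(b, interbout_interval_s=ibi))
    return out


def edge_filter(
    bouts: Sequence[BoutEvent],
    traj: "Trajectory",
    arena_radius_mm: float = 50.0,
    margin_mm: float = 4.0,
) -> list[BoutEvent]:
    """Keep bouts starting at least ``margin_mm`` from the arena wall."""
    if margin_mm >= arena_radius_mm:
        raise ValueError("edge margin must be smaller than the arena radius")
    cx, cy = traj.arena_center
    kept = []
    for b in bouts:
        r = math.hypot(traj.x[b.start_frame] - cx, traj.y[b.start_frame] - cy)
        if arena_radius_mm - r >= margin_mm:
            kept.append(b)
    return kept


def per_bout_delta_t(
    bouts: Sequence[BoutEvent],
    temperature: np.ndarray,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bout |temperature change| and a matched random-interval control.

    For each bout, |T(end) - T(start)|.  The control draws one uniformly
    placed interval of identical frame length per bout anywhere within the
    trace and computes the same quantity, quantifying the temperature change
    expected over bout-length windows irrespective of swimming.
    """
    if len(bouts) == 0:
        raise ValueError("empty bout list")
    temperature = np.asarray(temperature, dtype=float)
    n = temperature.size
    rng = np.random.default_rng(seed)
    bout_dt = np.empty(len(bouts))
    ctrl_dt = np.empty(len(bouts))
    for i, b in enumerate(bouts):
        if b.end_frame > n:
            raise ValueError("temperature trace does not cover all bouts")
        length = b.n_frames
        end = min(b.end_frame, n - 1)
        bout_dt[i] = abs(temperature[end] - temperature[b.start_frame])
        u = int(rng.integers(0, n - length))
        ctrl_dt[i] = abs(temperature[u + length] - temperature[u])
    return bout_dt, ctrl_dt


def bout_table(bouts: Sequence[BoutEvent], frame_rate: float = 250.0) -> pd.DataFrame:
    """One row per bout: start_s, end_s, displacement_mm, turn_deg, ibi_s."""
    return pd.DataFrame(
        {
            "start_s": [b.start_frame / frame_rate for b in bouts],
            "end_s": [b.end_frame / frame_rate for b in bouts],
            "displacement_mm": [b.displacement_mm for b in bouts],
            "turn_deg": [b.turn_angle_deg for b in bouts],
            "ibi_s": [b.interbout_interval_s for b in bouts],
        }
    )
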