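"""Per-track motility classification and run decomposition.

Tracks are classified as stalled, oscillating or transported from their
leading-end displacements; transported tracks are decomposed into runs —
continuous bouts of movement terminated by pauses of >= 6 s — with per-run
summed path length ("run length", direction-agnostic), net displacement,
direction switches and per-directional-bout velocities.

Definitions
-----------
detectable movement
    A frame-to-frame leading-end displacement greater than 0.24 um
    (2 pixels); smaller steps are treated as localisation jitter.
transported
    Cumulative detectable excursion exceeds 1 um in either direction.
oscillating
    Detectable back-and-forth movement that never exceeds 1 um excursion.
stalled
    No detectable movement (the class precedence transported > oscillating
    > stalled makes classification total: a track that stalls for the
    first minute and later moves beyond 1 um counts as transported).
run termination
    A period of >= 6 s (two frames at 3 s) without detectable movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: detectable-movement threshold (um between consecutive frames; 2 pixels)
DETECT_MOVE_UM = 0.24
#: a pause at least this long terminates a run (s)
PAUSE_SPLIT_S = 6.0
#: transported means displacement beyond this (um)
TRANSPORT_UM = 1.0
#: a track must span at least this long to be classified (s)
MIN_CLASSIFY_S = 60.0

ANTEROGRADE, RETROGRADE = "anterograde", "retrograde"


@dataclass
class Bout:
    """A unidirectional stretch of continuous movement within a run."""

    start_step: int            # index of first displacement interval
    n_steps: int
    displacement: float        # signed um
    duration_s: float

    @property
    def direction(self) -> str:
        return ANTEROGRADE if self.displacement > 0 else RETROGRADE

    @property
    def velocity(self) -> float:
        """Magnitude of displacement over elapsed time (um/s)."""
        return abs(self.displacement) / self.duration_s


@dataclass
class Run:
    """A continuous bout of transport terminated by a >= 6 s pause."""

    start_frame: int           # first frame of movement (end of first step)
    end_frame: int
    run_length: float          # summed |displacement| regardless of direction
    net_displacement: float
    n_switches: int
    bouts: list[Bout] = field(default_factory=list)
    complete: bool = True      # False when cut off by the end of observation


@dataclass
class MotilityRecord:
    track_id: int
    cls: str                   # stalled | oscillating | transported | unclassifiable
    runs: list[Run] = field(default_factory=list)
    percent_time_moving: dict = field(default_factory=dict)


def leading_end_displacements(intervals: np.ndarray) -> np.ndarray:
    """Per-step displacement of the leading end (um).

    The leading end is the end facing the direction of the current step;
    for rigid motion this equals the displacement of either end.
    """
    iv = np.asarray(intervals, dtype=float)
    da = np.diff(iv[:, 0])
    db = np.diff(iv[:, 1])
    s = np.sign(da + db)
    return np.where(s > 0, db, np.where(s < 0, da, 0.0))


def _moving_mask(d: np.ndarray, threshold: float) -> np.ndarray:
    return np.abs(d) > threshold


def classify_displacements(d: np.ndarray, frame_interval: float,
                           threshold: float = DETECT_MOVE_UM) -> str:
    """Classify from a displacement sequence; see the module docstring."""
    if len(d) * frame_interval < MIN_CLASSIFY_S:
        return "unclassifiable"
    moving = _moving_mask(d, threshold)
    if not moving.any():
        return "stalled"
    traj = np.concatenate([[0.0], np.cumsum(np.where(moving, d, 0.0))])
    if np.max(np.abs(traj)) > TRANSPORT_UM:
        return "transported"
    return "oscillating"


def classify_motility(track, frame_interval: float | None = None,
                      series=None) -> MotilityRecord:
    """Classify one track and attach its run decomposition.

    ``track`` may be a linked image track or a ground-truth track; both
    expose ``frame_index()`` and ``interval_array()``.  ``frame_interval``
    is read from ``series`` when given.
    """
    if series is not None:
        frame_interval = series.frame_interval
    if frame_interval is None:
        raise ValueError("frame_interval (or series) is required")
    iv = track.interval_array()
    d = leading_end_displacements(iv)
    cls = classify_displacements(d, frame_interval)
    runs = extract_runs(track, frame_interval) if cls == "transported" else []
    moving = _moving_mask(d, DETECT_MOVE_UM)
    n = max(len(d), 1)
    pct = {
        ANTEROGRADE: 100.0 * np.sum(moving & (d > 0)) / n,
        RETROGRADE: 100.0 * np.sum(moving & (d < 0)) / n,
    }
    return MotilityRecord(track_id=getattr(track, "id", -1), cls=cls,
                          runs=runs, percent_time_moving=pct)


def runs_from_displacements(d: np.ndarray, frame_interval: float,
                            first_frame: int = 0,
                            threshold: float = DETECT_MOVE_UM,
                            pause_split_s: float = PAUSE_SPLIT_S,
                            ) -> list[Run]:
    """Decompose a displacement sequence into runs.

    Step ``i`` spans frames ``first_frame + i`` to ``first_frame + i + 1``.
    Movement steps separated by pauses shorter than ``pause_split_s``
    belong to the same run; a pause of at least ``pause_split_s`` (or the
    end of observation) terminates it.
    """
    moving = _moving_mask(np.asarray(d, dtype=float), threshold)
    pause_steps = max(1, int(np.ceil(pause_split_s / frame_interval)))
    runs: list[Run] = []
    i = 0
    n = len(d)
    while i < n:
        if not moving[i]:
            i += 1
            continue
        # run starts at step i; extend while pauses stay short
        steps = [i]
        j = i + 1
        gap = 0
        while j < n:
            if moving[j]:
                steps.append(j)
                gap = 0
            else:
                gap += 1
                if gap >= pause_steps:
                    break
            j += 1
        complete = not (j >= n and (gap < pause_steps))
        seq = np.asarray([d[k] for k in steps])
        signs = np.sign(seq)
        n_switches = int(np.sum(signs[1:] != signs[:-1]))
        # bouts: maximal groups of consecutive same-sign movement steps
        bouts: list[Bout] = []
        b0 = 0
        for k in range(1, len(steps) + 1):
            boundary = (k == len(steps)
                        or steps[k] != steps[k - 1] + 1
                        or signs[k] != signs[k - 1])
            if boundary:
                sub = seq[b0:k]
                bouts.append(Bout(
                    start_step=steps[b0], n_steps=k - b0,
                    displacement=float(sub.sum()),
                    duration_s=(k - b0) * frame_interval))
                b0 = k
        runs.append(Run(
            start_frame=first_frame + steps[0],
            end_frame=first_frame + steps[-1] + 1,
            run_length=float(np.abs(seq).sum()),
            net_displacement=float(seq.sum()),
            n_switches=n_switches,
            bouts=bouts,
            complete=complete))
        i = j
    return runs


def extract_runs(track, frame_interval: float) -> list[Run]:
    """Run decomposition for one (transported) track."""
    d = leading_end_displacements(track.interval_array())
    frames = track.frame_index()
    return runs_from_displacements(d, frame_interval,
                                   first_frame=int(frames[0]))


def run_velocity(run: Run) -> list[float]:
    """Velocity (um/s) of each directional bout within a run.

    A bout's velocity is its end displacement divided by elapsed time;
    degenerate zero-duration bouts cannot occur by construction (every
    bout spans at least one frame interval).
    """
    return [b.velocity for b in run.bouts]


def percent_time_moving(record: MotilityRecord, direction: str) -> float:
    """Percent of observed time the track spent moving in ``direction``."""
    if direction not in record.percent_time_moving:
        raise ValueError(f"direction must be one of "
                         f"{sorted(record.percent_time_moving)}")
    return record.percent_time_moving[direction]


def switch_fraction(runs: Sequence[Run]) -> float:
    """Fraction of runs containing at least one direction switch."""
    if not runs:
        raise ValueError("switch_fraction needs at least one run")
    return sum(1 for r in runs if r.n_switches >= 1) / len(runs)


def motility_table(records: Sequence[MotilityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "track_id": r.track_id, "class": r.cls,
            "n_runs": len(r.runs),
            "pct_moving_anterograde": r.percent_time_moving.get(ANTEROGRADE),
            "pct_moving_retrograde": r.percent_time_moving.get(RETROGRADE),
        })
    return pd.DataFrame(rows, columns=["track_id", "class", "n_runs",
                                       "pct_moving_anterograde",
                                       "pct_moving_retrograde"])


def runs_table(records: Sequence[MotilityRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for k, r in enumerate(rec.runs):
            rows.append({
                "track_id": rec.track_id, "run": k,
                "start_frame": r.start_frame, "end_frame": r.end_frame,
                "run_length_um": r.run_length,
                "net_displacement_um": r.net_displacement,
                "n_switches": r.n_switches, "complete": r.complete,
                "mean_bout_velocity_um_s":
                    float(np.mean(run_velocity(r))) if r.bouts else np.nan,
            })
    return pd.DataFrame(rows, columns=["track_id", "run", "start_frame",
                                       "end_frame", "run_length_um",
                                       "net_displacement_um", "n_switches",
                                       "complete",
                                       "mean_bout_velocity_um_s"])
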