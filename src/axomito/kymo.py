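"""Kymograph representation of axonal timelapse stacks and mitochondrial morphometry.

Axons are quasi-one-dimensional, so every downstream stage in this package
operates on calibrated intensity profiles sampled along the annotated axon
path (the kymograph representation): one row per frame, one column per
pixel-sized step of arc length.  This module converts annotated image stacks
into that representation, segments mitochondria per frame, links segments
into tracks, and computes the standard morphometric read-outs (length,
density per 10 um, branch density per 100 um, and the length x density
"mass" index).

Conventions
-----------
* arc length is measured in um from the proximal (soma) end of the path;
  increasing arc length is the anterograde direction,
* intervals are half-open ``[start, end)`` in um,
* frames are 0-based and time = frame * frame_interval seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

#: minimum detectable mitochondrion extent, in pixels
MIN_SEGMENT_PIXELS = 2
#: default segmentation threshold is background + K_SIGMA * background SD
K_SIGMA = 3.0
#: floor on thresholds, as a fraction of the series dynamic range, so that
#: thresholding remains meaningful in the noise-free limit (sigma_bg == 0)
RANGE_FLOOR_FRAC = 0.02
#: a plateau brighter than this multiple of the reference plateau is flagged
#: as two spatially overlapping mitochondria (fluorescence is additive)
OVERLAP_PLATEAU_FACTOR = 1.6

#: growth-cone sampling constants: the distal window is 50 um of axon shaft
#: ending at the growth-cone neck; when no neck is annotated the distal 10 um
#: of the shaft are treated as the growth cone
DISTAL_WINDOW_UM = 50.0
GROWTH_CONE_FALLBACK_UM = 10.0

#: a projection must be strictly longer than this to count as a branch
BRANCH_MIN_UM = 10.0


class PathError(ValueError):
    """Raised when an axon path annotation is unusable."""


# ---------------------------------------------------------------------------
# axon path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxonPath:
    """Polyline annotation of an axon in image coordinates (um).

    Parameters
    ----------
    vertices:
        ``(V, 2)`` array of ``(x, y)`` positions in um, ordered soma to
        growth cone so that increasing arc length is anterograde.
    growth_cone_boundary:
        Arc length (um) of the growth-cone neck, if annotated.
    """

    vertices: np.ndarray
    growth_cone_boundary: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise PathError("axon path needs at least two (x, y) vertices")
        object.__setattr__(self, "vertices", v)
        if self.length <= 0:
            raise PathError("axon path has zero length")
        b = self.growth_cone_boundary
        if b is not None and not (0.0 < b <= self.length):
            raise PathError("growth_cone_boundary outside the path extent")

    @property
    def _seg_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    @property
    def length(self) -> float:
        """Total arc length in um."""
        return float(self._seg_lengths.sum())

    def point_at(self, arcs: np.ndarray) -> np.ndarray:
        """Interpolate ``(x, y)`` positions at the given arc lengths."""
        arcs = np.asarray(arcs, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self._seg_lengths)])
        xs = np.interp(arcs, cum, self.vertices[:, 0])
        ys = np.interp(arcs, cum, self.vertices[:, 1])
        return np.column_stack([xs, ys])

    def normal_at(self, arcs: np.ndarray) -> np.ndarray:
        """Unit normals to the path at the given arc lengths."""
        arcs = np.asarray(arcs, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self._seg_lengths)])
        idx = np.clip(np.searchsorted(cum, arcs, side="right") - 1, 0,
                      len(self._seg_lengths) - 1)
        tang = np.diff(self.vertices, axis=0)[idx]
        tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
        return np.column_stack([-tang[:, 1], tang[:, 0]])

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {"vertices_um": self.vertices.tolist()}
        if self.growth_cone_boundary is not None:
            d["growth_cone_boundary_um"] = self.growth_cone_boundary
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "AxonPath":
        d = json.loads(text)
        return cls(np.asarray(d["vertices_um"], dtype=float),
                   d.get("growth_cone_boundary_um"))

    @classmethod
    def from_csv(cls, path, pixel_size: float = 1.0,
                 growth_cone_boundary: float | None = None) -> "AxonPath":
        """Read a two-column (x, y) polyline; ``pixel_size`` converts
        pixel-unit annotations to um (use 1.0 for um-calibrated files)."""
        df = pd.read_csv(path)
        v = df.iloc[:, :2].to_numpy(dtype=float) * pixel_size
        return cls(v, growth_cone_boundary)


def distal_sampling_window(path: AxonPath,
                           window: float = DISTAL_WINDOW_UM,
                           fallback: float = GROWTH_CONE_FALLBACK_UM,
                           ) -> tuple[float, float]:
    """Distal sampling interval ``[start, stop)`` in arc length (um).

    The window is ``window`` um of axon shaft ending at the growth-cone
    neck.  When no neck is annotated, the distal ``fallback`` um of the
    path are treated as the growth cone and excluded.
    """
    if path.growth_cone_boundary is not None:
        stop = path.growth_cone_boundary
    else:
        stop = path.length - fallback
    start = stop - window
    if start <= 0:
        raise PathError(
            f"path of {path.length:.1f} um too short for a {window:.0f} um "
            "distal window plus growth-cone exclusion")
    return (start, stop)


# ---------------------------------------------------------------------------
# frame series
# ---------------------------------------------------------------------------

def estimate_background(values: np.ndarray) -> tuple[float, float]:
    """Robust per-frame background (mean, SD) from off-mitochondria pixels.

    Mitochondria occupy a minority of the axon, so the median and the
    median absolute deviation of the profile characterise the background;
    pixels within 3 robust SDs of the median are averaged.
    """
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med))) * 1.4826
    bg = v[v <= med + 3.0 * mad]
    if bg.size == 0:  # pragma: no cover - median guarantees nonempty
        bg = v
    return float(bg.mean()), float(bg.std())


@dataclass
class AxonFrameSeries:
    """Arc-length-indexed intensity profiles for one axon and channel.

    ``data`` has shape ``(n_frames, n_samples)`` with uniform sampling at
    ``pixel_size`` um; sample *i* covers ``[i, i+1) * pixel_size``.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = "mito"
    raw: np.ndarray | None = None
    _bg: dict = field(default_factory=dict, repr=False)
    _amplitude: float | None = field(default=None, repr=False)
    _plateau_ref: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("series data must be (n_frames, n_samples)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def length(self) -> float:
        """Sampled axon length in um."""
        return self.n_samples * self.pixel_size

    @property
    def positions(self) -> np.ndarray:
        """Arc-length sample centres in um."""
        return (np.arange(self.n_samples) + 0.5) * self.pixel_size

    def profile(self, frame: int) -> np.ndarray:
        if not 0 <= frame < self.n_frames:
            raise IndexError(f"frame {frame} out of range 0..{self.n_frames - 1}")
        return self.data[frame]

    def background(self, frame: int) -> tuple[float, float]:
        """Cached per-frame background (mean, SD)."""
        if frame not in self._bg:
            self._bg[frame] = estimate_background(self.profile(frame))
        return self._bg[frame]

    def amplitude(self) -> float:
        """Series dynamic range: max intensity minus typical background."""
        if self._amplitude is None:
            bg = float(np.median(self.data))
            self._amplitude = max(float(self.data.max()) - bg, 0.0)
        return self._amplitude

    def threshold(self, frame: int, k_sigma: float = K_SIGMA) -> float:
        """Segmentation threshold: background + k*sigma with a dynamic-range
        floor so the noise-free limit (sigma == 0) stays well defined."""
        mean, sd = self.background(frame)
        return mean + max(k_sigma * sd, RANGE_FLOOR_FRAC * self.amplitude())


# ---------------------------------------------------------------------------
# profile extraction from 2-D stacks
# ---------------------------------------------------------------------------

def extract_profiles(stack: np.ndarray, path: AxonPath, pixel_size: float,
                     frame_interval: float, width: float = 0.72,
                     channel: str = "mito") -> AxonFrameSeries:
    """Reduce a ``(frames, H, W)`` stack to a 1-D arc-length series.

    For each arc-length sample the intensity is the maximum over a transect
    of +-``width``/2 um perpendicular to the path (bilinear interpolation).

    Raises
    ------
    PathError
        If any transect point falls outside the image bounds.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    n_frames, H, W = stack.shape
    arcs = np.arange(pixel_size / 2, path.length, pixel_size)
    pts = path.point_at(arcs)          # (N, 2) x, y um
    nrm = path.normal_at(arcs)
    n_off = max(1, int(round(width / pixel_size)) + 1)
    offsets = np.linspace(-width / 2, width / 2, n_off) if n_off > 1 else np.zeros(1)
    # (N, n_off, 2) sample points in pixel coordinates (centre convention)
    sample = pts[:, None, :] + offsets[None, :, None] * nrm[:, None, :]
    cols = sample[..., 0] / pixel_size - 0.5
    rows = sample[..., 1] / pixel_size - 0.5
    if (cols.min() < -0.5 or cols.max() > W - 0.5
            or rows.min() < -0.5 or rows.max() > H - 0.5):
        raise PathError("axon path (plus transect width) exits image bounds "
                        "(frame 0)")
    coords = np.vstack([rows.ravel(), cols.ravel()])
    data = np.empty((n_frames, len(arcs)))
    for f in range(n_frames):
        vals = ndimage.map_coordinates(stack[f].astype(float), coords,
                                       order=1, mode="nearest")
        data[f] = vals.reshape(len(arcs), n_off).max(axis=1)
    return AxonFrameSeries(data, pixel_size, frame_interval, channel=channel)


# ---------------------------------------------------------------------------
# per-frame segmentation
# ---------------------------------------------------------------------------

@dataclass
class MitoSegment:
    """One mitochondrion in one frame: a half-open interval in arc length."""

    frame: int
    start: float
    end: float
    mean_intensity: float
    plateau: float
    excluded_overlap: bool = False

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def centre(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlap(self, other: "MitoSegment") -> float:
        return max(0.0, min(self.end, other.end) - max(self.start, other.start))


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (first, last) inclusive index pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _half_crossing(v: np.ndarray, centres: np.ndarray, i0: int, i1: int,
                   half: float, px: float) -> tuple[float, float]:
    """Sub-pixel endpoints of run [i0, i1] at the half-plateau level."""
    seg = v[i0:i1 + 1]
    above = np.flatnonzero(seg >= half)
    j0, j1 = i0 + above[0], i0 + above[-1]
    if j0 > 0 and v[j0] > v[j0 - 1]:
        frac = (half - v[j0 - 1]) / (v[j0] - v[j0 - 1])
        start = centres[j0 - 1] + frac * px
    else:
        start = centres[j0] - 0.5 * px
    if j1 < len(v) - 1 and v[j1] > v[j1 + 1]:
        frac = (v[j1] - half) / (v[j1] - v[j1 + 1])
        end = centres[j1] + frac * px
    else:
        end = centres[j1] + 0.5 * px
    return start, end


def reference_plateau(series: AxonFrameSeries) -> float:
    """Median plateau intensity of candidate segments over the whole series.

    Used as the single-mitochondrion reference when flagging additive
    (spatially overlapping) segments.
    """
    if series._plateau_ref is None:
        plateaus = []
        for f in range(series.n_frames):
            thr = series.threshold(f)
            for i0, i1 in _runs_above(series.data[f] > thr):
                if i1 - i0 + 1 >= MIN_SEGMENT_PIXELS:
                    plateaus.append(series.data[f, i0:i1 + 1].max())
        series._plateau_ref = float(np.median(plateaus)) if plateaus else np.inf
    return series._plateau_ref


def segment_mitochondria(series: AxonFrameSeries, frame: int,
                         k_sigma: float = K_SIGMA,
                         ref_plateau: float | None = None,
                         ) -> list[MitoSegment]:
    """Segment mitochondria in one frame of the series.

    Maximal runs of samples above background + ``k_sigma`` * SD form
    candidate segments; endpoints are refined to the half-plateau crossing
    with linear interpolation, which recovers the physical extent of a
    PSF-blurred uniform interval to sub-pixel accuracy.  Segments whose
    plateau exceeds :data:`OVERLAP_PLATEAU_FACTOR` times the reference
    plateau are flagged ``excluded_overlap`` (additive fluorescence of
    spatially overlapping mitochondria); they remain in the output so the
    caller can count them for density while excluding them from length
    statistics.
    """
    v = series.profile(frame)
    bg_mean, _ = series.background(frame)
    thr = series.threshold(frame, k_sigma)
    px = series.pixel_size
    centres = series.positions
    if ref_plateau is None:
        ref_plateau = reference_plateau(series)
    out: list[MitoSegment] = []
    for i0, i1 in _runs_above(v > thr):
        if i1 - i0 + 1 < MIN_SEGMENT_PIXELS:
            continue
        plateau = float(v[i0:i1 + 1].max())
        half = bg_mean + 0.5 * (plateau - bg_mean)
        start, end = _half_crossing(v, centres, i0, i1, half, px)
        if end - start < MIN_SEGMENT_PIXELS * px:
            continue
        out.append(MitoSegment(
            frame=frame, start=start, end=end,
            mean_intensity=float(v[i0:i1 + 1].mean()) - bg_mean,
            plateau=plateau,
            excluded_overlap=bool(plateau > OVERLAP_PLATEAU_FACTOR * ref_plateau),
        ))
    return out


def segment_series(series: AxonFrameSeries, k_sigma: float = K_SIGMA,
                   ) -> list[list[MitoSegment]]:
    """Segment every frame; convenience wrapper for the linking stage."""
    ref = reference_plateau(series)
    return [segment_mitochondria(series, f, k_sigma, ref)
            for f in range(series.n_frames)]


# ---------------------------------------------------------------------------
# frame-to-frame linking
# ---------------------------------------------------------------------------

@dataclass
class MitoTrack:
    """A mitochondrion's segments through time, with lineage hooks."""

    id: int
    segments: list[MitoSegment] = field(default_factory=list)
    parent_ids: list[int] = field(default_factory=list)
    child_ids: list[int] = field(default_factory=list)

    @property
    def birth_frame(self) -> int:
        return self.segments[0].frame

    @property
    def death_frame(self) -> int:
        return self.segments[-1].frame

    @property
    def n_frames(self) -> int:
        return len(self.segments)

    def frame_index(self) -> np.ndarray:
        return np.array([s.frame for s in self.segments])

    def interval_array(self) -> np.ndarray:
        return np.array([[s.start, s.end] for s in self.segments])

    def interval_at(self, frame: int) -> tuple[float, float] | None:
        if self.birth_frame <= frame <= self.death_frame:
            s = self.segments[frame - self.birth_frame]
            return (s.start, s.end)
        return None

    def segment_at(self, frame: int) -> MitoSegment | None:
        if self.birth_frame <= frame <= self.death_frame:
            return self.segments[frame - self.birth_frame]
        return None


@dataclass
class LinkCandidate:
    """A 1->2 (split) or 2->1 (merge) linking event awaiting confirmation."""

    kind: str                 # "split" | "merge"
    frame: int                # first frame of the new configuration
    parent_tracks: list[int]
    child_tracks: list[int]


def link_tracks(per_frame: Sequence[Sequence[MitoSegment]],
                max_jump: float = 2.5,
                candidate_reach: float = 1.5,
                ) -> tuple[list[MitoTrack], list[LinkCandidate]]:
    """Link per-frame segments into tracks by maximal interval overlap.

    Ties break on smaller mean-intensity difference, making assignment
    deterministic.  Segments left unmatched by the overlap pass are matched
    by nearest centre within ``max_jump`` um (fast-moving mitochondria can
    displace more than their own length between frames).  Remaining
    unmatched segments open or close tracks; a new segment appearing within
    ``candidate_reach`` um of a continuing track is recorded as a split
    candidate and a dying track ending near a continuing one as a merge
    candidate, for confirmation by the event-calling stage.
    """
    tracks: list[MitoTrack] = []
    candidates: list[LinkCandidate] = []
    active: dict[int, MitoSegment] = {}     # track id -> segment in prev frame

    def new_track(seg: MitoSegment) -> int:
        tid = len(tracks)
        tracks.append(MitoTrack(id=tid, segments=[seg]))
        return tid

    for seg in per_frame[0] if per_frame else []:
        active[new_track(seg)] = seg

    for f in range(1, len(per_frame)):
        prev = list(active.items())
        cur = list(per_frame[f])
        pairs = []
        for ti, (tid, pseg) in enumerate(prev):
            for cj, cseg in enumerate(cur):
                ov = pseg.overlap(cseg)
                gap = abs(pseg.centre - cseg.centre)
                if ov > 0:
                    pairs.append((-ov, abs(pseg.mean_intensity
                                           - cseg.mean_intensity), ti, cj))
                elif gap <= max_jump:
                    # no overlap: rank below all overlap pairs, by distance
                    pairs.append((gap, abs(pseg.mean_intensity
                                           - cseg.mean_intensity), ti, cj))
        pairs.sort()
        used_p: set[int] = set()
        used_c: set[int] = set()
        assign: dict[int, int] = {}         # cur index -> track id
        for _, _, ti, cj in pairs:
            if ti in used_p or cj in used_c:
                continue
            used_p.add(ti)
            used_c.add(cj)
            assign[cj] = prev[ti][0]

        next_active: dict[int, MitoSegment] = {}
        matched_tids = set(assign.values())
        # continuing tracks
        for cj, tid in assign.items():
            tracks[tid].segments.append(cur[cj])
            next_active[tid] = cur[cj]
        # unmatched current segments -> new tracks, possibly split candidates
        for cj, cseg in enumerate(cur):
            if cj in used_c:
                continue
            tid = new_track(cseg)
            next_active[tid] = cseg
            best = None
            for pt, (ptid, pseg) in enumerate(prev):
                if ptid not in matched_tids:
                    continue
                reach = max(0.0, max(pseg.start - cseg.end,
                                     cseg.start - pseg.end))
                if reach <= candidate_reach and (best is None or reach < best[0]):
                    best = (reach, ptid)
            if best is not None:
                # the parent track continues as one child of the split
                ptid = best[1]
                candidates.append(LinkCandidate(
                    "split", f, [ptid], sorted([ptid, tid])))
                tracks[ptid].child_ids.append(tid)
                tracks[tid].parent_ids.append(ptid)
        # unmatched previous tracks -> closed, possibly merge candidates
        for ptid, pseg in prev:
            if ptid in matched_tids or ptid not in active:
                continue
            best = None
            for cj, cseg in enumerate(cur):
                if cj not in assign:
                    continue
                reach = max(0.0, max(pseg.start - cseg.end,
                                     cseg.start - pseg.end))
                if reach <= max(candidate_reach, max_jump) and (
                        best is None or reach < best[0]):
                    best = (reach, assign[cj])
            if best is not None:
                mtid = best[1]
                candidates.append(LinkCandidate(
                    "merge", f, sorted([ptid, mtid]), [mtid]))
                tracks[ptid].child_ids.append(mtid)
                tracks[mtid].parent_ids.append(ptid)
        active = next_active

    return tracks, candidates


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

def measure_density(segments: Sequence[MitoSegment],
                    sampled_length: float) -> float:
    """Mitochondria per 10 um of sampled axon.

    Overlap-flagged segments count toward density (each still marks at
    least one mitochondrion) even though they are excluded from length
    statistics; see :func:`length_statistics`.
    """
    if sampled_length <= 0:
        raise ValueError("sampled_length must be positive")
    return 10.0 * len(segments) / sampled_length


def length_statistics(segments: Sequence[MitoSegment]) -> dict:
    """Mean/median length over segments, excluding overlap-flagged ones."""
    lengths = np.array([s.length for s in segments if not s.excluded_overlap])
    if lengths.size == 0:
        return {"n": 0, "mean_um": np.nan, "median_um": np.nan,
                "sem_um": np.nan}
    return {"n": int(lengths.size),
            "mean_um": float(lengths.mean()),
            "median_um": float(np.median(lengths)),
            "sem_um": float(lengths.std(ddof=1) / np.sqrt(lengths.size))
            if lengths.size > 1 else np.nan}


def branch_density(projection_lengths: Sequence[float],
                   axon_length: float) -> float:
    """Branches per 100 um of axon.

    A projection counts as a branch only if strictly longer than
    :data:`BRANCH_MIN_UM` (10 um); a 10.0 um projection is not a branch.
    """
    if axon_length <= 0:
        raise ValueError("axon_length must be positive")
    if any(l < 0 for l in projection_lengths):
        raise ValueError("projection lengths must be non-negative")
    n = sum(1 for l in projection_lengths if l > BRANCH_MIN_UM)
    return 100.0 * n / axon_length


def mito_mass(mean_length: float, density_per_10um: float) -> float:
    """Dimensionless mitochondrial mass index: mean length x density/10 um."""
    if mean_length < 0 or density_per_10um < 0:
        raise ValueError("inputs must be non-negative")
    return mean_length * density_per_10um


def segments_to_frame(segments: Sequence[Sequence[MitoSegment]]) -> pd.DataFrame:
    """Flatten per-frame segments into a tidy table (CSV-ready)."""
    rows = [{"frame": s.frame, "start_um": s.start, "end_um": s.end,
             "length_um": s.length, "mean_intensity": s.mean_intensity,
             "excluded_overlap": s.excluded_overlap}
            for frame in segments for s in frame]
    return pd.DataFrame(rows, columns=["frame", "start_um", "end_um",
                                       "length_um", "mean_intensity",
                                       "excluded_overlap"])


def tracks_to_frame(tracks: Sequence[MitoTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for s in t.segments:
            rows.append({"track_id": t.id, "frame": s.frame,
                         "start_um": s.start, "end_um": s.end,
                         "length_um": s.length})
    return pd.DataFrame(rows, columns=["track_id", "frame", "start_um",
                                       "end_um", "length_um"])
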