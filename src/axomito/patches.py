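"""Actin patches, Drp1 puncta, and the random-overlap probability statistic.

Transient local elevations in the actin (or Drp1) channel are detected as
patch records, classified by their spatial relationship to mitochondria
and fission sites, and summarised.  The headline statistic asks: if
fission sites were placed at random along their mitochondria, how likely
is it that *every* observed site would have landed inside an actin patch?
For each fission event the per-row chance of random overlap is
``C = B / A`` where ``A`` is the parent mitochondrion length and ``B`` the
summed length of actin patches on it at the first frame where fission is
evident; the joint probability across independent events is the product of
the ``C`` values, accumulated in log space.

Two dialects of the product are reported: ``full`` multiplies the exact
``B/A`` ratios, while ``rounded`` first rounds each ``C`` to two decimals —
the convention used when the proportions are tabulated to two decimal
places before multiplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kymo import AxonFrameSeries, _half_crossing, _runs_above

PATCH_CLASSES = ("fission_associated", "mito_associated", "non_mito")

#: a transient elevation must persist at least this many frames
PATCH_MIN_FRAMES = 2
#: default patch-to-event association window (s): the call frame +- 1 frame
ASSOC_WINDOW_S = 3.0


@dataclass
class PatchRecord:
    """A detected actin patch or Drp1 accumulation."""

    channel: str               # "actin" | "drp1"
    onset: int
    offset: int
    start: float               # um, extent at the peak frame
    end: float
    peak_frame: int
    peak_intensity: float
    frame_interval: float
    cls: str | None = None
    filopodium: bool | None = None

    @property
    def position(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def extent(self) -> float:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset + 1) * self.frame_interval

    def active(self, frame: int, slop: int = 0) -> bool:
        return self.onset - slop <= frame <= self.offset + slop


def detect_patches(series: AxonFrameSeries, k_sigma: float = 3.0,
                   min_frames: int = PATCH_MIN_FRAMES) -> list[PatchRecord]:
    """Detect transient supra-threshold elevations lasting >= 2 frames.

    Per-frame spans above background + k*sigma, refined to their half-peak
    crossings (which undoes the PSF widening of the thresholded footprint),
    are linked across frames by spatial overlap; each linked group becomes
    one record whose extent is the refined span at its brightest frame.
    Single-frame flickers are rejected.
    """
    px = series.pixel_size
    centres = series.positions

    def frame_spans(f: int) -> list[tuple[float, float, float]]:
        v = series.profile(f)
        bg_mean, _ = series.background(f)
        thr = series.threshold(f, k_sigma)
        out = []
        for i0, i1 in _runs_above(v > thr):
            peak = float(v[i0:i1 + 1].max())
            half = bg_mean + 0.5 * (peak - bg_mean)
            s, e = _half_crossing(v, centres, i0, i1, half, px)
            out.append((s, e, peak - bg_mean))
        return out

    active: list[dict] = []    # {'spans': [(frame, start, end, peak)], ...}
    done: list[dict] = []
    for f in range(series.n_frames):
        spans = frame_spans(f)
        matched_new: set[int] = set()
        still: list[dict] = []
        for patch in active:
            _, ps, pe, _ = patch["spans"][-1]
            hit = None
            for k, (s, e, _) in enumerate(spans):
                if k not in matched_new and s < pe and e > ps:
                    hit = k
                    break
            if hit is None:
                done.append(patch)
            else:
                matched_new.add(hit)
                patch["spans"].append((f, *spans[hit]))
                still.append(patch)
        for k, (s, e, pk) in enumerate(spans):
            if k not in matched_new:
                still.append({"spans": [(f, s, e, pk)]})
        active = still
    done.extend(active)
    out = []
    for patch in done:
        spans = patch["spans"]
        if len(spans) < min_frames:
            continue
        k = int(np.argmax([pk for _, _, _, pk in spans]))
        f, s, e, pk = spans[k]
        out.append(PatchRecord(
            channel=series.channel, onset=spans[0][0], offset=spans[-1][0],
            start=s, end=e, peak_frame=f, peak_intensity=pk,
            frame_interval=series.frame_interval))
    out.sort(key=lambda p: (p.onset, p.start))
    return out


def classify_patches(patches: Sequence, tracks: Sequence,
                     fission_events: Sequence,
                     window_s: float = ASSOC_WINDOW_S,
                     frame_interval: float | None = None) -> list:
    """Assign each patch to fission_associated / mito_associated / non_mito.

    A patch is fission-associated when its extent contains a fission
    position and the event frame falls within +-``window_s`` of the patch
    lifetime; otherwise mito-associated when its extent overlaps any
    mitochondrion footprint while the patch is alive; otherwise
    non-mitochondrial.  Classification is in place; the list is returned.
    """
    if frame_interval is None:
        frame_interval = getattr(patches[0], "frame_interval", None) \
            if patches else None
    slop = int(round(window_s / frame_interval)) if frame_interval else 1
    for p in patches:
        cls = None
        for e in fission_events:
            frame = e.frame if hasattr(e, "frame") else e["frame"]
            pos = e.position if hasattr(e, "position") else e["position"]
            if p.start <= pos <= p.end and \
                    p.onset - slop <= frame <= p.offset + slop:
                cls = "fission_associated"
                break
        if cls is None:
            for t in tracks:
                for f in range(p.onset, p.offset + 1):
                    iv = t.interval_at(f)
                    if iv and min(iv[1], p.end) > max(iv[0], p.start):
                        cls = "mito_associated"
                        break
                if cls:
                    break
        p.cls = cls or "non_mito"
    return list(patches)


def patch_fate_stats(patches: Sequence) -> dict:
    """Per-class filopodium probability with pairwise Fisher exact tests.

    Patches whose fate is unknown (``filopodium is None``) are ignored;
    a class with no scored patches reports a missing proportion.
    """
    counts = {c: [0, 0] for c in PATCH_CLASSES}      # [filopodia, total]
    for p in patches:
        if p.cls in counts and p.filopodium is not None:
            counts[p.cls][1] += 1
            counts[p.cls][0] += int(p.filopodium)
    props = {c: (k / n if n else None) for c, (k, n) in counts.items()}
    pairwise = {}
    classes = list(PATCH_CLASSES)
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            (ka, na), (kb, nb) = counts[a], counts[b]
            if na and nb:
                table = [[ka, na - ka], [kb, nb - kb]]
                pairwise[(a, b)] = float(sps.fisher_exact(table)[1])
            else:
                pairwise[(a, b)] = None
    return {"counts": counts, "probabilities": props,
            "fisher_pairwise": pairwise}


# ---------------------------------------------------------------------------
# the overlap table and its probability product
# ---------------------------------------------------------------------------

def _interval_union_length(spans: list[tuple[float, float]]) -> float:
    if not spans:
        return 0.0
    spans = sorted(spans)
    total, cur_s, cur_e = 0.0, spans[0][0], spans[0][1]
    for s, e in spans[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


@dataclass
class OverlapTable:
    """Per-fission-event rows (A, B, C = B/A) and their summaries.

    A is the mitochondrion length (um), B the summed length of actin
    patches on it at the time of fission (patch extents clipped to the
    mitochondrion, overlaps merged so B <= A), and C the proportion of the
    mitochondrion occupied by patches — the chance that a uniformly random
    fission site would overlap a patch.
    """

    table: pd.DataFrame

    COLUMNS = ("mito_length_um", "patch_length_um", "proportion")

    @classmethod
    def from_lengths(cls, mito_lengths: Sequence[float],
                     patch_lengths: Sequence[float]) -> "OverlapTable":
        A = np.asarray(mito_lengths, dtype=float)
        B = np.asarray(patch_lengths, dtype=float)
        if A.shape != B.shape:
            raise ValueError("length arrays must match")
        if np.any(B > A + 1e-9):
            raise ValueError("summed patch length exceeds mitochondrion "
                             "length; clip patch extents first")
        df = pd.DataFrame({"mito_length_um": A, "patch_length_um": B,
                           "proportion": B / A})
        df["proportion_2dp"] = df["proportion"].round(2)
        return cls(df)

    def summary(self) -> dict:
        A = self.table["mito_length_um"].to_numpy()
        B = self.table["patch_length_um"].to_numpy()
        sem = lambda v: float(v.std(ddof=1) / np.sqrt(len(v))) \
            if len(v) > 1 else float("nan")
        return {"n": len(A),
                "mean_mito_length_um": float(A.mean()),
                "sem_mito_length_um": sem(A),
                "mean_patch_length_um": float(B.mean()),
                "sem_patch_length_um": sem(B)}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_overlap_table(fission_events: Sequence, patches: Sequence,
                        tracks_by_id: dict) -> OverlapTable:
    """One (A, B, C) row per fission event.

    A is the parent length in the last frame before the split; B sums the
    extents of actin patches active at the call frame, clipped to the
    parent interval with overlaps merged.
    """
    A_list, B_list = [], []
    for e in fission_events:
        frame = e.frame if hasattr(e, "frame") else e["frame"]
        pid = (e.parent_ids if hasattr(e, "parent_ids") else e["parents"])[0]
        parent = tracks_by_id[pid]
        iv = parent.interval_at(parent.death_frame
                                if hasattr(parent, "death_frame")
                                and parent.death_frame is not None
                                else frame - 1)
        if iv is None:
            iv = parent.interval_at(frame - 1)
        if iv is None:
            continue
        a, b = iv
        spans = [(max(p.start, a), min(p.end, b)) for p in patches
                 if p.channel == "actin" and p.active(frame, slop=1)
                 and min(p.end, b) > max(p.start, a)]
        A_list.append(b - a)
        B_list.append(_interval_union_length(spans))
    return OverlapTable.from_lengths(A_list, B_list)


@dataclass(frozen=True)
class OverlapProbability:
    rounded: float             # two-decimal-proportion dialect
    full: float                # exact B/A proportions
    log10_rounded: float
    log10_full: float


def random_overlap_probability(table: OverlapTable) -> OverlapProbability:
    """Probability that every fission site overlapped a patch by chance.

    The product of the per-row proportions is accumulated in log space to
    avoid underflow; both the exact and the two-decimal-rounded dialects
    are returned.  Any zero proportion makes the product zero (an observed
    overlap with zero patch coverage is contradictory) with a warning.
    """
    out = {}
    for name, col in (("full", "proportion"), ("rounded", "proportion_2dp")):
        c = table.table[col].to_numpy(dtype=float)
        if np.any((c < 0) | (c > 1 + 1e-12)):
            raise ValueError("proportions must lie in [0, 1]")
        if np.any(c == 0):
            warnings.warn("zero overlap proportion in a row with an "
                          "observed overlap; product set to 0")
            out[name] = (0.0, -np.inf)
        else:
            log10 = float(np.sum(np.log10(c)))
            out[name] = (float(10.0 ** log10), log10)
    return OverlapProbability(rounded=out["rounded"][0], full=out["full"][0],
                              log10_rounded=out["rounded"][1],
                              log10_full=out["full"][1])


def colocalization_fraction(fission_events: Sequence,
                            patches: Sequence) -> float:
    """Fraction of fission sites lying inside a patch at the call frame."""
    if not fission_events:
        raise ValueError("no fission events")
    n_hit = 0
    for e in fission_events:
        frame = e.frame if hasattr(e, "frame") else e["frame"]
        pos = e.position if hasattr(e, "position") else e["position"]
        n_hit += any(p.channel == "actin" and p.active(frame, slop=1)
                     and p.start <= pos <= p.end for p in patches)
    return n_hit / len(fission_events)


def drp1_accumulations_per_mito(puncta: Sequence, tracks: Sequence,
                                window_s: float,
                                frame_interval: float) -> dict:
    """Drp1 accumulations per mitochondrion, normalised to 10 min.

    Counts puncta whose extent overlaps the track's interval at the
    punctum onset, for onsets within the window; each track's count is
    scaled by 600 s / window.
    """
    if not tracks:
        raise ValueError("no tracks")
    window_frames = int(round(window_s / frame_interval))
    counts = []
    for t in tracks:
        n = 0
        for p in puncta:
            if p.channel != "drp1" or p.onset > window_frames:
                continue
            iv = t.interval_at(p.onset)
            if iv and min(iv[1], p.end) > max(iv[0], p.start):
                n += 1
        counts.append(n * 600.0 / window_s)
    arr = np.asarray(counts, dtype=float)
    return {"per_track": arr, "mean": float(arr.mean()),
            "n_tracks": len(arr)}


def patches_to_frame(patches: Sequence) -> pd.DataFrame:
    rows = [{"channel": p.channel, "onset": p.onset, "offset": p.offset,
             "start_um": p.start, "end_um": p.end,
             "duration_s": p.duration_s, "class": p.cls,
             "filopodium": p.filopodium}
            for p in patches]
    return pd.DataFrame(rows, columns=["channel", "onset", "offset",
                                       "start_um", "end_um", "duration_s",
                                       "class", "filopodium"])
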