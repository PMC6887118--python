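"""Immunofluorescence intensity quantification and FRAP recovery."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class FrapExclusion(ValueError):
    """A FRAP trace that fails an inclusion rule."""


@dataclass(frozen=True)
class RoiMeasurement:
    """Background-subtracted integrated intensity of a region of interest.

    ``total_integrated = area_px * max(mean - background, 0)``: the ROI
    area multiplied by the background-subtracted mean intensity.
    """

    area_px: int
    area_um2: float
    mean_intensity: float
    background_mean: float
    total_integrated: float


def roi_background(values: np.ndarray) -> float:
    """Background estimate from a stain-free region: the median, which
    resists bright outliers."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty background region")
    return float(np.median(values))


def integrated_intensity(roi_pixels: np.ndarray, background: float,
                         pixel_size: float = 1.0) -> RoiMeasurement:
    """Total integrated fluorescence of an ROI above background.

    A negative background-subtracted mean clips to zero with a warning
    (the stain cannot remove signal).
    """
    v = np.asarray(roi_pixels, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    mean = float(v.mean())
    net = mean - background
    if net < 0:
        warnings.warn("ROI mean below background; total clipped to 0")
        net = 0.0
    return RoiMeasurement(
        area_px=int(v.size),
        area_um2=float(v.size * pixel_size ** 2),
        mean_intensity=mean,
        background_mean=float(background),
        total_integrated=float(v.size * net))


#: a trace qualifies only when bleached to <= 10 % of its pre-bleach value
BLEACH_INCLUSION_FRAC = 0.10


@dataclass
class FRAPTrace:
    """A fluorescence-recovery-after-photobleaching time course.

    Intensities are background-subtracted means over a fixed-length axon
    segment: before bleaching, immediately after (t = 0), and at the
    subsequent timepoints (typically 5-min intervals).
    """

    pre_bleach: float
    post_bleach: float
    times_s: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise ValueError("times and intensities must align")

    @property
    def include(self) -> bool:
        """True when photobleaching removed at least 90 % of the signal."""
        return self.post_bleach <= BLEACH_INCLUSION_FRAC * self.pre_bleach


def frap_recovery(trace: FRAPTrace) -> np.ndarray:
    """Percent recovery from the t = 0 value toward the pre-bleach value.

    ``100 * (I_t - I_0) / (I_pre - I_0)`` per timepoint.  Raises
    :class:`FrapExclusion` for traces bleached by less than 90 % or with a
    degenerate denominator.
    """
    if not trace.include:
        raise FrapExclusion(
            f"bleached to {100 * trace.post_bleach / trace.pre_bleach:.0f}% "
            "of baseline; inclusion requires <= 10%")
    denom = trace.pre_bleach - trace.post_bleach
    if denom <= 0:
        raise FrapExclusion("pre-bleach equals post-bleach; recovery undefined")
    return 100.0 * (trace.intensities - trace.post_bleach) / denom


def frap_table(traces: dict[str, FRAPTrace]) -> pd.DataFrame:
    """Recovery per timepoint for a set of traces; excluded traces are
    reported with their exclusion reason instead of values."""
    rows = []
    for name, tr in traces.items():
        try:
            rec = frap_recovery(tr)
            for t, r in zip(tr.times_s, rec):
                rows.append({"trace": name, "time_s": t,
                             "recovery_pct": r, "excluded": ""})
        except FrapExclusion as exc:
            rows.append({"trace": name, "time_s": np.nan,
                         "recovery_pct": np.nan, "excluded": str(exc)})
    return pd.DataFrame(rows, columns=["trace", "time_s", "recovery_pct",
                                       "excluded"])
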