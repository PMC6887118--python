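"""Batch orchestration: configuration, I/O and the full per-axon analysis.

``analyze_series`` runs the in-memory chain (segmentation -> linking ->
event calling -> motility -> patches) on one axon's profile series;
``run_pipeline`` wraps it with file I/O, per-axon error isolation and a
provenance log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from . import events as ev
from . import kymo, motility as mot, patches as pt

log = logging.getLogger("axomito")


class ManifestError(ValueError):
    """Raised when an analysis manifest fails validation."""


@dataclass
class AxonInput:
    """One axon's inputs: a mitochondria stack, optional extra channels,
    and a path annotation."""

    mito_stack: str
    path_file: str
    pixel_size: float
    frame_interval: float
    actin_stack: str | None = None
    drp1_stack: str | None = None
    name: str | None = None


@dataclass
class AnalysisConfig:
    axons: list[AxonInput]
    out_dir: str
    seed: int = 0
    transect_width: float = 0.72       # um
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.axons:
            raise ManifestError("empty manifest: no axons to analyze")
        for ax in self.axons:
            for f in (ax.mito_stack, ax.path_file, ax.actin_stack,
                      ax.drp1_stack):
                if f is not None and not Path(f).exists():
                    raise ManifestError(f"input file not found: {f}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        axons = [AxonInput(**a) for a in d.pop("axons", [])]
        return cls(axons=axons, **d)


def analyze_series(mito: kymo.AxonFrameSeries,
                   actin: kymo.AxonFrameSeries | None = None,
                   drp1: kymo.AxonFrameSeries | None = None) -> dict:
    """Run the full analysis chain on one axon's profile series.

    Returns a result bundle: segments, tracks, fission/fusion events,
    motility records, patch records, and (when an actin channel is
    present) the overlap table with its probability product.
    """
    segments = kymo.segment_series(mito)
    tracks, candidates = kymo.link_tracks(segments)
    fissions = ev.detect_fission(tracks, candidates, mito)
    fusions = ev.detect_fusion(tracks, candidates, mito)
    records = [mot.classify_motility(t, series=mito) for t in tracks]
    result: dict = {
        "series": mito, "segments": segments, "tracks": tracks,
        "candidates": candidates, "fission_events": fissions,
        "fusion_events": fusions, "motility": records,
    }
    all_patches: list = []
    if actin is not None:
        actin_patches = pt.detect_patches(actin)
        pt.classify_patches(actin_patches, tracks, fissions,
                            frame_interval=mito.frame_interval)
        all_patches.extend(actin_patches)
        result["actin_patches"] = actin_patches
        if fissions:
            table = pt.build_overlap_table(
                fissions, actin_patches, {t.id: t for t in tracks})
            result["overlap_table"] = table
            if len(table.table):
                result["overlap_probability"] = \
                    pt.random_overlap_probability(table)
    if drp1 is not None:
        puncta = pt.detect_patches(drp1)
        for p in puncta:
            p.cls = None
        all_patches.extend(puncta)
        result["drp1_puncta"] = puncta
    result["patches"] = all_patches
    return result


def summarize_axon(result: dict) -> dict:
    """Per-axon scalar summary of the analysis bundle."""
    series: kymo.AxonFrameSeries = result["series"]
    first = result["segments"][0] if result["segments"] else []
    stats = kymo.length_statistics(first)
    density = kymo.measure_density(first, series.length) if first else 0.0
    n0 = len(first)
    window_s = (series.n_frames - 1) * series.frame_interval
    classes = pd.Series([r.cls for r in result["motility"]])
    out = {
        "n_mito_frame0": n0,
        "mean_length_um": stats["mean_um"],
        "density_per_10um": density,
        "mass_index": (kymo.mito_mass(stats["mean_um"], density)
                       if n0 else 0.0),
        "n_fission": len(result["fission_events"]),
        "n_fusion": len(result["fusion_events"]),
        "fission_rate_pct_per_10min":
            ev.event_rate(result["fission_events"], n0, window_s)
            if n0 else float("nan"),
        "fusion_rate_pct_per_10min":
            ev.event_rate(result["fusion_events"], n0, window_s)
            if n0 else float("nan"),
        "motility_counts": classes.value_counts().to_dict(),
    }
    if "overlap_probability" in result:
        out["overlap_probability_full"] = result["overlap_probability"].full
    return out


def _load_series(path, pixel_size, frame_interval, axon_path, width, channel):
    stack = tifffile.imread(path)
    if stack.ndim == 3 and stack.shape[1] == 1:
        # profile-series fixtures: (frames, 1, width) single-row stacks
        return kymo.AxonFrameSeries(stack[:, 0, :].astype(float),
                                    pixel_size, frame_interval,
                                    channel=channel)
    return kymo.extract_profiles(stack, axon_path, pixel_size,
                                 frame_interval, width=width,
                                 channel=channel)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Analyze every axon in the manifest; write tables and provenance.

    Per-axon failures are logged and skipped; the run fails only when all
    axons fail.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    failures = {}
    for i, ax in enumerate(config.axons):
        name = ax.name or f"axon{i:03d}"
        try:
            apath = kymo.AxonPath.from_json(Path(ax.path_file).read_text()) \
                if ax.path_file.endswith(".json") \
                else kymo.AxonPath.from_csv(ax.path_file)
            mito = _load_series(ax.mito_stack, ax.pixel_size,
                                ax.frame_interval, apath,
                                config.transect_width, "mito")
            actin = (_load_series(ax.actin_stack, ax.pixel_size,
                                  ax.frame_interval, apath,
                                  config.transect_width, "actin")
                     if ax.actin_stack else None)
            drp1 = (_load_series(ax.drp1_stack, ax.pixel_size,
                                 ax.frame_interval, apath,
                                 config.transect_width, "drp1")
                    if ax.drp1_stack else None)
            result = analyze_series(mito, actin, drp1)
            adir = out_dir / name
            adir.mkdir(exist_ok=True)
            kymo.tracks_to_frame(result["tracks"]).to_csv(
                adir / "tracks.csv", index=False)
            ev.events_to_frame(result["fission_events"]
                               + result["fusion_events"]).to_csv(
                adir / "events.csv", index=False)
            mot.runs_table(result["motility"]).to_csv(
                adir / "runs.csv", index=False)
            mot.motility_table(result["motility"]).to_csv(
                adir / "motility.csv", index=False)
            if result["patches"]:
                pt.patches_to_frame(result["patches"]).to_csv(
                    adir / "patches.csv", index=False)
            if "overlap_table" in result:
                result["overlap_table"].to_csv(adir / "overlap_table.csv")
            summaries[name] = summarize_axon(result)
        except Exception as exc:          # noqa: BLE001 - isolate per axon
            log.error("axon %s failed: %s", name, exc)
            failures[name] = str(exc)
    if not summaries:
        raise RuntimeError(f"all {len(config.axons)} axons failed: "
                           f"{failures}")
    provenance = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "params": config.params,
        "inputs": [dataclasses.asdict(a) for a in config.axons],
        "failures": failures,
    }
    (out_dir / "summary.json").write_text(
        json.dumps({"axons": summaries, "provenance": provenance},
                   indent=1, default=_jsonable))
    return {"summaries": summaries, "failures": failures,
            "provenance": provenance}


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
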