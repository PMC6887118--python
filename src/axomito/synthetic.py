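"""Stochastic simulator of axonal mitochondria with microscope-like rendering.

The simulator is the test bed for the whole pipeline: it evolves
mitochondria as intensity-labelled intervals on a continuous 1-D arc-length
axis (run-and-pause bidirectional transport, stochastic fission and fusion),
spawns transient actin patches and Drp1 puncta, and logs exact ground truth
for every event.  A separate renderer discretises the truth onto the pixel
grid, convolves with a Gaussian PSF and applies Poisson-Gaussian noise, so
dynamics stay decoupled from the imaging model.

Model summary
-------------
* Mitochondria are rigid intervals; spatially overlapping intensity is
  additive at render time.
* Fission: a per-frame hazard applied to stationary mitochondria, converted
  from the configured probability per 10 min; the fission site is uniform in
  the parent interior (optionally biased toward actin patches).  Children
  lengths sum exactly to the parent length.  After fission the children
  drift apart to a resolvable gap, and with probability
  ``p_transport_after_fission`` one (or both) child is transported away.
* Fusion: a moving mitochondrion approaching another either commits to
  fusion (merging into a single interval of exactly additive length, with
  intensity redistributed to the length-weighted mean) or halts with a
  >= 1 um gap.  Sub-resolution non-fusion contacts therefore never occur,
  mirroring the experimental practice of only scoring unambiguous events.
* Transport: run-and-pause with uniform velocities, direction switches
  (one Bernoulli draw per run) and shifted-exponential pauses that always
  exceed the 6 s run-termination rule.

All stochastic draws come from substreams of a single seeded generator, so
identical configurations give identical event logs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.special import ndtr

from .kymo import AxonFrameSeries


class ConfigError(ValueError):
    """Raised for simulator configurations that cannot be realised."""


PATCH_CLASSES = ("fission_associated", "mito_associated", "non_mito")


@dataclass
class SimConfig:
    """Study conditions for one synthetic axon.

    Geometry and sampling default to the imaging protocol the pipeline is
    built for: 110 frames at 3 s intervals, 0.12 um pixels.  Kinetic rates
    default to the measured NGF-treated condition (fission of 30% of
    mitochondria per 10 min, transport following 80% of fissions, direction
    switches in 55% of runs).  Transport velocities and pause durations are
    plausible placeholders (0.1-0.6 um/s, mean pause 12 s); the source
    measurements report no numeric values for them.
    """

    # geometry / sampling
    axon_length: float = 80.0           # um
    n_frames: int = 110
    frame_interval: float = 3.0         # s
    pixel_size: float = 0.12            # um
    # mitochondria population
    n_mito: int = 6
    mito_length_dist: tuple[float, float] = (2.0, 0.35)   # lognormal median, shape
    min_mito_length: float = 0.8        # um
    mito_intensity_range: tuple[float, float] = (70.0, 130.0)
    placement_gap: float = 2.0          # um minimum initial edge-to-edge gap
    # event kinetics
    fission_prob_per_10min: float = 0.30
    fusion_prob_per_10min: float = 0.05   # probability a contact opportunity fuses
    p_transport_after_fission: float = 0.80   # per event: >=1 child transported
    p_both_children_transport: float = 0.30
    min_child_length: float = 0.6       # um; fission site keeps this per child
    separation_frames: int = 5
    separation_step: float = 0.1        # um per frame per child while separating
    # transport kinetics
    velocity_range: tuple[float, float] = (0.1, 0.6)      # um/s
    pause_mean_s: float = 12.0          # shifted exponential, minimum 6 s
    run_mean_frames: float = 8.0
    run_switch_prob: float = 0.55
    approach_gap: float = 1.0           # um standoff for non-fusing contacts
    motility_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    oscillation_amplitude: float = 0.45   # um, keeps excursion below 1 um
    oscillation_step: float = 0.3
    oscillation_move_prob: float = 0.7
    # actin patches
    patch_rate: float = 0.05            # patches / um / min
    patch_duration_mean_s: float = 60.0
    patch_length_dist: tuple[float, float] = (0.6, 0.35)
    patch_intensity: float = 100.0
    fission_patch_bias: float = 0.0     # 0 = sites independent of patches
    filopodium_probs: Mapping[str, float] = field(
        default_factory=lambda: {"fission_associated": 0.07,
                                 "mito_associated": 0.40,
                                 "non_mito": 0.10})
    # Drp1 puncta
    drp1_rate_per_mito_per_10min: float = 2.0
    drp1_duration_mean_s: float = 30.0
    drp1_length: float = 0.3
    drp1_intensity: float = 100.0
    # imaging
    psf_sigma: float = 0.15             # um
    background_level: float = 10.0
    noise: tuple[float, float] = (1.0, 2.0)   # (Poisson gain, Gaussian SD)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fission_prob_per_10min", "fusion_prob_per_10min",
                     "p_transport_after_fission", "p_both_children_transport",
                     "run_switch_prob", "fission_patch_bias",
                     "oscillation_move_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.axon_length <= 0 or self.n_frames < 2 or self.n_mito < 0:
            raise ConfigError("invalid geometry")
        if abs(sum(self.motility_fractions) - 1.0) > 1e-9:
            raise ConfigError("motility_fractions must sum to 1")

    @property
    def n_pixels(self) -> int:
        return int(np.ceil(self.axon_length / self.pixel_size))

    @property
    def dt(self) -> float:
        return self.frame_interval

    def per_frame_prob(self, p_per_10min: float) -> float:
        """Convert a probability per 10-min window to a per-frame hazard
        such that 1 - (1 - p_frame)^(600/dt) == p_per_10min."""
        return 1.0 - (1.0 - p_per_10min) ** (self.dt / 600.0)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["filopodium_probs"] = dict(d["filopodium_probs"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        for key in ("mito_length_dist", "mito_intensity_range",
                    "velocity_range", "patch_length_dist", "noise",
                    "motility_fractions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class TrueTrack:
    """Exact trajectory of one mitochondrion between its birth and death."""

    id: int
    root: int                 # lineage root among the window-start population
    birth_frame: int
    intensity: float
    origin: str = "initial"   # initial | fission | fusion
    motility: str = "stalled"
    bounds: list[tuple[float, float]] = field(default_factory=list)
    death_frame: int | None = None
    transported_after_fission: bool = False

    @property
    def length(self) -> float:
        a, b = self.bounds[0]
        return b - a

    def frame_index(self) -> np.ndarray:
        return np.arange(self.birth_frame, self.birth_frame + len(self.bounds))

    def interval_array(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)

    def interval_at(self, frame: int) -> tuple[float, float] | None:
        i = frame - self.birth_frame
        if 0 <= i < len(self.bounds):
            return self.bounds[i]
        return None


@dataclass
class TruePatch:
    """A transient actin patch or Drp1 accumulation (static in space)."""

    channel: str              # actin | drp1
    onset: int
    offset: int
    start: float
    end: float
    cls: str | None = None
    overlaps_fission: bool = False
    filopodium: bool | None = None
    induced: bool = False     # spawned by patch-biased fission

    @property
    def position(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def extent(self) -> float:
        return self.end - self.start

    def active(self, frame: int, slop: int = 0) -> bool:
        return self.onset - slop <= frame <= self.offset + slop


@dataclass
class GroundTruth:
    """Complete event log of one simulated axon."""

    config: SimConfig
    tracks: list[TrueTrack]
    fission_events: list[dict]
    fusion_events: list[dict]
    patches: list[TruePatch]
    n_initial: int

    def track_by_id(self, tid: int) -> TrueTrack:
        return self.tracks[tid]

    def tracks_by_id(self) -> dict[int, TrueTrack]:
        return {t.id: t for t in self.tracks}

    def lineage_root(self, tid: int) -> int:
        return self.tracks[tid].root

    def actin_patches(self) -> list[TruePatch]:
        return [p for p in self.patches if p.channel == "actin"]

    def drp1_puncta(self) -> list[TruePatch]:
        return [p for p in self.patches if p.channel == "drp1"]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": yaml.safe_load(self.config.to_yaml()),
            "n_initial": self.n_initial,
            "tracks": [
                {**dataclasses.asdict(t),
                 "bounds": [[float(a), float(b)] for a, b in t.bounds]}
                for t in self.tracks],
            "fission_events": self.fission_events,
            "fusion_events": self.fusion_events,
            "patches": [dataclasses.asdict(p) for p in self.patches],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        cfg = SimConfig.from_yaml(yaml.safe_dump(d["config"]))
        tracks = []
        for td in d["tracks"]:
            td = dict(td)
            td["bounds"] = [tuple(b) for b in td["bounds"]]
            tracks.append(TrueTrack(**td))
        patches = [TruePatch(**pd_) for pd_ in d["patches"]]
        return cls(cfg, tracks, d["fission_events"], d["fusion_events"],
                   patches, d["n_initial"])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class _Mito:
    """Mutable runtime state; truth is recorded into the TrueTrack."""

    __slots__ = ("track", "a", "length", "state", "refractory_until",
                 "anchor", "phase", "frames_left", "direction", "velocity",
                 "switch_at", "step_index", "forced_run", "sep_patience",
                 "sep_dir", "sib", "will_transport", "alive")

    def __init__(self, track: TrueTrack, a: float, length: float,
                 state: str) -> None:
        self.track = track
        self.a = a
        self.length = length
        self.state = state          # stalled | oscillating | transported | separating
        self.refractory_until = -1
        self.anchor = a + length / 2
        self.phase = "pause"
        self.frames_left = 0
        self.direction = 0
        self.velocity = 0.0
        self.switch_at: int | None = None
        self.step_index = 0
        self.forced_run = False
        self.sep_patience = 0
        self.sep_dir = 0
        self.sib: "_Mito | None" = None
        self.will_transport = False
        self.alive = True

    @property
    def b(self) -> float:
        return self.a + self.length


_EDGE_MARGIN = 0.3   # um standoff from the axon ends
#: siblings separate until their gap is at least this (um); comfortably
#: beyond the 0.6 um completed-fission criterion plus PSF blur
_MIN_SIBLING_GAP = 0.9
#: frames a child keeps trying to separate before giving up
_SEPARATION_PATIENCE = 10


class _Simulator:
    def __init__(self, config: SimConfig) -> None:
        self.cfg = config
        seed = config.seed
        self.rng_dyn = np.random.default_rng([seed, 0])
        self.rng_patch = np.random.default_rng([seed, 1])
        self.rng_drp1 = np.random.default_rng([seed, 2])
        self.rng_fate = np.random.default_rng([seed, 4])
        self.tracks: list[TrueTrack] = []
        self.mitos: list[_Mito] = []
        self.fissions: list[dict] = []
        self.fusions: list[dict] = []
        self.patches: list[TruePatch] = []
        self.no_fuse: set[tuple[int, int]] = set()

    # -- helpers ------------------------------------------------------------

    def _new_track(self, root: int, birth: int, intensity: float,
                   origin: str, motility: str) -> TrueTrack:
        t = TrueTrack(id=len(self.tracks), root=root, birth_frame=birth,
                      intensity=intensity, origin=origin, motility=motility)
        self.tracks.append(t)
        return t

    def _draw_length(self) -> float:
        med, shape = self.cfg.mito_length_dist
        l = float(med * np.exp(self.rng_dyn.normal(0.0, shape)))
        return max(l, self.cfg.min_mito_length)

    def _alive(self) -> list[_Mito]:
        return [m for m in self.mitos if m.alive]

    def _clearance(self, m: _Mito, direction: int) -> float:
        """Free space from m's leading edge to the nearest obstacle."""
        L = self.cfg.axon_length
        if direction > 0:
            edge = m.b
            limit = L - _EDGE_MARGIN
            for o in self._alive():
                if o is not m and o.a >= edge and o.a < limit:
                    limit = o.a
            return limit - edge
        edge = m.a
        limit = _EDGE_MARGIN
        for o in self._alive():
            if o is not m and o.b <= edge and o.b > limit:
                limit = o.b
        return edge - limit

    def _neighbor(self, m: _Mito, direction: int) -> _Mito | None:
        best = None
        for o in self._alive():
            if o is m:
                continue
            if direction > 0 and o.a >= m.b:
                if best is None or o.a < best.a:
                    best = o
            elif direction < 0 and o.b <= m.a:
                if best is None or o.b > best.b:
                    best = o
        return best

    # -- placement ----------------------------------------------------------

    def _place_initial(self) -> None:
        cfg = self.cfg
        lengths = [self._draw_length() for _ in range(cfg.n_mito)]
        occupied = sum(lengths) + (cfg.n_mito - 1) * cfg.placement_gap \
            + 2 * _EDGE_MARGIN if cfg.n_mito else 0.0
        slack = cfg.axon_length - occupied
        if cfg.n_mito and slack < 0:
            raise ConfigError(
                f"axon of {cfg.axon_length} um too short for {cfg.n_mito} "
                "non-overlapping mitochondria at the configured lengths")
        # distribute the slack randomly over the n_mito + 1 gaps
        if cfg.n_mito:
            w = self.rng_dyn.dirichlet(np.ones(cfg.n_mito + 1)) * slack
            pos = _EDGE_MARGIN
            classes = self.rng_dyn.choice(
                ["stalled", "oscillating", "transported"],
                size=cfg.n_mito, p=list(cfg.motility_fractions))
            for i, l in enumerate(lengths):
                pos += w[i]
                track = self._new_track(root=i, birth=0,
                                        intensity=float(self.rng_dyn.uniform(
                                            *cfg.mito_intensity_range)),
                                        origin="initial",
                                        motility=str(classes[i]))
                m = _Mito(track, pos, l, str(classes[i]))
                self.mitos.append(m)
                pos += l + cfg.placement_gap

    # -- transport machinery -------------------------------------------------

    def _start_run(self, m: _Mito, direction: int | None = None,
                   forced: bool = False) -> None:
        cfg = self.cfg
        m.phase = "run"
        m.velocity = float(self.rng_dyn.uniform(*cfg.velocity_range))
        m.direction = direction if direction is not None else \
            (1 if self.rng_dyn.random() < 0.5 else -1)
        if forced:
            # post-fission escape: a committed switch-free bout long enough
            # to clear the 1 um transport threshold
            need = int(np.ceil(1.6 / (m.velocity * cfg.dt))) + 1
            m.frames_left = max(need, 2)
            m.switch_at = None
        else:
            m.frames_left = max(2, 1 + int(self.rng_dyn.geometric(
                1.0 / cfg.run_mean_frames)))
            if self.rng_dyn.random() < cfg.run_switch_prob:
                m.switch_at = int(self.rng_dyn.integers(1, m.frames_left))
            else:
                m.switch_at = None
        m.step_index = 0
        m.forced_run = forced

    def _start_pause(self, m: _Mito) -> None:
        cfg = self.cfg
        m.phase = "pause"
        dur = 6.0 + self.rng_dyn.exponential(max(cfg.pause_mean_s - 6.0, 1e-6))
        m.frames_left = max(2, int(np.ceil(dur / cfg.dt)))

    def _fuse(self, mover: _Mito, target: _Mito, frame: int) -> None:
        """Merge mover into target at contact; lengths are exactly additive."""
        if mover.a < target.a:
            a = target.a - mover.length
            position = target.a
        else:
            a = target.a
            position = target.b
        la, lb = mover.length, target.length
        child_len = la + lb
        intensity = (mover.track.intensity * la
                     + target.track.intensity * lb) / child_len
        for p in (mover, target):
            p.alive = False
            p.track.death_frame = frame - 1
        root = min(mover.track.root, target.track.root)
        track = self._new_track(root=root, birth=frame, intensity=intensity,
                                origin="fusion", motility="stalled")
        child = _Mito(track, a, child_len, "stalled")
        child.refractory_until = frame + self.cfg.separation_frames
        self.mitos.append(child)
        self.fusions.append({
            "frame": frame, "position": float(position),
            "parents": [mover.track.id, target.track.id],
            "children": [track.id],
            "parent_lengths": [float(la), float(lb)],
        })

    def _step_transported(self, m: _Mito, frame: int) -> None:
        cfg = self.cfg
        if m.phase == "pause":
            m.frames_left -= 1
            if m.frames_left <= 0:
                self._start_run(m)
            return
        if m.switch_at is not None and m.step_index == m.switch_at:
            m.direction = -m.direction
            m.velocity = float(self.rng_dyn.uniform(*cfg.velocity_range))
        d = m.direction * m.velocity * cfg.dt
        nb = self._neighbor(m, m.direction)
        gap = (nb.a - m.b if m.direction > 0 else m.a - nb.b) if nb else np.inf
        if nb is not None and gap - abs(d) < cfg.approach_gap:
            pair = tuple(sorted((m.track.id, nb.track.id)))
            target_ready = (nb.state != "separating"
                            and frame >= nb.refractory_until)
            if target_ready and pair not in self.no_fuse and \
                    self.rng_dyn.random() < cfg.fusion_prob_per_10min:
                self._fuse(m, nb, frame)
                return
            if target_ready:
                self.no_fuse.add(pair)
            m.a += m.direction * max(gap - cfg.approach_gap, 0.0)
            self._start_pause(m)
            return
        lo, hi = _EDGE_MARGIN, cfg.axon_length - _EDGE_MARGIN
        new_a = m.a + d
        if new_a < lo or new_a + m.length > hi:
            m.a = min(max(new_a, lo), hi - m.length)
            self._start_pause(m)
            return
        m.a = new_a
        m.step_index += 1
        m.frames_left -= 1
        if m.frames_left <= 0:
            self._start_pause(m)

    def _step_oscillating(self, m: _Mito, frame: int) -> None:
        cfg = self.cfg
        if self.rng_dyn.random() >= cfg.oscillation_move_prob:
            return
        centre = m.a + m.length / 2
        step = cfg.oscillation_step if self.rng_dyn.random() < 0.5 \
            else -cfg.oscillation_step
        if abs(centre + step - m.anchor) > cfg.oscillation_amplitude:
            step = -step
        if abs(centre + step - m.anchor) > cfg.oscillation_amplitude:
            return
        direction = 1 if step > 0 else -1
        if self._clearance(m, direction) - abs(step) < cfg.approach_gap:
            return
        m.a += step

    def _sibling_gap(self, m: _Mito) -> float:
        if m.sib is None or not m.sib.alive:
            return np.inf
        return max(m.sib.a - m.b, m.a - m.sib.b)

    def _finish_separation(self, m: _Mito) -> None:
        if m.will_transport:
            m.state = "transported"
            m.track.motility = "transported"
            # escape away from the sibling unless that side is blocked
            direction = m.sep_dir
            if self._clearance(m, direction) < 3.0 and \
                    self._clearance(m, -direction) > self._clearance(m, direction):
                direction = -direction
            self._start_run(m, direction=direction, forced=True)
        else:
            m.state = "stalled"

    def _step_separating(self, m: _Mito, frame: int) -> None:
        """Post-fission drift: the child backs away from its sibling until
        their gap is resolvable, never encroaching on other standoffs."""
        cfg = self.cfg
        if self._sibling_gap(m) >= _MIN_SIBLING_GAP:
            self._finish_separation(m)
            return
        step = cfg.separation_step
        if self._clearance(m, m.sep_dir) - step >= cfg.approach_gap:
            m.a += m.sep_dir * step
        m.sep_patience -= 1
        if m.sep_patience <= 0:
            self._finish_separation(m)

    # -- fission -------------------------------------------------------------

    def _active_patches(self, frame: int) -> list[TruePatch]:
        return [p for p in self.patches
                if p.channel == "actin" and p.onset <= frame <= p.offset]

    def _fission_site(self, m: _Mito, frame: int) -> float:
        cfg = self.cfg
        lo, hi = m.a + cfg.min_child_length, m.b - cfg.min_child_length
        if cfg.fission_patch_bias > 0 and \
                self.rng_dyn.random() < cfg.fission_patch_bias:
            spans = []
            for p in self._active_patches(frame):
                s, e = max(p.start, lo), min(p.end, hi)
                if e > s:
                    spans.append((s, e))
            if spans:
                w = np.array([e - s for s, e in spans])
                k = int(self.rng_dyn.choice(len(spans), p=w / w.sum()))
                s, e = spans[k]
                return float(self.rng_dyn.uniform(s, e))
            if cfg.fission_patch_bias >= 1.0:
                # patch-mediated fission: recruit an actin patch at the site
                site = float(self.rng_dyn.uniform(lo, hi))
                self._spawn_patch(frame, centre=site, induced=True)
                return site
        return float(self.rng_dyn.uniform(lo, hi))

    def _try_fission(self, m: _Mito, frame: int) -> None:
        cfg = self.cfg
        spare = (max(self._clearance(m, -1) - cfg.approach_gap, 0.0)
                 + max(self._clearance(m, 1) - cfg.approach_gap, 0.0))
        if spare < _MIN_SIBLING_GAP:
            return      # too crowded for a resolvable separation; rare
        site = self._fission_site(m, frame)
        m.alive = False
        m.track.death_frame = frame - 1
        kids = []
        for (a, l, direction) in ((m.a, site - m.a, -1),
                                  (site, m.b - site, 1)):
            track = self._new_track(root=m.track.root, birth=frame,
                                    intensity=m.track.intensity,
                                    origin="fission", motility="stalled")
            child = _Mito(track, a, l, "separating")
            child.sep_dir = direction
            child.sep_patience = _SEPARATION_PATIENCE
            child.refractory_until = frame + cfg.separation_frames + 1
            self.mitos.append(child)
            kids.append(child)
        kids[0].sib, kids[1].sib = kids[1], kids[0]
        # the two children may never re-fuse with each other
        self.no_fuse.add(tuple(sorted((kids[0].track.id, kids[1].track.id))))
        if self.rng_dyn.random() < cfg.p_transport_after_fission:
            if self.rng_dyn.random() < cfg.p_both_children_transport:
                chosen = kids
            else:
                # prefer the child with escape room on its side so the
                # event-level transport commitment can actually be realised
                clears = [self._clearance(kids[0], -1),
                          self._clearance(kids[1], 1)]
                if abs(clears[0] - clears[1]) < 1e-9:
                    chosen = [kids[int(self.rng_dyn.integers(0, 2))]]
                else:
                    chosen = [kids[int(np.argmax(clears))]]
            for c in chosen:
                c.will_transport = True
                c.track.transported_after_fission = True
        self.fissions.append({
            "frame": frame, "position": float(site),
            "parents": [m.track.id],
            "children": [k.track.id for k in kids],
            "parent_length": float(m.length),
        })

    # -- patches / puncta ----------------------------------------------------

    def _spawn_patch(self, frame: int, centre: float | None = None,
                     induced: bool = False) -> None:
        cfg = self.cfg
        rng = self.rng_patch
        med, shape = cfg.patch_length_dist
        ext = max(float(med * np.exp(rng.normal(0.0, shape))),
                  2 * cfg.pixel_size)
        if centre is None:
            centre = float(rng.uniform(0.0, cfg.axon_length))
        dur = max(2, int(np.ceil(rng.exponential(cfg.patch_duration_mean_s)
                                 / cfg.dt)))
        onset = max(0, frame - 1) if induced else frame
        offset = min(onset + dur - 1, cfg.n_frames - 1)
        self.patches.append(TruePatch(
            channel="actin", onset=onset, offset=offset,
            start=max(0.0, centre - ext / 2),
            end=min(cfg.axon_length, centre + ext / 2),
            induced=induced))

    def _patch_arrivals(self, frame: int) -> None:
        cfg = self.cfg
        lam = cfg.patch_rate * cfg.axon_length * cfg.dt / 60.0
        if lam <= 0:
            return
        for _ in range(int(self.rng_patch.poisson(lam))):
            if frame <= cfg.n_frames - 2:
                self._spawn_patch(frame)

    def _drp1_arrivals(self, frame: int) -> None:
        cfg = self.cfg
        lam = cfg.drp1_rate_per_mito_per_10min * cfg.dt / 600.0
        if lam <= 0:
            return
        for m in self._alive():
            for _ in range(int(self.rng_drp1.poisson(lam))):
                if frame > cfg.n_frames - 2:
                    continue
                centre = float(self.rng_drp1.uniform(m.a, m.b))
                dur = max(2, int(np.ceil(
                    self.rng_drp1.exponential(cfg.drp1_duration_mean_s)
                    / cfg.dt)))
                self.patches.append(TruePatch(
                    channel="drp1", onset=frame,
                    offset=min(frame + dur - 1, cfg.n_frames - 1),
                    start=max(0.0, centre - cfg.drp1_length / 2),
                    end=min(cfg.axon_length, centre + cfg.drp1_length / 2)))

    # -- labelling -----------------------------------------------------------

    def _label_patches(self) -> None:
        cfg = self.cfg
        for p in self.patches:
            if p.channel != "actin":
                continue
            p.overlaps_fission = any(
                p.start <= e["position"] <= p.end
                and p.onset - 1 <= e["frame"] <= p.offset + 1
                for e in self.fissions)
            if p.overlaps_fission:
                p.cls = "fission_associated"
            else:
                on_mito = False
                for t in self.tracks:
                    f0 = max(p.onset, t.birth_frame)
                    f1 = min(p.offset, t.birth_frame + len(t.bounds) - 1)
                    for f in range(f0, f1 + 1):
                        a, b = t.bounds[f - t.birth_frame]
                        if min(b, p.end) > max(a, p.start):
                            on_mito = True
                            break
                    if on_mito:
                        break
                p.cls = "mito_associated" if on_mito else "non_mito"
            p.filopodium = bool(self.rng_fate.random()
                                < cfg.filopodium_probs.get(p.cls, 0.0))

    # -- main loop -----------------------------------------------------------

    def run(self) -> GroundTruth:
        cfg = self.cfg
        self._place_initial()
        for m in self._alive():
            m.track.bounds.append((m.a, m.b))
        self._patch_arrivals(0)
        self._drp1_arrivals(0)
        p_fis = cfg.per_frame_prob(cfg.fission_prob_per_10min)
        # stop drawing fissions when their completion (separation beyond
        # the 0.6 um criterion) could no longer be observed before the end
        last_fission_frame = cfg.n_frames - 1 - (cfg.separation_frames + 2)
        for frame in range(1, cfg.n_frames):
            for m in sorted(self._alive(), key=lambda x: x.track.id):
                if not m.alive:
                    continue
                if m.state == "separating":
                    self._step_separating(m, frame)
                elif m.state == "transported":
                    self._step_transported(m, frame)
                elif m.state == "oscillating":
                    self._step_oscillating(m, frame)
            if p_fis > 0 and frame <= last_fission_frame:
                for m in sorted(self._alive(), key=lambda x: x.track.id):
                    if (m.state == "stalled" and frame >= m.refractory_until
                            and m.length >= 2 * cfg.min_child_length + 0.1
                            and self.rng_dyn.random() < p_fis):
                        self._try_fission(m, frame)
            for m in self._alive():
                m.track.bounds.append((m.a, m.b))
            self._patch_arrivals(frame)
            self._drp1_arrivals(frame)
        for m in self._alive():
            m.track.death_frame = cfg.n_frames - 1
        self._label_patches()
        return GroundTruth(config=cfg, tracks=self.tracks,
                           fission_events=self.fissions,
                           fusion_events=self.fusions,
                           patches=self.patches, n_initial=cfg.n_mito)


def simulate_dynamics(config: SimConfig) -> GroundTruth:
    """Simulate one axon under ``config``; reproducible given the seed."""
    return _Simulator(config).run()


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _box_profile(x: np.ndarray, a: float, b: float, sigma: float) -> np.ndarray:
    """Uniform interval [a, b) convolved with a Gaussian PSF of SD sigma."""
    if sigma <= 0:
        return ((x >= a) & (x < b)).astype(float)
    return ndtr((b - x) / sigma) - ndtr((a - x) / sigma)


def render_series(truth: GroundTruth, channel: str = "mito",
                  noise: tuple[float, float] | None = None,
                  ) -> AxonFrameSeries:
    """Render ground truth into a 1-D arc-length intensity series.

    Spatially overlapping sources add; the PSF is applied analytically and
    Poisson-Gaussian noise last.  ``noise=None`` uses the config's noise.
    """
    cfg = truth.config
    if noise is None:
        noise = cfg.noise
    x = (np.arange(cfg.n_pixels) + 0.5) * cfg.pixel_size
    data = np.full((cfg.n_frames, cfg.n_pixels), float(cfg.background_level))
    if channel == "mito":
        for t in truth.tracks:
            for i, (a, b) in enumerate(t.bounds):
                data[t.birth_frame + i] += t.intensity * _box_profile(
                    x, a, b, cfg.psf_sigma)
    elif channel in ("actin", "drp1"):
        inten = cfg.patch_intensity if channel == "actin" else cfg.drp1_intensity
        for p in truth.patches:
            if p.channel != channel:
                continue
            prof = inten * _box_profile(x, p.start, p.end, cfg.psf_sigma)
            data[p.onset:p.offset + 1] += prof
    else:
        raise ValueError(f"unknown channel {channel!r}")
    gain, gauss_sd = noise
    if gain > 0 or gauss_sd > 0:
        rng = np.random.default_rng([cfg.seed, 3, hash(channel) % (2 ** 31)])
        if gain > 0:
            data = rng.poisson(np.maximum(data, 0.0) / gain) * gain
        if gauss_sd > 0:
            data = data + rng.normal(0.0, gauss_sd, data.shape)
    return AxonFrameSeries(data.astype(float), cfg.pixel_size,
                           cfg.frame_interval, channel=channel)


def render_stack(truth: GroundTruth, channel: str = "mito",
                 height: int = 7,
                 noise: tuple[float, float] | None = None) -> np.ndarray:
    """Render a ``(n_frames, height, width)`` image stack.

    The axon runs horizontally along the centre row; the transverse PSF is
    Gaussian with the same sigma as the axial one.  Noise is applied per
    pixel after projection, so a 1-pixel-wide transect through the centre
    row reproduces :func:`render_series` statistics.
    """
    cfg = truth.config
    series = render_series(truth, channel=channel, noise=(0.0, 0.0))
    y = (np.arange(height) - (height - 1) / 2) * cfg.pixel_size
    transverse = np.exp(-0.5 * (y / max(cfg.psf_sigma, 1e-9)) ** 2)
    signal = series.data - cfg.background_level
    stack = (signal[:, None, :] * transverse[None, :, None]
             + cfg.background_level)
    gain, gauss_sd = cfg.noise if noise is None else noise
    if gain > 0 or gauss_sd > 0:
        rng = np.random.default_rng([cfg.seed, 5, hash(channel) % (2 ** 31)])
        if gain > 0:
            stack = rng.poisson(np.maximum(stack, 0.0) / gain) * gain
        if gauss_sd > 0:
            stack = stack + rng.normal(0.0, gauss_sd, stack.shape)
    return stack.astype(np.float32)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def tracks_table(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for t in truth.tracks:
        for i, (a, b) in enumerate(t.bounds):
            rows.append({"track_id": t.id, "root": t.root,
                         "frame": t.birth_frame + i,
                         "start_um": a, "end_um": b,
                         "origin": t.origin, "motility": t.motility})
    return pd.DataFrame(rows, columns=["track_id", "root", "frame",
                                       "start_um", "end_um", "origin",
                                       "motility"])


def write_fixture(truth: GroundTruth, directory,
                  channels: tuple[str, ...] = ("mito",),
                  stacks: bool = False) -> dict[str, Path]:
    """Write a fixture bundle: TIFF stack(s), truth JSON, track CSV, config.

    With ``stacks=False`` the TIFFs hold the 1-D profile series (one row
    per frame); with ``stacks=True`` full (frames, H, W) image stacks.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ch in channels:
        arr = (render_stack(truth, channel=ch) if stacks
               else render_series(truth, channel=ch).data[:, None, :])
        p = directory / f"{ch}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths[f"stack_{ch}"] = p
    p = directory / "ground_truth.json"
    p.write_text(json.dumps(truth.to_dict(), indent=1))
    paths["truth"] = p
    p = directory / "tracks.csv"
    tracks_table(truth).to_csv(p, index=False)
    paths["tracks"] = p
    p = directory / "config.yaml"
    p.write_text(truth.config.to_yaml())
    paths["config"] = p
    return paths


def read_fixture(directory) -> tuple[GroundTruth, dict[str, np.ndarray]]:
    """Read a fixture bundle back; inverse of :func:`write_fixture`."""
    directory = Path(directory)
    truth = GroundTruth.from_dict(
        json.loads((directory / "ground_truth.json").read_text()))
    stacks = {}
    for p in sorted(directory.glob("*.tif")):
        stacks[p.stem] = tifffile.imread(p)
    return truth, stacks
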