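"""End-to-end tracking runs: calibration, player tracking, ball tracking.

Binds the modules into the two pipelines a user runs on a clip:

* players — background/cue images per frame (computed once, shared by all
  four trackers), reference appearance from the calibration frame and the
  user's four click positions, then either the particle filter or the
  rigid-grid tracker per player, with the cross-set confusion guard;
* ball — movement mask per frame, size/isolation-gated candidates, then
  trajectory growth and/or Hough-line estimation, and contact events from
  parabola intersections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .appearance import (
    CueWeights,
    HistogramConfig,
    ReferenceAppearance,
    hsv_histogram,
    integral_histogram,
)
from .background import BackgroundConfig, BackgroundState, FrameBundle, make_bundle
from .ball_detection import BallCandidate, CandidateConfig, detect_candidates
from .contact_estimation import contacts as contact_events
from .geometry import Homography, image_to_world, project_box, world_to_image
from .grid_tracker import GridLayout, grid_step, make_grid
from .hough_trajectories import HoughConfig, hough_trajectories
from .particle_tracker import (
    ConfusionGuard,
    ParticleSet,
    ResampleConfig,
    estimate_state,
    init_set,
    resample,
    weight_set,
)
from .trajectory_growth import (
    GrowthConfig,
    extrapolate,
    grow_trajectories,
    merge_collinear,
    select_parallel,
)

__all__ = [
    "TrackerConfig",
    "build_references",
    "track_players",
    "track_ball",
]


@dataclass
class TrackerConfig:
    method: str = "grid"                   # "particle" | "grid"
    n_particles: int = 30
    grid_layout: GridLayout = field(default_factory=GridLayout)
    cue_weights: CueWeights = field(default_factory=CueWeights)
    hist: HistogramConfig = field(default_factory=HistogramConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    player_height_m: float = 2.0
    init_halfwidth_m: float = 1.0          # particle init region around each click
    seed: int = 0


def build_references(
    bundle: FrameBundle,
    h: Homography,
    clicks_px,
    cfg: TrackerConfig,
) -> list[ReferenceAppearance]:
    """Per-player reference histograms from the masked calibration frame.

    ``clicks_px`` are the four user click positions (between the feet of
    each player, in pixels); player ids are 1..4 in click order.
    """
    refs = []
    for i, click in enumerate(clicks_px):
        world = image_to_world(h, click)
        box = project_box(
            h, world, height_m=cfg.player_height_m,
            n_subwindows=cfg.cue_weights.n_subwindows,
            frame_shape=bundle.frame.shape,
        )
        hists = [
            hsv_histogram(bundle.masked_frame[r.y0 : r.y1, r.x0 : r.x1], cfg.hist)
            for r in box.subwindows
        ]
        refs.append(ReferenceAppearance(player_id=i + 1, histograms=hists))
    return refs


def _iter_bundles(frames, bg_cfg: BackgroundConfig):
    state = BackgroundState.blank(frames[0].shape, bg_cfg)
    prev = None
    for t, frame in enumerate(frames):
        yield make_bundle(state, prev, frame, t, bg_cfg)
        prev = frame


@dataclass
class _GridGuard:
    """Same-player safeguard for grids: reset the weaker anchor uniformly."""

    rc: ResampleConfig
    rng: np.random.Generator
    counters: dict = field(default_factory=dict)

    def step(self, grids) -> None:
        for i in range(len(grids)):
            for j in range(i + 1, len(grids)):
                a, b = grids[i], grids[j]
                key = (a.player_id, b.player_id)
                d = float(np.hypot(*(a.anchor - b.anchor)))
                self.counters[key] = self.counters.get(key, 0) + 1 if d < self.rc.guard_overlap_dist_m else 0
                if self.counters.get(key, 0) > self.rc.guard_frames:
                    weaker = a if a.mean_color_score() <= b.mean_color_score() else b
                    x0, x1, y0, y1 = self.rc.court_bounds
                    weaker.anchor = np.array(
                        [self.rng.uniform(x0, x1), self.rng.uniform(y0, y1)]
                    )
                    for k in list(self.counters):
                        if weaker.player_id in k:
                            self.counters[k] = 0


def track_players(
    frames,
    h: Homography,
    clicks_px,
    cfg: TrackerConfig,
    calib_frame: int = 0,
    track_start: int | None = None,
) -> pd.DataFrame:
    """Track the four players through a clip.

    Frames before ``calib_frame`` only feed the background model; at the
    calibration frame the reference appearances are built from the masked
    frame and the trackers initialized at the click positions.  Returns a
    track table ``frame, player_id, x_m, y_m, x_px, y_px, lost, method``.
    """
    track_start = calib_frame if track_start is None else track_start
    rows = []
    refs = None
    psets: list[ParticleSet] = []
    grids = []
    guard = None
    grid_rng = np.random.default_rng([cfg.seed, 977])
    for bundle in _iter_bundles(frames, cfg.background):
        t = bundle.index
        if t < calib_frame:
            continue
        if refs is None:
            refs = build_references(bundle, h, clicks_px, cfg)
            if cfg.method == "particle":
                for ref, click in zip(refs, clicks_px):
                    world = image_to_world(h, click)
                    hw = cfg.init_halfwidth_m
                    region = (world[0] - hw, world[0] + hw, world[1] - hw, world[1] + hw)
                    psets.append(
                        init_set(region, cfg.n_particles, ref, cfg.seed, ref.player_id)
                    )
                guard = ConfusionGuard(rc=cfg.resample)
            else:
                for ref, click in zip(refs, clicks_px):
                    grids.append(
                        make_grid(image_to_world(h, click), cfg.grid_layout, h, ref)
                    )
                guard = _GridGuard(rc=cfg.resample, rng=grid_rng)
        if cfg.method == "particle":
            for pset in psets:
                weight_set(pset, bundle, h, cfg.cue_weights, cfg.hist, cfg.player_height_m)
                est = estimate_state(pset)
                px = world_to_image(h, est)
                rows.append((t, pset.player_id, est[0], est[1], px[0], px[1], pset.lost, "particle"))
            guard.step(psets)
            for pset in psets:
                resample(pset, cfg.resample)
        else:
            ih = integral_histogram(bundle.masked_frame, cfg.hist)
            for grid in grids:
                est, _ = grid_step(grid, bundle, h, cfg.cue_weights, ih, cfg.player_height_m)
                px = world_to_image(h, est)
                rows.append((t, grid.player_id, est[0], est[1], px[0], px[1], grid.lost, "grid"))
            guard.step(grids)
    return pd.DataFrame(
        rows, columns=["frame", "player_id", "x_m", "y_m", "x_px", "y_px", "lost", "method"]
    )


@dataclass
class BallConfig:
    candidates: CandidateConfig = field(default_factory=CandidateConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    hough: HoughConfig = field(default_factory=HoughConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    method: str = "growth"                 # "growth" | "hough" | "both"
    contact_slack_frames: float = 15.0


def detect_all_candidates(frames, h: Homography, cfg: BallConfig) -> dict[int, list[BallCandidate]]:
    """Movement-mask ball candidates for every frame of a clip."""
    by_frame: dict[int, list[BallCandidate]] = {}
    for bundle in _iter_bundles(frames, cfg.background):
        t = bundle.index
        if t == 0:
            continue
        cands = detect_candidates(bundle.mov_mask, h, cfg.candidates, frame_index=t)
        if cands:
            by_frame[t] = cands
    return by_frame


def ball_from_candidates(
    candidates_by_frame: dict[int, list[BallCandidate]],
    cfg: BallConfig,
    frame_height: int,
    n_frames: int,
) -> dict:
    """Trajectories and contact events from per-frame candidates."""
    out: dict = {}
    flat = [c for t in sorted(candidates_by_frame) for c in candidates_by_frame[t]]
    if cfg.method in ("growth", "both"):
        grown = grow_trajectories(candidates_by_frame, cfg.growth, frame_height, n_frames)
        selected = select_parallel(grown)
        selected = merge_collinear(selected)
        selected = extrapolate(selected, clip_start=0, clip_end=n_frames - 1)
        out["growth"] = {
            "trajectories": selected,
            "contacts": contact_events(selected, cfg.contact_slack_frames),
        }
    if cfg.method in ("hough", "both"):
        trajs = hough_trajectories(flat, cfg.hough, n_frames, frame_height)
        out["hough"] = {
            "trajectories": trajs,
            "contacts": contact_events(trajs, cfg.contact_slack_frames),
        }
    return out


def track_ball(frames, h: Homography, cfg: BallConfig) -> dict:
    """Full ball pipeline on a clip: candidates, trajectories, contacts."""
    by_frame = detect_all_candidates(frames, h, cfg)
    result = ball_from_candidates(by_frame, cfg, frames[0].shape[0], len(frames))
    result["candidates_by_frame"] = by_frame
    return result
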