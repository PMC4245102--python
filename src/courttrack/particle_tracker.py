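"""Classical per-player particle filter.

Each of the four players owns a set of 20-50 particles whose state is the
player's position on the court plane in meters.  Per frame every particle
projects its bounding box into the image and scores three cues — color
(subwindow HSV histograms against the calibration reference), foreground
mask and movement counts — each normalized to the set's per-frame maximum
and alpha-mixed into a total weight.  The estimate is the weighted mean of
particle positions.  Roulette-wheel (multinomial) resampling follows, with
two-tier Gaussian jitter: 0.2 m normally, 0.04 m for particles within the
top 0.1% of the set's maximum weight, concentrating refinement around the
best hypotheses while keeping exploration.  A confusion safeguard watches
pairs of sets: when two track the same spot for more than ten frames, the
one with the weaker average color score is thrown back to a uniform
redraw over the court to go find its lost player.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .appearance import (
    CueWeights,
    HistogramConfig,
    ReferenceAppearance,
    bhattacharyya,
    color_score,
    count_score,
    hsv_histogram,
    total_weight,
)
from .background import FrameBundle
from .geometry import Homography, project_box

__all__ = ["ResampleConfig", "ParticleSet", "init_set", "weight_set", "estimate_state", "resample", "confusion_guard"]


@dataclass
class ResampleConfig:
    sigma_base: float = 0.2      # m
    sigma_top: float = 0.04      # m, for the top 0.1%-of-max weight band
    top_band: float = 0.001
    guard_frames: int = 10
    guard_overlap_dist_m: float = 0.5
    court_bounds: tuple = (0.0, 8.0, 0.0, 16.0)  # x0, x1, y0, y1
    player_height_m: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.sigma_top < self.sigma_base):
            raise ValueError("need 0 < sigma_top < sigma_base")
        if self.guard_frames < 1:
            raise ValueError("guard_frames must be >= 1")


@dataclass
class ParticleSet:
    player_id: int
    positions: np.ndarray            # (n, 2) world meters
    weights: np.ndarray              # (n,)
    cue_scores: np.ndarray           # (n, 3) raw color/mask/mov
    reference: ReferenceAppearance | None
    rng: np.random.Generator
    estimate: np.ndarray | None = None
    lost: bool = False

    @property
    def n(self) -> int:
        return len(self.positions)

    def mean_color_score(self) -> float:
        return float(self.cue_scores[:, 0].mean())


def init_set(
    region, n: int, ref: ReferenceAppearance | None, seed: int, player_id: int = 0
) -> ParticleSet:
    """Uniformly scatter ``n`` particles over a world rectangle.

    ``region`` is (x0, x1, y0, y1) in meters.  The per-set RNG stream is
    split by player id, so results are independent of update order.
    """
    x0, x1, y0, y1 = region
    if n < 1 or x1 <= x0 or y1 <= y0:
        raise ValueError("need n >= 1 and a region of positive area")
    rng = np.random.default_rng([seed, player_id])
    pos = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    return ParticleSet(
        player_id=player_id,
        positions=pos,
        weights=np.full(n, 1.0 / n),
        cue_scores=np.zeros((n, 3)),
        reference=ref,
        rng=rng,
        estimate=pos.mean(axis=0),
    )


def score_position(
    pos,
    bundle: FrameBundle,
    h: Homography,
    ref: ReferenceAppearance,
    cw: CueWeights,
    hist_cfg: HistogramConfig,
    player_height_m: float = 2.0,
) -> tuple[float, float, float]:
    """Raw (color, mask, movement) scores of one world-position hypothesis."""
    box = project_box(
        h, pos, height_m=player_height_m, n_subwindows=cw.n_subwindows,
        frame_shape=bundle.frame.shape,
    )
    if box.empty:
        return 0.0, 0.0, 0.0
    dists = []
    for rect, ref_hist in zip(box.subwindows, ref.histograms):
        if rect.empty:
            dists.append(1.0)
            continue
        hyp = hsv_histogram(
            bundle.masked_frame[rect.y0 : rect.y1, rect.x0 : rect.x1], hist_cfg
        )
        dists.append(bhattacharyya(ref_hist, hyp))
    col = color_score(dists, cw)
    mask_s = count_score(bundle.fg_mask, box.subwindows, cw)
    mov_s = count_score(bundle.mov_mask, box.subwindows, cw)
    return col, mask_s, mov_s


def weight_set(
    pset: ParticleSet,
    bundle: FrameBundle,
    h: Homography,
    cw: CueWeights,
    hist_cfg: HistogramConfig = HistogramConfig(),
    player_height_m: float = 2.0,
) -> ParticleSet:
    """Score all particles and set per-frame max-normalized total weights."""
    scores = np.array(
        [
            score_position(p, bundle, h, pset.reference, cw, hist_cfg, player_height_m)
            for p in pset.positions
        ]
    )
    pset.cue_scores = scores
    maxima = scores.max(axis=0)
    if np.all(maxima <= 0):
        pset.weights = np.full(pset.n, 1.0 / pset.n)
        pset.lost = True
        return pset
    pset.lost = False
    normed = np.where(maxima > 0, scores / np.where(maxima > 0, maxima, 1.0), 0.0)
    pset.weights = np.array(
        [total_weight(c, m, v, cw) for c, m, v in normed]
    )
    return pset


def estimate_state(pset: ParticleSet) -> np.ndarray:
    """Weighted mean of particle positions; previous estimate if weightless."""
    total = pset.weights.sum()
    if total <= 0:
        pset.lost = True
        return pset.estimate if pset.estimate is not None else pset.positions.mean(axis=0)
    est = (pset.weights[:, None] * pset.positions).sum(axis=0) / total
    pset.estimate = est
    return est


def resample(pset: ParticleSet, rc: ResampleConfig) -> ParticleSet:
    """Roulette-wheel resampling with two-tier Gaussian jitter.

    Offspring are drawn with probability proportional to weight; copies of
    particles within ``top_band`` of the maximum weight are jittered with
    ``sigma_top``, all others with ``sigma_base``.  All-zero weights mean
    the track is lost: redraw uniformly over the court.
    """
    n = pset.n
    total = pset.weights.sum()
    if total <= 0 or pset.lost:
        x0, x1, y0, y1 = rc.court_bounds
        pset.positions = np.column_stack(
            [pset.rng.uniform(x0, x1, n), pset.rng.uniform(y0, y1, n)]
        )
        pset.weights = np.full(n, 1.0 / n)
        return pset
    p = pset.weights / total
    idx = pset.rng.choice(n, size=n, p=p)
    top = pset.weights >= (1.0 - rc.top_band) * pset.weights.max()
    sigma = np.where(top[idx], rc.sigma_top, rc.sigma_base)
    noise = pset.rng.normal(0.0, 1.0, (n, 2)) * sigma[:, None]
    pset.positions = pset.positions[idx] + noise
    pset.weights = np.full(n, 1.0 / n)
    return pset


@dataclass
class ConfusionGuard:
    """Pairwise overlap counters implementing the same-player safeguard."""

    rc: ResampleConfig
    counters: dict = field(default_factory=dict)

    def step(self, sets: list[ParticleSet]) -> list[int]:
        """Update counters from current estimates; reset confused sets.

        Returns the player ids that were re-initialized this frame.  After
        two sets stay within ``guard_overlap_dist_m`` for strictly more
        than ``guard_frames`` frames, the one with the smaller average
        color score is redrawn uniformly over the court.
        """
        reset_ids: list[int] = []
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                a, b = sets[i], sets[j]
                key = (a.player_id, b.player_id)
                d = float(np.hypot(*(a.estimate - b.estimate)))
                if d < self.rc.guard_overlap_dist_m:
                    self.counters[key] = self.counters.get(key, 0) + 1
                else:
                    self.counters[key] = 0
                if self.counters.get(key, 0) > self.rc.guard_frames:
                    weaker = a if a.mean_color_score() <= b.mean_color_score() else b
                    x0, x1, y0, y1 = self.rc.court_bounds
                    n = weaker.n
                    weaker.positions = np.column_stack(
                        [weaker.rng.uniform(x0, x1, n), weaker.rng.uniform(y0, y1, n)]
                    )
                    weaker.weights = np.full(n, 1.0 / n)
                    reset_ids.append(weaker.player_id)
                    for k in list(self.counters):
                        if weaker.player_id in k:
                            self.counters[k] = 0
        return reset_ids


def confusion_guard(sets: list[ParticleSet], guard: ConfusionGuard) -> list[ParticleSet]:
    """Apply the safeguard step to a list of sets (functional wrapper)."""
    guard.step(sets)
    return sets
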