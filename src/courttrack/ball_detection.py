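"""Per-frame ball candidate extraction from the movement mask.

The ball appears in the movement mask as a small isolated blob.  Connected
components are gated on area — the expected pixel size of a 21 cm ball at
the blob's court position, from the homography's local scale — and then on
isolation: an inner 40x40 window centered on the centroid must hold more
than Q non-zero pixels while the outer 60x60 window may exceed it by at
most R pixels, so accepted blobs have nothing else nearby.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .geometry import Homography, image_to_world, local_scale

__all__ = ["CandidateConfig", "BallCandidate", "detect_candidates"]


@dataclass
class CandidateConfig:
    ball_diameter_m: float = 0.21
    area_ratio_lo: float = 0.25
    area_ratio_hi: float = 4.0
    inner_side: int = 40
    outer_side: int = 60
    q_min_inner: int = 30     # inner window must hold more than Q non-zero pixels
    r_slack: int = 5          # outer window may hold at most inner + R
    isolation_mode: str = "inner_plus_r"  # or literal "q_plus_r"

    def __post_init__(self):
        if self.inner_side >= self.outer_side:
            raise ValueError("inner window must be smaller than outer window")
        if self.q_min_inner <= 0 or self.r_slack < 0:
            raise ValueError("invalid isolation thresholds")


@dataclass
class BallCandidate:
    frame: int
    x_px: float
    y_px: float
    area: int
    margin: int  # outer - inner non-zero count at acceptance


def _window_count(mask: np.ndarray, cx: float, cy: float, side: int) -> int:
    h, w = mask.shape
    half = side // 2
    x0 = max(int(round(cx)) - half, 0)
    y0 = max(int(round(cy)) - half, 0)
    x1 = min(x0 + side, w)
    y1 = min(y0 + side, h)
    return int(np.count_nonzero(mask[y0:y1, x0:x1]))


def detect_candidates(
    mov_mask: np.ndarray,
    h: Homography,
    cfg: CandidateConfig = CandidateConfig(),
    frame_index: int = 0,
) -> list[BallCandidate]:
    """Size- and isolation-filtered moving blobs (8-connectivity).

    The expected ball area at a blob is pi*(d_px/2)^2 with d_px the ball
    diameter times the pixel scale at the blob's back-projected ground
    point; blobs within [area_ratio_lo, area_ratio_hi] of it proceed to the
    concentric-square isolation test.  Candidates are sorted by x.
    """
    mov_mask = np.asarray(mov_mask)
    if mov_mask.ndim != 2:
        raise ValueError("movement mask must be a 2-D binary image")
    labels = measure.label(mov_mask > 0, connectivity=2)
    out: list[BallCandidate] = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        world = image_to_world(h, (cx, cy))
        d_px = cfg.ball_diameter_m * local_scale(h, world)
        expected = np.pi * (d_px / 2.0) ** 2
        if not (cfg.area_ratio_lo * expected <= region.area <= cfg.area_ratio_hi * expected):
            continue
        inner = _window_count(mov_mask, cx, cy, cfg.inner_side)
        outer = _window_count(mov_mask, cx, cy, cfg.outer_side)
        if inner <= cfg.q_min_inner:
            continue
        limit = (
            cfg.q_min_inner + cfg.r_slack
            if cfg.isolation_mode == "q_plus_r"
            else inner + cfg.r_slack
        )
        if outer > limit:
            continue
        out.append(
            BallCandidate(
                frame=frame_index, x_px=float(cx), y_px=float(cy),
                area=int(region.area), margin=outer - inner,
            )
        )
    out.sort(key=lambda c: c.x_px)
    return out
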