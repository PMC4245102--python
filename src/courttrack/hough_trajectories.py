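"""Hough-line-based ball trajectory estimation.

Candidate positions are plotted against frame index as two binary scatter
images — x versus t and y versus t (t on the horizontal axis).  Stationary
flicker (spectators, net) shows up as horizontal point rows; candidates
near detected horizontal lines are discarded.  In the cleaned x-t image a
probabilistic Hough transform finds non-horizontal segments of a minimum
length with a bounded gap; candidates are assigned to their nearest
segment, and each resulting set receives a least-squares line in x-t and
parabola in height-t.  Neighbouring sets are joined when their x-t lines
intersect inside the inter-set frame gap and their height models agree
there to within a few pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import probabilistic_hough_line

from .ball_detection import BallCandidate
from .trajectory_growth import Trajectory, fit_trajectory

__all__ = [
    "HoughConfig",
    "scatter_images",
    "remove_horizontal",
    "detect_line_sets",
    "fit_and_join",
    "hough_trajectories",
]


@dataclass
class HoughConfig:
    min_line_len: int = 20
    max_gap: int = 10
    horizontal_angle_tol_deg: float = 5.0
    assign_dist_px: float = 3.0
    join_max_dy: float = 15.0
    hough_threshold: int = 5
    skip_horizontal_removal: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.min_line_len, self.max_gap) <= 0:
            raise ValueError("line gates must be positive")


def scatter_images(
    candidates: list[BallCandidate], clip_length: int, frame_height: int
):
    """Binary (value, t) scatter images: rows index x (or height), cols t.

    One set pixel per candidate at column t; the x-t image row is the
    rounded x position, the y-t image row the rounded height
    (frame_height - y_px), so upward ball motion points up.
    """
    if not candidates:
        raise ValueError("no candidates to plot")
    max_x = int(max(np.ceil(c.x_px) for c in candidates)) + 1
    xt = np.zeros((max_x + 1, clip_length), dtype=bool)
    yt = np.zeros((frame_height + 1, clip_length), dtype=bool)
    for c in candidates:
        xt[int(round(c.x_px)), c.frame] = True
        yt[int(round(frame_height - c.y_px)), c.frame] = True
    return xt, yt


def _segments(img: np.ndarray, cfg: HoughConfig, line_length: int):
    return probabilistic_hough_line(
        img,
        threshold=cfg.hough_threshold,
        line_length=line_length,
        line_gap=cfg.max_gap,
        rng=cfg.seed,
    )


def _is_horizontal(seg, tol_deg: float) -> bool:
    (c0, r0), (c1, r1) = seg  # (col, row) = (t, value)
    if c0 == c1:
        return False
    slope = (r1 - r0) / (c1 - c0)
    return abs(np.degrees(np.arctan(slope))) <= tol_deg


def _point_segment_dist(pt, seg) -> float:
    p = np.asarray(pt, dtype=float)
    a = np.asarray(seg[0], dtype=float)
    b = np.asarray(seg[1], dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    u = 0.0 if denom == 0 else np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return float(np.hypot(*(p - (a + u * ab))))


def remove_horizontal(
    candidates: list[BallCandidate], cfg: HoughConfig, clip_length: int, frame_height: int
) -> list[BallCandidate]:
    """Drop candidates near horizontal lines in either scatter image.

    Horizontal rows in x-t or y-t come from objects that flicker in place;
    a candidate is removed when it lies within ``assign_dist_px`` of a
    detected near-horizontal segment in either image.
    """
    if cfg.skip_horizontal_removal or not candidates:
        return list(candidates)
    xt, yt = scatter_images(candidates, clip_length, frame_height)
    h_xt = [s for s in _segments(xt, cfg, cfg.min_line_len) if _is_horizontal(s, cfg.horizontal_angle_tol_deg)]
    h_yt = [s for s in _segments(yt, cfg, cfg.min_line_len) if _is_horizontal(s, cfg.horizontal_angle_tol_deg)]
    kept = []
    for c in candidates:
        p_x = (c.frame, c.x_px)
        p_y = (c.frame, frame_height - c.y_px)
        near = any(_point_segment_dist(p_x, s) <= cfg.assign_dist_px for s in h_xt) or any(
            _point_segment_dist(p_y, s) <= cfg.assign_dist_px for s in h_yt
        )
        if not near:
            kept.append(c)
    return kept


def detect_line_sets(
    candidates: list[BallCandidate], cfg: HoughConfig, clip_length: int, frame_height: int
) -> list[list[BallCandidate]]:
    """Group candidates by non-horizontal Hough segments in the x-t image.

    Each candidate joins at most one segment (the nearest within
    ``assign_dist_px``); sets with fewer than three members are dropped.
    Returned sets are ordered by their earliest frame.
    """
    if not candidates:
        return []
    xt, _ = scatter_images(candidates, clip_length, frame_height)
    segs = [
        s
        for s in _segments(xt, cfg, cfg.min_line_len)
        if not _is_horizontal(s, cfg.horizontal_angle_tol_deg)
    ]
    sets: dict[int, list[BallCandidate]] = {i: [] for i in range(len(segs))}
    for c in candidates:
        p = (c.frame, c.x_px)
        dists = [_point_segment_dist(p, s) for s in segs]
        if not dists:
            continue
        best = int(np.argmin(dists))
        if dists[best] <= cfg.assign_dist_px:
            sets[best].append(c)
    out = [sorted(s, key=lambda c: c.frame) for s in sets.values() if len(s) >= 3]
    out.sort(key=lambda s: s[0].frame)
    return out


def fit_and_join(
    line_sets: list[list[BallCandidate]], cfg: HoughConfig, frame_height: int
) -> list[Trajectory]:
    """Fit each candidate set and join consistent neighbours.

    Per set: least-squares x-t line (m, b) and height-t parabola
    (a2, a1, a0) over its frame span.  Consecutive sets are joined by
    interpolation iff their x-t lines intersect strictly inside the
    inter-set frame gap and the two height models differ by less than
    ``join_max_dy`` pixels at that intersection frame.
    """
    trajectories: list[Trajectory] = []
    for s in line_sets:
        if len({c.frame for c in s}) < 3:
            continue
        try:
            traj = Trajectory(frame_height=frame_height, members=list(s))
            traj.refit()
        except np.linalg.LinAlgError:
            continue
        traj.status = "selected"
        traj.ext_start, traj.ext_end = traj.frame_start, traj.frame_end
        trajectories.append(traj)
    trajectories.sort(key=lambda t: t.frame_start)

    for prev, nxt in zip(trajectories, trajectories[1:]):
        if abs(prev.m - nxt.m) < 1e-12:
            continue
        t_star = (nxt.b - prev.b) / (prev.m - nxt.m)
        if not (prev.frame_end < t_star < nxt.frame_start):
            continue
        y_prev = prev.a2 * t_star**2 + prev.a1 * t_star + prev.a0
        y_next = nxt.a2 * t_star**2 + nxt.a1 * t_star + nxt.a0
        if abs(y_prev - y_next) < cfg.join_max_dy:
            prev.ext_end = int(np.floor(t_star))
            nxt.ext_start = int(np.ceil(t_star))
            prev.interpolated.append((prev.frame_end + 1, prev.ext_end))
            nxt.interpolated.append((nxt.ext_start, nxt.frame_start - 1))
    return trajectories


def hough_trajectories(
    candidates: list[BallCandidate],
    cfg: HoughConfig,
    clip_length: int,
    frame_height: int,
) -> list[Trajectory]:
    """Full Hough pipeline: clean, detect line sets, fit and join."""
    filtered = remove_horizontal(candidates, cfg, clip_length, frame_height)
    sets = detect_line_sets(filtered, cfg, clip_length, frame_height)
    return fit_and_join(sets, cfg, frame_height)
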