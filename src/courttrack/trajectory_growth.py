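"""Incremental ball-trajectory building from per-frame candidates.

Between contacts the ball's image motion is modelled as a straight line in
x versus frame index and a downward parabola in height versus frame index:

    x(t) = m*t + b
    y_height(t) = a2*t^2 + a1*t + a0,   a2 < 0,

with y_height measured upward from the image bottom (frame_height - y_px)
so that gravity makes a2 negative.  A trajectory is seeded when at least
three nearby candidates (pairwise distance < 20 px) are collinear in the
x-t scatter; it is then extended frame by frame — the model predicts the
next position, the nearest candidate within a gate is absorbed and the fit
refreshed, and a run of more than three missing frames terminates it.  Of
trajectories overlapping in time only the best (most members, then lowest
residual) is kept, and the survivors are extrapolated from their equations
across the gaps for intersection finding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .ball_detection import BallCandidate

__all__ = [
    "GrowthConfig",
    "Trajectory",
    "fit_trajectory",
    "seed_trajectories",
    "extend",
    "select_parallel",
    "extrapolate",
    "grow_trajectories",
]


@dataclass
class GrowthConfig:
    seed_min_candidates: int = 3
    seed_max_dist_px: float = 20.0
    seed_collinearity_tol_px: float = 2.0
    match_tol_px: float = 10.0
    max_missing: int = 3

    def __post_init__(self):
        if min(self.seed_max_dist_px, self.seed_collinearity_tol_px, self.match_tol_px) <= 0:
            raise ValueError("gates must be positive")


@dataclass
class Trajectory:
    """A piecewise-ballistic track over a frame range."""

    frame_height: int
    members: list = field(default_factory=list)  # BallCandidate, sorted by frame
    a2: float = 0.0
    a1: float = 0.0
    a0: float = 0.0
    m: float = 0.0
    b: float = 0.0
    missing_run: int = 0
    status: str = "growing"  # growing | terminated | selected
    interpolated: list = field(default_factory=list)  # (t0, t1) inclusive extensions
    ext_start: int | None = None
    ext_end: int | None = None

    @property
    def frame_start(self) -> int:
        return self.members[0].frame

    @property
    def frame_end(self) -> int:
        return self.members[-1].frame

    def refit(self) -> None:
        self.a2, self.a1, self.a0, self.m, self.b = fit_trajectory(
            self.members, self.frame_height
        )

    def predict(self, t: float) -> tuple[float, float]:
        """(x_px, y_px) from the current model at frame t."""
        x = self.m * t + self.b
        y_h = self.a2 * t * t + self.a1 * t + self.a0
        return x, self.frame_height - y_h

    def rms_residual(self) -> float:
        if not self.members:
            return float("inf")
        errs = []
        for c in self.members:
            px, py = self.predict(c.frame)
            errs.append((c.x_px - px) ** 2 + (c.y_px - py) ** 2)
        return float(np.sqrt(np.mean(errs)))

    def covers(self, t: int) -> bool:
        lo = self.frame_start if self.ext_start is None else self.ext_start
        hi = self.frame_end if self.ext_end is None else self.ext_end
        return lo <= t <= hi


def fit_trajectory(members, frame_height: int):
    """Least-squares (a2, a1, a0, m, b) from member candidates.

    The parabola needs >= 3 members; with exactly 2 only the line is fit
    and the parabola falls back to the straight line through the heights
    (a2 = 0).  Noiseless inputs are recovered exactly.
    """
    if len(members) < 2:
        raise ValueError("need at least two members to fit")
    t = np.array([c.frame for c in members], dtype=float)
    if np.all(t == t[0]):
        raise np.linalg.LinAlgError("all members at one frame: rank-deficient fit")
    x = np.array([c.x_px for c in members], dtype=float)
    y_h = frame_height - np.array([c.y_px for c in members], dtype=float)
    m, b = np.polyfit(t, x, 1)
    if len(members) >= 3 and len(set(t)) >= 3:
        a2, a1, a0 = np.polyfit(t, y_h, 2)
    else:
        a1, a0 = np.polyfit(t, y_h, 1)
        a2 = 0.0
    return float(a2), float(a1), float(a0), float(m), float(b)


def _collinear_xt(triple, tol: float) -> bool:
    t = np.array([c.frame for c in triple], dtype=float)
    x = np.array([c.x_px for c in triple], dtype=float)
    if len(set(t)) < 3:
        return False
    coef = np.polyfit(t, x, 1)
    resid = x - np.polyval(coef, t)
    return bool(np.max(np.abs(resid)) < tol)


def seed_trajectories(
    buffer: list[BallCandidate],
    cfg: GrowthConfig,
    frame_height: int,
    claimed: set | None = None,
) -> list[Trajectory]:
    """Spawn trajectories from collinear close triples in the buffer.

    A triple must come from three distinct frames, have pairwise image
    distance below ``seed_max_dist_px`` and x-t collinearity residual below
    tolerance.  Triples whose members are all already claimed by a
    trajectory are skipped (dedup by shared members), and each new seed
    claims its members.
    """
    claimed = set() if claimed is None else claimed
    seeds: list[Trajectory] = []
    ordered = sorted(buffer, key=lambda c: (c.frame, c.x_px, c.y_px))
    for triple in itertools.combinations(ordered, 3):
        if len({c.frame for c in triple}) < 3:
            continue
        if all(id(c) in claimed for c in triple):
            continue
        pts = np.array([[c.x_px, c.y_px] for c in triple])
        dists = [np.hypot(*(pts[i] - pts[j])) for i, j in itertools.combinations(range(3), 2)]
        if max(dists) >= cfg.seed_max_dist_px:
            continue
        if not _collinear_xt(triple, cfg.seed_collinearity_tol_px):
            continue
        traj = Trajectory(frame_height=frame_height, members=sorted(triple, key=lambda c: c.frame))
        traj.refit()
        seeds.append(traj)
        claimed.update(id(c) for c in triple)
    return seeds


def extend(traj: Trajectory, candidates: list[BallCandidate], cfg: GrowthConfig, t: int) -> Trajectory:
    """Advance a growing trajectory to frame ``t``.

    The nearest candidate within ``match_tol_px`` of the model prediction
    is absorbed (ties broken toward lower x, then lower y) and the fit
    refreshed; otherwise the frame counts as missing, and more than
    ``max_missing`` consecutive missing frames terminate the trajectory.
    """
    if traj.status != "growing":
        return traj
    px, py = traj.predict(t)
    best = None
    best_key = None
    for c in candidates:
        d = np.hypot(c.x_px - px, c.y_px - py)
        if d >= cfg.match_tol_px:
            continue
        key = (d, c.x_px, c.y_px)
        if best_key is None or key < best_key:
            best, best_key = c, key
    if best is not None:
        traj.members.append(best)
        traj.members.sort(key=lambda c: c.frame)
        traj.refit()
        traj.missing_run = 0
    else:
        traj.missing_run += 1
        if traj.missing_run > cfg.max_missing:
            traj.status = "terminated"
    return traj


def select_parallel(trajectories: list[Trajectory]) -> list[Trajectory]:
    """Resolve time-overlapping trajectories to a disjoint set.

    Preference order: more members, then lower RMS residual.  The result
    contains no two trajectories overlapping in frames.
    """
    ranked = sorted(
        (t for t in trajectories if len(t.members) >= 2),
        key=lambda t: (-len(t.members), t.rms_residual(), t.frame_start),
    )
    kept: list[Trajectory] = []
    for t in ranked:
        if all(
            t.frame_end < k.frame_start or t.frame_start > k.frame_end for k in kept
        ):
            t.status = "selected"
            kept.append(t)
    kept.sort(key=lambda t: t.frame_start)
    return kept


def merge_collinear(selected: list[Trajectory], merge_tol_px: float = 5.0) -> list[Trajectory]:
    """Fuse consecutive trajectories that are fragments of one arc.

    Growth can break a single ballistic arc into pieces when candidates go
    missing for more than ``max_missing`` frames (apex stall, brief
    occlusion).  Two consecutive non-overlapping trajectories whose models
    mutually predict each other's members within ``merge_tol_px`` RMS are
    the same arc: they are refit on the union of members.  Applied
    repeatedly until stable.
    """

    def cross_rms(model: Trajectory, other: Trajectory) -> float:
        errs = []
        for c in other.members:
            px, py = model.predict(c.frame)
            errs.append((c.x_px - px) ** 2 + (c.y_px - py) ** 2)
        return float(np.sqrt(np.mean(errs))) if errs else float("inf")

    out = sorted(selected, key=lambda t: t.frame_start)
    changed = True
    while changed:
        changed = False
        for i in range(len(out) - 1):
            t1, t2 = out[i], out[i + 1]
            if len(t1.members) < 3 or len(t2.members) < 3:
                continue
            if cross_rms(t1, t2) < merge_tol_px and cross_rms(t2, t1) < merge_tol_px:
                merged = Trajectory(
                    frame_height=t1.frame_height,
                    members=sorted(t1.members + t2.members, key=lambda c: c.frame),
                    status="selected",
                )
                merged.refit()
                out[i : i + 2] = [merged]
                changed = True
                break
    return out


def _parabola_intersection(t1: Trajectory, t2: Trajectory, lo: float, hi: float) -> float | None:
    da2, da1, da0 = t1.a2 - t2.a2, t1.a1 - t2.a1, t1.a0 - t2.a0
    if abs(da2) < 1e-12:
        if abs(da1) < 1e-12:
            return None
        roots = [-da0 / da1]
    else:
        disc = da1 * da1 - 4 * da2 * da0
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        roots = [(-da1 - sq) / (2 * da2), (-da1 + sq) / (2 * da2)]
    mid = 0.5 * (lo + hi)
    inside = [r for r in roots if lo <= r <= hi]
    if not inside:
        return None
    return min(inside, key=lambda r: abs(r - mid))


def extrapolate(
    selected: list[Trajectory], clip_start: int = 0, clip_end: int | None = None
) -> list[Trajectory]:
    """Extend each selected trajectory's model beyond its members.

    Within each inter-trajectory gap the two neighbours are extended until
    they meet — at their height-parabola intersection when one lies in the
    gap, else at the gap midpoint.  The outermost trajectories extend to
    the clip bounds.  Member points are never altered; extension ranges are
    recorded as interpolated.
    """
    if not selected:
        return selected
    ordered = sorted(selected, key=lambda t: t.frame_start)
    for traj in ordered:
        traj.ext_start, traj.ext_end = traj.frame_start, traj.frame_end
    ordered[0].ext_start = min(clip_start, ordered[0].frame_start)
    if clip_end is not None:
        ordered[-1].ext_end = max(clip_end, ordered[-1].frame_end)
    for prev, nxt in zip(ordered, ordered[1:]):
        lo, hi = prev.frame_end, nxt.frame_start
        if hi <= lo + 1:
            continue
        meet = _parabola_intersection(prev, nxt, lo, hi)
        if meet is None:
            meet = 0.5 * (lo + hi)
        prev.ext_end = int(np.floor(meet))
        nxt.ext_start = int(np.ceil(meet))
    for traj in ordered:
        if traj.ext_start < traj.frame_start:
            traj.interpolated.append((traj.ext_start, traj.frame_start - 1))
        if traj.ext_end > traj.frame_end:
            traj.interpolated.append((traj.frame_end + 1, traj.ext_end))
    return ordered


def grow_trajectories(
    candidates_by_frame: dict[int, list[BallCandidate]],
    cfg: GrowthConfig,
    frame_height: int,
    n_frames: int | None = None,
) -> list[Trajectory]:
    """Run the full growth pass over per-frame candidates.

    Returns every trajectory ever grown (growing trajectories are closed
    at the end); selection and extrapolation are separate steps.
    """
    if n_frames is None:
        n_frames = (max(candidates_by_frame) + 1) if candidates_by_frame else 0
    trajectories: list[Trajectory] = []
    claimed: set = set()
    buffer: list[BallCandidate] = []
    window = cfg.seed_min_candidates + cfg.max_missing + 1
    for t in range(n_frames):
        cands = candidates_by_frame.get(t, [])
        for traj in trajectories:
            extended = extend(traj, cands, cfg, t)
            if extended.missing_run == 0 and extended.status == "growing" and extended.members:
                claimed.add(id(extended.members[-1]))
        buffer = [c for c in buffer if t - c.frame < window] + list(cands)
        fresh = [c for c in buffer if id(c) not in claimed]
        trajectories.extend(seed_trajectories(fresh, cfg, frame_height, claimed))
    for traj in trajectories:
        if traj.status == "growing":
            traj.status = "terminated"
    return trajectories
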