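"""Ball-contact time points from trajectory intersections.

Each hit starts a new ballistic arc, so the contact frame between two
consecutive trajectories is where their height parabolas intersect — the y
intersection is used because it localizes the contact more sharply than
the shallow x-line crossing.  The serve opens the rally without a
preceding arc, so the first contact is taken as the first trajectory's
initial frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_growth import Trajectory

__all__ = ["ContactEvent", "intersect_parabolas", "contacts"]


@dataclass
class ContactEvent:
    frame: int
    frame_fractional: float
    kind: str  # "serve" | "intersection"
    traj_a: int | None = None
    traj_b: int | None = None
    y_height: float | None = None


def intersect_parabolas(
    t1: Trajectory, t2: Trajectory, slack_frames: float = 15.0
) -> ContactEvent | None:
    """Intersection of two consecutive height parabolas, if any.

    Solves (a2-a2')t^2 + (a1-a1')t + (a0-a0') = 0 and keeps the real root
    closest to the midpoint of the inter-trajectory gap, provided it lies
    within the gap extended by ``slack_frames`` on each side.  Numerically
    identical parabolas are degenerate and yield no event.
    """
    da2 = t1.a2 - t2.a2
    da1 = t1.a1 - t2.a1
    da0 = t1.a0 - t2.a0
    if abs(da2) < 1e-12 and abs(da1) < 1e-12:
        return None
    if abs(da2) < 1e-12:
        roots = np.array([-da0 / da1])
    else:
        disc = da1 * da1 - 4.0 * da2 * da0
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        roots = np.array([(-da1 - sq) / (2 * da2), (-da1 + sq) / (2 * da2)])
    lo, hi = t1.frame_end, t2.frame_start
    mid = 0.5 * (lo + hi)
    ok = roots[(roots >= lo - slack_frames) & (roots <= hi + slack_frames)]
    if ok.size == 0:
        return None
    t_star = float(ok[np.argmin(np.abs(ok - mid))])
    y = t1.a2 * t_star**2 + t1.a1 * t_star + t1.a0
    return ContactEvent(
        frame=int(round(t_star)), frame_fractional=t_star, kind="intersection",
        y_height=float(y),
    )


def contacts(trajectories: list[Trajectory], slack_frames: float = 15.0) -> list[ContactEvent]:
    """Ordered contact events for a time-ordered, non-overlapping rally.

    The first event is the serve (initial frame of the first trajectory);
    then one event per consecutive pair with a valid parabola
    intersection.  Events are strictly increasing in frame.
    """
    ordered = sorted(trajectories, key=lambda t: t.frame_start)
    if not ordered:
        return []
    events = [
        ContactEvent(
            frame=ordered[0].frame_start,
            frame_fractional=float(ordered[0].frame_start),
            kind="serve",
            traj_a=0,
        )
    ]
    for i, (t1, t2) in enumerate(zip(ordered, ordered[1:])):
        ev = intersect_parabolas(t1, t2, slack_frames)
        if ev is None:
            continue
        ev.traj_a, ev.traj_b = i, i + 1
        if ev.frame > events[-1].frame:
            events.append(ev)
    return events
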