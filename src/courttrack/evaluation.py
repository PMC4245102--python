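"""Accuracy protocol for player tracks, ball trajectories and contacts.

A player frame counts as correctly tracked when the estimate is within
0.5 m of the reference in world coordinates or within 20 px in the image
(the pixel criterion matters for the far half of the court, where half a
meter is only a handful of pixels).  Evaluation starts once all four
players have been correct for two consecutive frames and then samples
every third frame.  Identity swaps between players of the same team can
optionally be forgiven, since same-team kits are often near identical.
Ball frames are correct within 20 px; contact frames within (strictly
less than) 10 frames of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = ["EvalConfig", "player_accuracy", "ball_accuracy", "contact_accuracy"]


@dataclass
class EvalConfig:
    player_dist_m: float = 0.5
    player_dist_px: float = 20.0
    ball_dist_px: float = 20.0
    contact_tol_frames: int = 10
    eval_stride: int = 3
    warmup_consecutive: int = 2
    allow_team_swaps: bool = False
    teams: tuple = ((1, 2), (3, 4))  # player ids per team


def _frame_correct(track_row, ref_row, cfg: EvalConfig) -> bool:
    dw = np.hypot(track_row["x_m"] - ref_row["x_m"], track_row["y_m"] - ref_row["y_m"])
    dp = np.hypot(track_row["x_px"] - ref_row["x_px"], track_row["y_px"] - ref_row["y_px"])
    return bool(dw < cfg.player_dist_m or dp < cfg.player_dist_px)


def _frame_assignment(tr: dict, rf: dict, cfg: EvalConfig) -> dict[int, bool]:
    """Per-player correctness for one frame, honoring the swap policy."""
    ids = sorted(rf)
    direct = {pid: pid in tr and _frame_correct(tr[pid], rf[pid], cfg) for pid in ids}
    if not cfg.allow_team_swaps:
        return direct
    best = direct
    for team in cfg.teams:
        members = [p for p in team if p in ids and p in tr]
        if len(members) < 2:
            continue
        for perm in permutations(members):
            if perm == tuple(members):
                continue
            cand = dict(best)
            for src, dst in zip(members, perm):
                cand[dst] = _frame_correct(tr[src], rf[dst], cfg)
            if sum(cand[p] for p in members) > sum(best[p] for p in members):
                best = cand
    return best


def player_accuracy(tracks: pd.DataFrame, reference: pd.DataFrame, cfg: EvalConfig = EvalConfig()):
    """Percent correctly tracked frames per player and front/back average.

    ``tracks``/``reference`` columns: frame, player_id, x_m, y_m, x_px,
    y_px.  Players with reference mean y below the court midline are
    reported as "front".  Frames missing from the reference are excluded
    (count reported).
    """
    t_by = {
        (int(r.frame), int(r.player_id)): r for r in tracks.itertuples()
    }
    r_by_frame: dict[int, dict] = {}
    for r in reference.itertuples():
        r_by_frame.setdefault(int(r.frame), {})[int(r.player_id)] = r
    ids = sorted(int(p) for p in reference["player_id"].unique())
    frames = sorted(r_by_frame)

    def correctness(frame):
        rf = r_by_frame[frame]
        tr = {pid: t_by[(frame, pid)] for pid in rf if (frame, pid) in t_by}
        tr_rows = {pid: {"x_m": v.x_m, "y_m": v.y_m, "x_px": v.x_px, "y_px": v.y_px} for pid, v in tr.items()}
        rf_rows = {pid: {"x_m": v.x_m, "y_m": v.y_m, "x_px": v.x_px, "y_px": v.y_px} for pid, v in rf.items()}
        return _frame_assignment(tr_rows, rf_rows, cfg)

    # warm-up: first frame where all players are correct warmup_consecutive
    # consecutive reference frames in a row
    start = None
    run = 0
    for f in frames:
        c = correctness(f)
        if all(c.get(pid, False) for pid in ids):
            run += 1
            if run >= cfg.warmup_consecutive:
                start = f
                break
        else:
            run = 0
    if start is None:
        start = frames[0] if frames else 0

    eval_frames = [f for f in frames[frames.index(start) :]][:: cfg.eval_stride] if frames else []
    per_player = {pid: [] for pid in ids}
    missing = 0
    for f in eval_frames:
        c = correctness(f)
        for pid in ids:
            if pid not in r_by_frame[f]:
                missing += 1
                continue
            per_player[pid].append(c.get(pid, False))

    pct = {
        pid: (float(100.0 * np.mean(v)) if v else 0.0) for pid, v in per_player.items()
    }
    mid = reference["y_m"].max() / 2.0 if len(reference) else 0.0
    mean_y = reference.groupby("player_id")["y_m"].mean()
    front = [pid for pid in ids if mean_y[pid] <= mid]
    back = [pid for pid in ids if mean_y[pid] > mid]
    report = {
        "per_player_pct": pct,
        "front_avg_pct": float(np.mean([pct[p] for p in front])) if front else float("nan"),
        "back_avg_pct": float(np.mean([pct[p] for p in back])) if back else float("nan"),
        "evaluated_frames": len(eval_frames),
        "start_frame": start,
        "missing_reference_rows": missing,
    }
    return report


def ball_accuracy(trajectories, reference: pd.DataFrame, cfg: EvalConfig = EvalConfig()):
    """Ball tracking report over every ``eval_stride``-th reference frame.

    ``trajectories`` is a list of fitted (possibly extended) trajectories;
    a frame is tracked when some trajectory covers it, and correct when
    the model position is within ``ball_dist_px`` of the reference.
    Percentages are reported against both total and tracked frames.
    """
    frames = sorted(reference["frame"].astype(int))[:: cfg.eval_stride]
    ref_by = {int(r.frame): (float(r.x_px), float(r.y_px)) for r in reference.itertuples()}
    total = len(frames)
    tracked = 0
    correct = 0
    for f in frames:
        cover = [t for t in trajectories if t.covers(f)]
        if not cover:
            continue
        tracked += 1
        x, y = cover[0].predict(f)
        rx, ry = ref_by[f]
        if np.hypot(x - rx, y - ry) < cfg.ball_dist_px:
            correct += 1
    return {
        "total_frames": total,
        "tracked_frames": tracked,
        "correct_frames": correct,
        "pct_of_total": 100.0 * correct / total if total else 0.0,
        "pct_of_tracked": 100.0 * correct / tracked if tracked else 0.0,
    }


def contact_accuracy(events, reference_frames, cfg: EvalConfig = EvalConfig()):
    """Greedy one-to-one matching of contact events to reference frames.

    Both lists are walked in time order; an event matches the earliest
    unmatched reference within strictly less than ``contact_tol_frames``.
    """
    est = sorted(e.frame if hasattr(e, "frame") else int(e) for e in events)
    ref = sorted(int(f) for f in reference_frames)
    used = [False] * len(ref)
    correct = 0
    for f in est:
        for i, rf in enumerate(ref):
            if used[i]:
                continue
            if abs(f - rf) < cfg.contact_tol_frames:
                used[i] = True
                correct += 1
                break
    total = len(ref)
    return {
        "reference_contacts": total,
        "estimated_contacts": len(est),
        "correct_contacts": correct,
        "pct_correct": 100.0 * correct / total if total else 0.0,
    }
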