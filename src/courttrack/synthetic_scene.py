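"""Seeded synthetic court scenes with exact ground truth.

The generator renders what the tracking stack consumes — a fixed
perspective camera over an 8 x 16 m court, a textured sand-like
background, four players as vertically banded color blobs whose size
follows the homography, and a small bright ball flying piecewise-ballistic
arcs between scheduled contacts — and emits the exact ground truth
alongside.  It is the test substrate for the whole pipeline: every scene
parameter (colors, paths, noise, illumination steps, clutter) is explicit
and every frame is reproducible from the seed.

Ball arcs are generated directly in image coordinates as a line in x
versus frame and a parabola in height versus frame, with the quadratic
coefficient set by gravity scaled to frames and pixels
(a2 = -g * s / (2 * fps^2), s the local pixel scale at the arc midpoint),
so a trajectory fitted to clean rendered positions recovers the generating
coefficients exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    CourtCalibration,
    Homography,
    estimate_homography,
    local_scale,
    world_to_image,
)

__all__ = [
    "PlayerSpec",
    "ContactSpec",
    "BallSpec",
    "ClutterSpec",
    "ScenarioConfig",
    "GroundTruth",
    "default_camera",
    "render_rally",
    "generate",
]

GRAVITY = 9.81  # m/s^2


@dataclass
class PlayerSpec:
    """One player blob: id, 4 band colors (top to bottom), waypoint path."""

    player_id: int
    band_colors: list            # 4 RGB uint8 triples, head to legs
    waypoints: list              # (frame, x_m, y_m), frame ascending
    width_m: float = 0.6
    height_m: float = 1.8

    def position(self, frame: int) -> np.ndarray:
        wp = self.waypoints
        if frame <= wp[0][0]:
            return np.array(wp[0][1:3], dtype=float)
        if frame >= wp[-1][0]:
            return np.array(wp[-1][1:3], dtype=float)
        for (f0, x0, y0), (f1, x1, y1) in zip(wp, wp[1:]):
            if f0 <= frame <= f1:
                u = (frame - f0) / (f1 - f0) if f1 > f0 else 0.0
                return np.array([x0 + u * (x1 - x0), y0 + u * (y1 - y0)])
        return np.array(wp[-1][1:3], dtype=float)


@dataclass
class ContactSpec:
    """A ball contact: frame, ground position (m) and contact height (m)."""

    frame: int
    x_m: float
    y_m: float
    height_m: float = 1.5


@dataclass
class BallSpec:
    contacts: list = field(default_factory=list)  # ContactSpec, frames increasing
    radius_px_mid: float = 4.2       # 0.21 m ball at the default mid-court scale
    color: tuple = (255, 250, 210)


@dataclass
class ClutterSpec:
    texture_sigma: float = 6.0        # static spatial texture on the sand
    noise_sigma: float = 2.0          # per-frame pixel noise (below threshold)
    net: bool = True
    net_height_m: float = 2.4
    illumination_steps: list = field(default_factory=list)  # (frame, gain)
    spectator_rate: float = 0.0       # flickering blobs per frame in the top band


@dataclass
class ScenarioConfig:
    frame_size: tuple = (480, 640)    # (height, width)
    fps: float = 25.0
    n_frames: int = 100
    warmup_frames: int = 0            # empty-court lead-in before players appear
    image_corners: np.ndarray | None = None
    players: list = field(default_factory=list)
    ball: BallSpec | None = None
    clutter: ClutterSpec = field(default_factory=ClutterSpec)
    sand_color: tuple = (194, 178, 128)
    seed: int = 0

    def __post_init__(self):
        if self.image_corners is None:
            self.image_corners = default_camera(self.frame_size)
        for p in self.players:
            for _, x, y in p.waypoints:
                if not (-2.0 <= x <= 10.0 and -2.0 <= y <= 18.0):
                    raise ValueError("player path leaves court + 2 m margin")
        if self.ball is not None:
            fr = [c.frame for c in self.ball.contacts]
            if any(b <= a for a, b in zip(fr, fr[1:])):
                raise ValueError("contact schedule must be strictly increasing in frame")

    def calibration(self) -> CourtCalibration:
        return CourtCalibration(image_corners=self.image_corners)

    def homography(self) -> Homography:
        return estimate_homography(self.calibration())


def default_camera(frame_size) -> np.ndarray:
    """Perspective preset: camera behind the near baseline, court trapezoid."""
    h, w = frame_size
    base = np.array([[70, 460], [570, 460], [430, 130], [210, 130]], dtype=float)
    return base * np.array([w / 640.0, h / 480.0])


@dataclass
class GroundTruth:
    players: pd.DataFrame       # frame, player_id, x_m, y_m, x_px, y_px
    ball: pd.DataFrame          # frame, x_px, y_px
    contacts: list              # contact frames
    arc_coefficients: list      # per arc: (a2, a1, a0, m, b, f0, f1)


def render_rally(ball: BallSpec, h: Homography, fps: float, frame_height: int):
    """Per-frame ball pixel positions for a contact schedule.

    Between consecutive contacts the pixel x is linear in frame and the
    pixel height (frame_height - y_px) parabolic with the gravity-scaled
    a2; arcs are continuous at the contacts by construction.  Returns
    (positions DataFrame, per-arc coefficient tuples).
    """
    contacts = ball.contacts
    if len(contacts) < 2:
        raise ValueError("need at least two contacts to span an arc")
    rows = []
    coeffs = []
    anchors = []
    for c in contacts:
        ground = np.array([c.x_m, c.y_m])
        px = world_to_image(h, ground)
        s = local_scale(h, ground)
        anchors.append((px[0], (frame_height - px[1]) + c.height_m * s))
    for (c0, c1), (p0, p1) in zip(zip(contacts, contacts[1:]), zip(anchors, anchors[1:])):
        f0, f1 = c0.frame, c1.frame
        mid = np.array([(c0.x_m + c1.x_m) / 2.0, (c0.y_m + c1.y_m) / 2.0])
        s_mid = local_scale(h, mid)
        a2 = -0.5 * GRAVITY * s_mid / (fps * fps)
        # line through the two anchor x positions
        m = (p1[0] - p0[0]) / (f1 - f0)
        b = p0[0] - m * f0
        # parabola through the two anchor heights with fixed a2
        a1 = (p1[1] - p0[1] - a2 * (f1 * f1 - f0 * f0)) / (f1 - f0)
        a0 = p0[1] - a2 * f0 * f0 - a1 * f0
        coeffs.append((a2, a1, a0, m, b, f0, f1))
        last = f1 if c1 is contacts[-1] else f1 - 1
        for t in range(f0, last + 1):
            x = m * t + b
            y_px = frame_height - (a2 * t * t + a1 * t + a0)
            rows.append((t, x, y_px))
    df = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
    return df, coeffs


def _draw_rect(img, x0, y0, x1, y1, color):
    h, w = img.shape[:2]
    x0, y0 = max(int(round(x0)), 0), max(int(round(y0)), 0)
    x1, y1 = min(int(round(x1)), w), min(int(round(y1)), h)
    if x1 > x0 and y1 > y0:
        img[y0:y1, x0:x1] = color


def _draw_disk(img, cx, cy, r, color):
    h, w = img.shape[:2]
    x0, x1 = max(int(cx - r - 1), 0), min(int(cx + r + 2), w)
    y0, y1 = max(int(cy - r - 1), 0), min(int(cy + r + 2), h)
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    img[y0:y1, x0:x1][mask] = color


def _background(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.frame_size
    base = np.full((h, w, 3), cfg.sand_color, dtype=float)
    base += rng.normal(0.0, cfg.clutter.texture_sigma, (h, w, 1))
    if cfg.clutter.net:
        hom = cfg.homography()
        for x in np.linspace(0.0, 8.0, 200):
            g = np.array([x, 8.0])
            px = world_to_image(hom, g)
            top = px[1] - cfg.clutter.net_height_m * local_scale(hom, g)
            _draw_rect(base, px[0], top, px[0] + 2, top + 2, (240, 240, 240))
    return np.clip(base, 0, 255)


def generate(cfg: ScenarioConfig):
    """Render the scenario; returns (frames uint8 (T,H,W,3), GroundTruth)."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame_size
    hom = cfg.homography()
    bg = _background(cfg, rng)

    ball_df = pd.DataFrame(columns=["frame", "x_px", "y_px"])
    arc_coeffs: list = []
    ball_radius: dict[int, float] = {}
    if cfg.ball is not None and len(cfg.ball.contacts) >= 2:
        ball_df, arc_coeffs = render_rally(cfg.ball, hom, cfg.fps, h)
        mid_scale = local_scale(hom, (4.0, 8.0))
        for a2, a1, a0, m, b, f0, f1 in arc_coeffs:
            c0 = next(c for c in cfg.ball.contacts if c.frame == f0)
            c1 = next(c for c in cfg.ball.contacts if c.frame == f1)
            mid = ((c0.x_m + c1.x_m) / 2.0, (c0.y_m + c1.y_m) / 2.0)
            r = cfg.ball.radius_px_mid * local_scale(hom, mid) / mid_scale
            for t in range(f0, f1 + 1):
                ball_radius.setdefault(t, r)
    ball_by_frame = {int(r.frame): (r.x_px, r.y_px) for r in ball_df.itertuples()}

    gains = np.ones(cfg.n_frames)
    for f_step, gain in cfg.clutter.illumination_steps:
        gains[f_step:] = gain

    frames = np.empty((cfg.n_frames, h, w, 3), dtype=np.uint8)
    player_rows = []
    for t in range(cfg.n_frames):
        img = bg.copy()
        if t >= cfg.warmup_frames:
            # draw far players first so near ones occlude them
            order = sorted(cfg.players, key=lambda p: -p.position(t)[1])
            for p in order:
                pos = p.position(t)
                px = world_to_image(hom, pos)
                s = local_scale(hom, pos)
                bw = p.width_m * s
                bh = p.height_m * s
                band_h = bh / len(p.band_colors)
                for k, color in enumerate(p.band_colors):
                    _draw_rect(
                        img,
                        px[0] - bw / 2,
                        px[1] - bh + k * band_h,
                        px[0] + bw / 2,
                        px[1] - bh + (k + 1) * band_h,
                        color,
                    )
            for p in cfg.players:
                pos = p.position(t)
                px = world_to_image(hom, pos)
                player_rows.append((t, p.player_id, pos[0], pos[1], px[0], px[1]))
        if t in ball_by_frame:
            bx, by = ball_by_frame[t]
            _draw_disk(img, bx, by, ball_radius.get(t, cfg.ball.radius_px_mid), cfg.ball.color)
        if cfg.clutter.spectator_rate > 0 and rng.random() < cfg.clutter.spectator_rate:
            sx = rng.uniform(0, w)
            sy = rng.uniform(0, h * 0.15)
            _draw_disk(img, sx, sy, 2.0, (250, 250, 250))
        img = img * gains[t]
        if cfg.clutter.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.clutter.noise_sigma, (h, w, 1))
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    gt = GroundTruth(
        players=pd.DataFrame(
            player_rows, columns=["frame", "player_id", "x_m", "y_m", "x_px", "y_px"]
        ),
        ball=ball_df,
        contacts=[c.frame for c in (cfg.ball.contacts if cfg.ball else [])],
        arc_coefficients=arc_coeffs,
    )
    return frames, gt


def benchmark_players_scenario(seed: int = 0, frame_size=(240, 320)) -> ScenarioConfig:
    """The standard four-player benchmark scene.

    40 empty-court warm-up frames let the background model settle; the
    four players then appear, stand for 20 frames (calibration window) and
    walk waypoint paths for 300 frames that include one front-pair and one
    back-pair path crossing.  Band colors put the two teams in clearly
    separated hue families (reds/blues front, greens/purples back).
    """
    players = [
        PlayerSpec(1, [(60, 10, 10), (220, 40, 40), (180, 20, 30), (240, 90, 80)],
                   [(40, 2.0, 3.0), (60, 2.0, 3.0), (140, 6.0, 3.0), (220, 2.5, 4.5), (339, 2.5, 4.5)]),
        PlayerSpec(2, [(10, 20, 70), (40, 80, 220), (30, 50, 180), (90, 130, 240)],
                   [(40, 6.0, 3.0), (60, 6.0, 3.0), (140, 2.0, 3.0), (220, 5.0, 5.0), (339, 5.0, 5.0)]),
        PlayerSpec(3, [(20, 60, 20), (40, 190, 60), (30, 150, 40), (110, 230, 120)],
                   [(40, 2.0, 12.0), (80, 2.0, 12.0), (180, 6.0, 12.5), (260, 3.0, 11.0), (339, 3.0, 11.0)]),
        PlayerSpec(4, [(60, 15, 70), (170, 50, 210), (140, 30, 170), (210, 120, 240)],
                   [(40, 6.0, 12.0), (80, 6.0, 12.0), (180, 2.5, 12.5), (260, 5.5, 13.0), (339, 5.5, 13.0)]),
    ]
    return ScenarioConfig(
        frame_size=frame_size,
        n_frames=340,
        warmup_frames=40,
        players=players,
        ball=None,
        seed=seed,
    )


def rally_scenario(seed: int = 0, frame_size=(480, 640), n_arcs: int = 6,
                   start_frame: int = 5, arc_frames: int = 24) -> ScenarioConfig:
    """A ball-only rally: ``n_arcs`` lob-like arcs alternating across mid-court.

    Contacts alternate between the two court sides at hitting height, with
    ground positions varied slightly by the seed so different seeds give
    different (still ballistic) rallies.  The default geometry gives launch
    speeds under ~10 px/frame, inside the 20 px candidate-pairing gate of
    the trajectory seeding — an easy, controlled rally rather than a
    worst-case smash exchange.
    """
    rng = np.random.default_rng(seed)
    contacts = []
    for k in range(n_arcs + 1):
        side = k % 2
        x = float(rng.uniform(2.7, 3.0)) if side == 0 else float(rng.uniform(5.0, 5.3))
        y = 5.2 + rng.uniform(-0.2, 0.2) if side == 0 else 8.8 + rng.uniform(-0.2, 0.2)
        contacts.append(
            ContactSpec(frame=start_frame + k * arc_frames, x_m=x, y_m=float(y),
                        height_m=float(rng.uniform(1.5, 1.7)))
        )
    return ScenarioConfig(
        frame_size=frame_size,
        n_frames=start_frame + n_arcs * arc_frames + 10,
        warmup_frames=0,
        players=[],
        ball=BallSpec(contacts=contacts),
        clutter=ClutterSpec(noise_sigma=2.0, texture_sigma=6.0),
        seed=seed,
    )


def truth_candidates(ball_df: pd.DataFrame, sigma_px: float = 0.0, rng=None):
    """Per-frame ball candidates taken directly from ground-truth positions.

    Bypasses the pixel detector: one candidate per ground-truth ball frame,
    optionally perturbed by isotropic Gaussian pixel noise.  Used to test
    the trajectory machinery under controlled candidate error.
    """
    from .ball_detection import BallCandidate

    rng = np.random.default_rng(0) if rng is None else rng
    out: dict[int, list] = {}
    for r in ball_df.itertuples():
        x, y = float(r.x_px), float(r.y_px)
        if sigma_px > 0:
            x += rng.normal(0.0, sigma_px)
            y += rng.normal(0.0, sigma_px)
        out.setdefault(int(r.frame), []).append(
            BallCandidate(frame=int(r.frame), x_px=x, y_px=y, area=50, margin=0)
        )
    return out
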