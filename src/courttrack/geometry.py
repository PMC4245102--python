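"""Court calibration and image <-> world coordinate geometry.

A fixed camera views a planar court.  The mapping between image pixels and
court-plane coordinates (meters) is a 3x3 planar homography estimated from
the four court corners clicked in a calibration frame.  All player state is
kept in world coordinates; this module also supplies the perspective-correct
sizing used to place a player's bounding box and its horizontal subwindows
in the image.

Conventions: pixel coordinates are 0-based with origin at the top-left and
y growing downward; world coordinates are meters with the court an
axis-aligned rectangle, origin at one corner, y along the court length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationError",
    "CourtCalibration",
    "Homography",
    "Rect",
    "estimate_homography",
    "image_to_world",
    "world_to_image",
    "local_scale",
    "project_box",
]


class CalibrationError(ValueError):
    """Raised for degenerate corner configurations or invalid mappings."""


def _default_world_corners() -> np.ndarray:
    return np.array([[0.0, 0.0], [8.0, 0.0], [8.0, 16.0], [0.0, 16.0]])


@dataclass
class CourtCalibration:
    """Four image-pixel corners matched to four court-plane corners.

    The world corners default to the 8 x 16 m court rectangle
    (0,0), (8,0), (8,16), (0,16); both lists are in corresponding order.
    """

    image_corners: np.ndarray
    world_corners: np.ndarray = field(default_factory=_default_world_corners)
    court_width_m: float = 8.0
    court_length_m: float = 16.0

    def __post_init__(self) -> None:
        self.image_corners = np.asarray(self.image_corners, dtype=float)
        self.world_corners = np.asarray(self.world_corners, dtype=float)
        if self.image_corners.shape != (4, 2) or self.world_corners.shape != (4, 2):
            raise CalibrationError("need exactly four 2-D corners on each plane")
        if _any_three_collinear(self.image_corners):
            raise CalibrationError("image corners are degenerate (three collinear)")


@dataclass
class Homography:
    """Normalized 3x3 projective map, direction image -> world."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise CalibrationError("homography must be 3x3")
        if abs(m[2, 2]) < 1e-15 or not np.isfinite(np.linalg.cond(m)):
            raise CalibrationError("homography is singular")
        self.matrix = m / m[2, 2]

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def _any_three_collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    from itertools import combinations

    for i, j, k in combinations(range(len(pts)), 3):
        a, b, c = pts[i], pts[j], pts[k]
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        scale = max(1.0, float(np.abs(pts).max()))
        if area2 <= tol * scale * scale:
            return True
    return False


def estimate_homography(calibration: CourtCalibration) -> Homography:
    """Solve the image->world homography from the four corner correspondences.

    Uses the normalized direct linear transform: both point sets are
    translated to their centroid and isotropically scaled to RMS sqrt(2)
    before assembling the 8x9 system, whose null vector (via SVD) is the
    homography.  With exactly four non-degenerate correspondences the solve
    is exact: each image corner maps onto its world corner to ~1e-9 m.
    """
    src = calibration.image_corners
    dst = calibration.world_corners
    if _any_three_collinear(src) or _any_three_collinear(dst):
        raise CalibrationError("collinear corners: homography underdetermined")

    def normalizer(pts: np.ndarray) -> np.ndarray:
        centroid = pts.mean(axis=0)
        rms = np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean())
        s = np.sqrt(2.0) / rms if rms > 0 else 1.0
        return np.array(
            [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
        )

    t_src = normalizer(src)
    t_dst = normalizer(dst)
    sh = (t_src @ np.column_stack([src, np.ones(4)]).T).T
    dh = (t_dst @ np.column_stack([dst, np.ones(4)]).T).T

    rows = []
    for (x, y, _), (u, v, _) in zip(sh, dh):
        rows.append([x, y, 1, 0, 0, 0, -u * x, -u * y, -u])
        rows.append([0, 0, 0, x, y, 1, -v * x, -v * y, -v])
    a = np.asarray(rows)
    _, _, vt = np.linalg.svd(a)
    h_norm = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ h_norm @ t_src
    return Homography(h)


def _apply(matrix: np.ndarray, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    hom = matrix @ np.column_stack([pts, np.ones(len(pts))]).T
    w = hom[2]
    if np.any(np.abs(w) < 1e-12):
        raise CalibrationError("point maps to the plane at infinity")
    out = (hom[:2] / w).T
    return out[0] if single else out


def image_to_world(h: Homography, p) -> np.ndarray:
    """Map pixel point(s) to court-plane meters."""
    return _apply(h.matrix, p)


def world_to_image(h: Homography, p) -> np.ndarray:
    """Map court-plane point(s) in meters to image pixels."""
    return _apply(h.inverse, p)


def local_scale(h: Homography, p) -> float:
    """Pixels-per-meter at world point ``p``.

    Image length of a 1 m segment centered at ``p`` along the court x-axis,
    by finite difference at +-0.5 m.
    """
    p = np.asarray(p, dtype=float)
    a = world_to_image(h, p + [0.5, 0.0])
    b = world_to_image(h, p - [0.5, 0.0])
    s = float(np.hypot(*(a - b)))
    if s <= 0:
        raise CalibrationError("non-positive local scale")
    return s


@dataclass(frozen=True)
class Rect:
    """Half-open integer pixel rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def empty(self) -> bool:
        return self.x1 <= self.x0 or self.y1 <= self.y0

    def clip(self, frame_shape) -> "Rect":
        h, w = frame_shape[:2]
        return Rect(
            max(self.x0, 0), max(self.y0, 0), min(self.x1, w), min(self.y1, h)
        )


@dataclass
class ProjectedBox:
    """A player's square image box plus its horizontal subwindow bands."""

    box: Rect
    subwindows: list  # top-to-bottom Rects tiling box
    clipped: bool
    empty: bool
    side_px: float


def project_box(
    h: Homography,
    foot_point,
    height_m: float = 2.0,
    n_subwindows: int = 4,
    frame_shape=None,
) -> ProjectedBox:
    """Square bounding box for a player standing at ``foot_point``.

    Side = ``height_m`` times the local pixel scale, anchored with its
    bottom-center at the image of the foot point (calibration clicks are
    placed between the feet).  The box is split into ``n_subwindows``
    equal-height horizontal bands, ordered top to bottom, that tile it
    exactly.  If ``frame_shape`` is given the rectangles are clipped to the
    frame and clipping/emptiness is flagged.
    """
    if height_m <= 0:
        raise ValueError("height_m must be positive")
    if n_subwindows < 1:
        raise ValueError("n_subwindows must be >= 1")
    side = height_m * local_scale(h, foot_point)
    cx, cy = world_to_image(h, foot_point)
    x0 = int(round(cx - side / 2.0))
    x1 = x0 + max(int(round(side)), 1)
    y1 = int(round(cy))
    y0 = y1 - (x1 - x0)
    box = Rect(x0, y0, x1, y1)

    edges = [y0 + int(round(k * (y1 - y0) / n_subwindows)) for k in range(n_subwindows + 1)]
    bands = [Rect(x0, edges[k], x1, edges[k + 1]) for k in range(n_subwindows)]

    clipped = False
    empty = False
    if frame_shape is not None:
        cbox = box.clip(frame_shape)
        cbands = [b.clip(frame_shape) for b in bands]
        clipped = cbox != box
        empty = cbox.empty
        box, bands = cbox, cbands
    return ProjectedBox(box=box, subwindows=bands, clipped=clipped, empty=empty, side_px=side)
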