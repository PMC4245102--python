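"""HSV histogram machinery and the multi-cue particle weighting.

Each player hypothesis carries a square image box split into horizontal
subwindows.  Appearance is summarized per subwindow by a 1-D HSV histogram:
an N_H x N_S chroma block (joint hue/saturation binning) with N_V value
bins appended, B = N_H*N_S + N_V bins total (110 with the 10/10/10
default).  Every foreground (nonzero-mask) pixel contributes one chroma
count and one value count.  Histograms are compared with the Bhattacharyya
distance; the per-subwindow scores are combined by multiplying the upper
subwindows (tight spatial coupling of head/torso) and adding the lowest
one (legs, loosely coupled).  Foreground-mask and movement cues are
normalized non-zero pixel counts over the same subwindows.

The integral-histogram form supports the rigid-grid tracker: a cumulative
per-bin count image from which any axis-aligned rectangle's histogram is
recovered exactly with four corner lookups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "HistogramConfig",
    "HSVHistogram",
    "ReferenceAppearance",
    "CueWeights",
    "hsv_bin_indices",
    "hsv_histogram",
    "IntegralHistogram",
    "integral_histogram",
    "bhattacharyya",
    "color_score",
    "count_score",
    "total_weight",
]


@dataclass(frozen=True)
class HistogramConfig:
    """Bin counts per HSV channel; B = N_H*N_S + N_V total bins."""

    n_h: int = 10
    n_s: int = 10
    n_v: int = 10

    def __post_init__(self):
        if min(self.n_h, self.n_s, self.n_v) < 1:
            raise ValueError("bin counts must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.n_h * self.n_s + self.n_v


@dataclass
class HSVHistogram:
    """Integer-count HSV histogram of a masked region.

    ``n_pixels`` counts contributing (nonzero-mask) pixels; each contributes
    one chroma and one value count, so bins sum to 2*n_pixels.
    """

    bins: np.ndarray
    n_pixels: int

    @property
    def empty(self) -> bool:
        return self.n_pixels == 0

    def normalized(self) -> np.ndarray:
        total = self.bins.sum()
        if total == 0:
            return np.zeros_like(self.bins, dtype=float)
        return self.bins / float(total)


def hsv_bin_indices(region_rgb: np.ndarray, config: HistogramConfig):
    """Per-pixel (chroma_bin, value_bin, mask) for an RGB uint8 region.

    Hue spans [0, 360), saturation and value [0, 1], binned uniformly;
    top-of-range values fall in the last bin.  The mask is nonzero where
    any channel is nonzero (masked frames zero out the background).
    """
    region_rgb = np.asarray(region_rgb)
    mask = region_rgb.any(axis=-1)
    hsv = rgb2hsv(region_rgb)  # all channels in [0, 1]
    h_idx = np.minimum((hsv[..., 0] * config.n_h).astype(np.int64), config.n_h - 1)
    s_idx = np.minimum((hsv[..., 1] * config.n_s).astype(np.int64), config.n_s - 1)
    v_idx = np.minimum((hsv[..., 2] * config.n_v).astype(np.int64), config.n_v - 1)
    chroma = h_idx * config.n_s + s_idx
    value = config.n_h * config.n_s + v_idx
    return chroma, value, mask


def hsv_histogram(region_rgb: np.ndarray, config: HistogramConfig = HistogramConfig()) -> HSVHistogram:
    """Histogram of the nonzero (foreground) pixels of a masked RGB region."""
    chroma, value, mask = hsv_bin_indices(region_rgb, config)
    b = config.n_bins
    if not mask.any():
        return HSVHistogram(bins=np.zeros(b, dtype=np.int64), n_pixels=0)
    bins = np.bincount(chroma[mask], minlength=b) + np.bincount(value[mask], minlength=b)
    return HSVHistogram(bins=bins.astype(np.int64), n_pixels=int(mask.sum()))


@dataclass
class IntegralHistogram:
    """Cumulative per-bin counts; ``table[y, x, b]`` sums rows < y, cols < x."""

    table: np.ndarray  # (H+1, W+1, B) int32
    config: HistogramConfig

    def region(self, x0: int, y0: int, x1: int, y1: int) -> HSVHistogram:
        """Histogram of the half-open rectangle [x0,x1) x [y0,y1).

        Exactly equal (bitwise) to brute-force ``hsv_histogram`` of the same
        rectangle: four corner lookups per bin, integer arithmetic only.
        """
        t = self.table
        bins = (t[y1, x1] - t[y0, x1] - t[y1, x0] + t[y0, x0]).astype(np.int64)
        return HSVHistogram(bins=bins, n_pixels=int(bins.sum()) // 2)


def integral_histogram(masked_rgb: np.ndarray, config: HistogramConfig = HistogramConfig()) -> IntegralHistogram:
    """Build the integral histogram of a masked RGB frame."""
    chroma, value, mask = hsv_bin_indices(masked_rgb, config)
    h, w = mask.shape
    b = config.n_bins
    per_px = np.zeros((h, w, b), dtype=np.int32)
    ys, xs = np.nonzero(mask)
    np.add.at(per_px, (ys, xs, chroma[ys, xs]), 1)
    np.add.at(per_px, (ys, xs, value[ys, xs]), 1)
    table = np.zeros((h + 1, w + 1, b), dtype=np.int32)
    np.cumsum(per_px, axis=0, out=per_px)
    np.cumsum(per_px, axis=1, out=per_px)
    table[1:, 1:] = per_px
    return IntegralHistogram(table=table, config=config)


def bhattacharyya(h_ref, h_hyp) -> float:
    """Bhattacharyya distance D = sqrt(1 - sum_b sqrt(p_b q_b)) in [0, 1].

    Inputs are ``HSVHistogram`` objects or raw vectors; both are normalized
    internally.  Two empty histograms carry no evidence and give D = 1.
    """
    p = h_ref.normalized() if isinstance(h_ref, HSVHistogram) else _norm_vec(h_ref)
    q = h_hyp.normalized() if isinstance(h_hyp, HSVHistogram) else _norm_vec(h_hyp)
    if p.shape != q.shape:
        raise ValueError("histogram bin counts differ")
    if p.sum() == 0 or q.sum() == 0:
        return 1.0
    bc = np.sqrt(p * q).sum()
    return float(np.sqrt(max(0.0, 1.0 - min(bc, 1.0))))


def _norm_vec(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    s = v.sum()
    return v / s if s > 0 else v


@dataclass
class ReferenceAppearance:
    """Per-subwindow reference histograms for one player, from calibration."""

    player_id: int
    histograms: list  # one HSVHistogram per subwindow, top to bottom

    @property
    def n_subwindows(self) -> int:
        return len(self.histograms)


@dataclass
class CueWeights:
    """Cue mixing constants and the color-score scaling.

    ``c`` scales the per-subwindow color score s_k = c*(1 - D_k) to avoid
    vanishing products; the three alphas mix the per-frame max-normalized
    color, foreground-mask and movement cues.
    """

    alpha_color: float = 1.0
    alpha_mask: float = 0.4
    alpha_mov: float = 0.1
    c: float = 100.0
    n_subwindows: int = 4
    score_form: str = "linear"  # "linear": c*(1-D); "exp": c*exp(-lambda*D^2)
    exp_lambda: float = 20.0

    def subwindow_score(self, d: float) -> float:
        if self.score_form == "exp":
            return self.c * float(np.exp(-self.exp_lambda * d * d))
        return self.c * (1.0 - d)


def color_score(distances, cw: CueWeights) -> float:
    """Combine per-subwindow Bhattacharyya distances into one color score.

    The upper NS-1 subwindows are tightly coupled by multiplying their
    scores; the lowest subwindow (legs) is loosely coupled by adding its
    score: prod(s_1..s_{NS-1}) + s_NS.
    """
    distances = list(distances)
    if len(distances) < 2:
        raise ValueError("need at least two subwindows")
    scores = [max(cw.subwindow_score(d), 0.0) for d in distances]
    upper = float(np.prod(scores[:-1]))
    return upper + scores[-1]


def count_score(binary: np.ndarray, subwindows, cw: CueWeights | None = None) -> float:
    """Non-zero pixel count per subwindow, normalized to subwindow width.

    Serves both the foreground-mask cue and the movement cue, depending on
    which binary image is passed.
    """
    total = 0.0
    for rect in subwindows:
        if rect.width <= 0:
            raise ValueError("zero-width subwindow")
        if rect.height <= 0:  # band fully clipped away
            continue
        nzp = np.count_nonzero(binary[rect.y0 : rect.y1, rect.x0 : rect.x1])
        total += nzp / float(rect.width)
    return total


def total_weight(color_n: float, mask_n: float, mov_n: float, cw: CueWeights) -> float:
    """Sum of the per-frame max-normalized cues, alpha-weighted."""
    return cw.alpha_color * color_n + cw.alpha_mask * mask_n + cw.alpha_mov * mov_n
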