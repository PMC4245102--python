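"""Adaptive Gaussian-mixture background model and the two binary cue images.

Each pixel keeps a capped set of weighted Gaussian color modes (16 by
default).  Only every N-th frame is fed to the model (N = 10 by default, so
player motion between ingestions averages out), and every third ingested
input is replaced by the current background image itself — this feedback
keeps the model's memory clean and stops slow-moving players from being
absorbed into the background.  A spike monitor watches the foreground pixel
count: when it exceeds a set fraction of the frame (sudden illumination
change, camera knock) the learning rate is raised until the count settles.

From the model two binary cues are derived per frame:

* the foreground mask — |frame - background|, luminance-converted,
  thresholded and cleaned with a morphological opening; applied to the
  frame it yields the masked color frame (background zero-valued);
* the movement mask — the same binarize/open pipeline on the difference of
  consecutive frames, so only moving objects survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BackgroundConfig",
    "BackgroundState",
    "FrameBundle",
    "update_background",
    "foreground_mask",
    "movement_mask",
    "binary_opening",
    "make_bundle",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class BackgroundConfig:
    n_modes: int = 16
    feed_stride: int = 10          # frames between model inputs (N)
    feedback_period: int = 3       # every k-th ingested input is the background image
    lr_normal: float = 0.01
    lr_high: float = 0.1
    fg_spike_fraction: float = 0.3
    diff_threshold: float = 25.0   # on the 0..255 intensity scale
    opening_radius: int = 1        # square structuring element of side 2r+1
    movement_source: str = "frame_diff"  # or "model_diff"
    match_sigmas: float = 2.5
    var_init: float = 225.0        # sigma = 15 intensity levels
    var_min: float = 16.0

    def __post_init__(self):
        if not (0 < self.lr_normal <= self.lr_high < 1):
            raise ValueError("need 0 < lr_normal <= lr_high < 1")
        if self.n_modes < 1 or self.feed_stride < 1:
            raise ValueError("n_modes and feed_stride must be >= 1")


@dataclass
class BackgroundState:
    """Per-pixel mixture state: mode weights, mean colors, variances."""

    weights: np.ndarray       # (K, H, W)
    means: np.ndarray         # (K, H, W, 3)
    variances: np.ndarray     # (K, H, W)
    frames_seen: int = 0
    ingested: int = 0
    high_rate_active: bool = False
    last_fg_fraction: float = 0.0

    @classmethod
    def blank(cls, frame_shape, config: BackgroundConfig) -> "BackgroundState":
        h, w = frame_shape[:2]
        k = config.n_modes
        return cls(
            weights=np.zeros((k, h, w), dtype=np.float32),
            means=np.zeros((k, h, w, 3), dtype=np.float32),
            variances=np.full((k, h, w), config.var_init, dtype=np.float32),
        )

    @property
    def initialized(self) -> bool:
        return self.ingested > 0

    def background_image(self) -> np.ndarray:
        """Most-probable per-pixel mean, as uint8."""
        best = np.argmax(self.weights, axis=0)  # (H, W)
        h, w = best.shape
        yy, xx = np.mgrid[0:h, 0:w]
        return np.clip(self.means[best, yy, xx], 0, 255).astype(np.uint8)


def _ingest(state: BackgroundState, frame_f: np.ndarray, lr: float, cfg: BackgroundConfig) -> None:
    """One recursive mixture update with learning rate ``lr`` (in place)."""
    d = frame_f[None] - state.means                     # (K, H, W, 3)
    d2 = (d * d).sum(axis=-1)                           # (K, H, W)
    thresh = (cfg.match_sigmas ** 2) * 3.0 * state.variances
    matches = (d2 < thresh) & (state.weights > 0)
    # best matching mode = highest-weight among matches
    w_masked = np.where(matches, state.weights, -1.0)
    best = np.argmax(w_masked, axis=0)                  # (H, W)
    has_match = np.take_along_axis(matches, best[None], axis=0)[0]

    h, w = has_match.shape
    yy, xx = np.mgrid[0:h, 0:w]

    # decay all weights, then boost (or create) the matched mode
    state.weights *= 1.0 - lr
    bm, by, bx = best[has_match], yy[has_match], xx[has_match]
    state.weights[bm, by, bx] += lr
    rho = lr
    state.means[bm, by, bx] += rho * d[bm, by, bx]
    new_var = state.variances[bm, by, bx] + rho * (d2[bm, by, bx] / 3.0 - state.variances[bm, by, bx])
    state.variances[bm, by, bx] = np.maximum(new_var, cfg.var_min)

    # unmatched pixels: replace the weakest mode with a fresh one
    um = ~has_match
    if um.any():
        weakest = np.argmin(state.weights, axis=0)
        wm, wy, wx = weakest[um], yy[um], xx[um]
        state.weights[wm, wy, wx] = lr
        state.means[wm, wy, wx] = frame_f[um]
        state.variances[wm, wy, wx] = cfg.var_init

    total = state.weights.sum(axis=0, keepdims=True)
    np.divide(state.weights, total, out=state.weights, where=total > 0)
    state.ingested += 1


def update_background(state: BackgroundState, frame: np.ndarray, config: BackgroundConfig) -> BackgroundState:
    """Advance the model by one frame (mutates and returns ``state``).

    The frame is ingested only when the running frame counter is a multiple
    of ``feed_stride``; every ``feedback_period``-th ingested input is the
    current background image instead of the frame.  The learning rate is
    ``lr_high`` while the last foreground fraction exceeds
    ``fg_spike_fraction``.
    """
    frame = np.asarray(frame)
    if state.weights.shape[1:3] != frame.shape[:2]:
        raise ValueError("frame shape does not match background state")
    if state.frames_seen % config.feed_stride == 0:
        lr = config.lr_high if state.high_rate_active else config.lr_normal
        feedback = (
            state.ingested > 0 and (state.ingested + 1) % config.feedback_period == 0
        )
        source = state.background_image() if feedback else frame
        _ingest(state, source.astype(np.float32), lr, config)
    state.frames_seen += 1
    return state


def _to_gray(diff: np.ndarray) -> np.ndarray:
    return diff @ _LUMA if diff.ndim == 3 else diff


def binary_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening with a square element of side 2*radius + 1."""
    if radius < 1:
        return mask
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    return ndimage.binary_opening(mask, structure=footprint)


def _diff_mask(a: np.ndarray, b: np.ndarray, cfg: BackgroundConfig) -> np.ndarray:
    diff = np.abs(a.astype(np.float32) - b.astype(np.float32))
    gray = _to_gray(diff)
    return binary_opening(gray > cfg.diff_threshold, cfg.opening_radius)


def foreground_mask(state: BackgroundState, frame: np.ndarray, config: BackgroundConfig):
    """(binary mask, masked color frame) of pixels differing from background.

    Pipeline: absolute difference frame - background -> luminance grayscale
    -> threshold -> opening -> mask applied to the frame.  Updates the
    spike monitor used for the adaptive learning rate.
    """
    if not state.initialized:
        raise RuntimeError("background model not initialized (no ingested frame)")
    frame = np.asarray(frame)
    mask = _diff_mask(frame, state.background_image(), config)
    state.last_fg_fraction = float(mask.mean())
    state.high_rate_active = state.last_fg_fraction > config.fg_spike_fraction
    masked = np.where(mask[..., None], frame, 0).astype(frame.dtype)
    return mask, masked


def movement_mask(
    prev_frame: np.ndarray,
    frame: np.ndarray,
    config: BackgroundConfig,
    state: BackgroundState | None = None,
) -> np.ndarray:
    """Binary mask of pixels changed between consecutive frames.

    With ``movement_source == "model_diff"`` the previous frame is replaced
    by the model's background image (requires ``state``).
    """
    frame = np.asarray(frame)
    if config.movement_source == "model_diff":
        if state is None or not state.initialized:
            raise RuntimeError("model_diff movement source needs an initialized state")
        ref = state.background_image()
    else:
        ref = np.asarray(prev_frame)
    if ref.shape != frame.shape:
        raise ValueError("consecutive frames must have equal shape")
    return _diff_mask(frame, ref, config)


@dataclass
class FrameBundle:
    """One frame with its derived cue images."""

    index: int
    frame: np.ndarray
    fg_mask: np.ndarray
    masked_frame: np.ndarray
    mov_mask: np.ndarray


def make_bundle(
    state: BackgroundState,
    prev_frame: np.ndarray | None,
    frame: np.ndarray,
    index: int,
    config: BackgroundConfig,
) -> FrameBundle:
    """Update the model and derive all cue images for one frame."""
    update_background(state, frame, config)
    fg, masked = foreground_mask(state, frame, config)
    if prev_frame is None:
        mov = np.zeros(frame.shape[:2], dtype=bool)
    else:
        mov = movement_mask(prev_frame, frame, config, state)
    return FrameBundle(index=index, frame=frame, fg_mask=fg, masked_frame=masked, mov_mask=mov)
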