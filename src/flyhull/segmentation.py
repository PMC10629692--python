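"""Motion-based body/wing segmentation of binary silhouette stacks.

The wings sweep past any given pixel briefly while the body occupies it for
the whole wingbeat, so summing the binary frames over one wingbeat window
makes body pixels the most intense.  Segmentation runs in two passes:

1. a sliding-window occupancy sum classifies pixels occupied in at least
   ``occupancy_fraction`` of the window as provisional body, giving a
   provisional 2D body CM per frame;
2. frames are translated by their provisional CM displacement (integer
   pixels) to compensate body motion, the occupancy is re-summed and
   re-thresholded, and the final body mask is shifted back per frame.

Wing pixels are the remaining foreground: ``wing = full & ~body``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as _nd_shift  # noqa: F401  (doc pointer)


@dataclass
class SegmentedFrame:
    """Per-camera, per-frame segmentation masks and 2D body CM."""

    camera_id: int
    frame: int
    full_mask: np.ndarray
    body_mask: np.ndarray
    wing_mask: np.ndarray
    body_cm_2d: np.ndarray  # (x, y) continuous pixel coordinates

    def __post_init__(self) -> None:
        if np.any(self.body_mask & ~self.full_mask):
            raise ValueError("body mask must be a subset of the full mask")
        if np.any(self.body_mask & self.wing_mask):
            raise ValueError("body and wing masks must be disjoint")


def binarize(
    frame: np.ndarray, threshold: float, fly_dark: bool = True
) -> np.ndarray:
    """Threshold a grayscale frame into a binary fly mask.

    With back illumination the fly is dark (``fly_dark=True``): foreground is
    ``intensity < threshold``.  Boolean input is passed through unchanged.
    """
    frame = np.asarray(frame)
    if frame.dtype == bool:
        return frame.copy()
    mask = frame < threshold if fly_dark else frame > threshold
    if not mask.any():
        warnings.warn("binarize produced an empty mask")
    return mask


def mask_centroid(mask: np.ndarray) -> np.ndarray:
    """Continuous (x, y) centroid of a binary mask."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return np.array([np.nan, np.nan])
    return np.array([xs.mean(), ys.mean()])


def _sliding_occupancy(stack: np.ndarray, window: int) -> np.ndarray:
    """Per-frame fraction of the centered window in which each pixel is on.

    Edge frames use a truncated, re-normalized window.  Returned as
    float16 to keep long stacks affordable; the quotient of two small
    integers is represented exactly enough for thresholding.
    """
    t = len(stack)
    cum = np.concatenate(
        [np.zeros((1,) + stack.shape[1:], dtype=np.uint16),
         np.cumsum(stack, axis=0, dtype=np.uint16)]
    )
    half = window // 2
    occ = np.empty(stack.shape, dtype=np.float16)
    for f in range(t):
        lo = max(0, f - half)
        hi = min(t, f + window - half)
        occ[f] = (cum[hi] - cum[lo]).astype(np.float32) / float(hi - lo)
    return occ


def _integer_shift(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift a 2D boolean image by whole pixels, zero-filling the border."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    xs0, xs1 = max(0, dx), min(w, w + dx)
    ys0, ys1 = max(0, dy), min(h, h + dy)
    out[ys0:ys1, xs0:xs1] = mask[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def dominant_period(
    sig: np.ndarray, min_period: int = 8, max_period: int | None = None
) -> int:
    """Dominant period of a (roughly periodic) signal in samples.

    Uses the overlap-normalized autocorrelation and returns the *first*
    prominent peak lag (>= half the zero-lag value) rather than the global
    argmax: for a periodic signal every multiple of the period ties, and
    the fundamental is the smallest.
    """
    sig = np.asarray(sig, float)
    sig = sig - sig.mean()
    if np.allclose(sig, 0):
        raise ValueError("signal is constant; cannot estimate a period")
    n = len(sig)
    ac = np.correlate(sig, sig, mode="full")[n - 1 :]
    ac = ac / (n - np.arange(n))  # unbiased: normalize overlap
    max_period = max_period or n // 2
    if max_period <= min_period:
        raise ValueError("signal too short to estimate the period")
    strong = 0.5 * ac[0]
    for lag in range(min_period, max_period):
        if ac[lag] >= strong and ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1]:
            return lag
    return int(min_period + np.argmax(ac[min_period : max_period + 1]))


def estimate_wingbeat_window(
    stack: np.ndarray, min_period: int = 8, max_period: int | None = None
) -> int:
    """Estimate the wingbeat period (frames) from the foreground-pixel count.

    The per-frame total fly pixel count oscillates with the stroke; its
    dominant period (first prominent autocorrelation peak) is the window.
    """
    counts = np.asarray(stack, bool).sum(axis=(1, 2)).astype(float)
    return dominant_period(counts, min_period, max_period)


def segment_body(
    stack: np.ndarray,
    camera_id: int = 0,
    window: int | str = "auto",
    occupancy_fraction: float = 0.85,
    boundary_regrow: int = 1,
) -> list[SegmentedFrame]:
    """Two-pass motion-based body segmentation of one camera's binary stack.

    Parameters
    ----------
    stack : (T, H, W) bool array
        Binary silhouette frames, T >= window.
    window : int or "auto"
        Wingbeat window length in frames; "auto" estimates it from the
        foreground-pixel-count autocorrelation.
    occupancy_fraction : float
        A pixel is body if it is occupied in at least this fraction of the
        (motion-compensated) window.
    boundary_regrow : int
        Occupancy summing smears the body boundary when the body moves or
        rotates within the window, eroding the mask by a phase-dependent
        pixel or two; regrowing the mask by this many pixels *inside the
        instantaneous full-fly silhouette* (whose edge is exact) removes
        the smear.  0 disables.
    """
    stack = np.asarray(stack, dtype=bool)
    if window == "auto":
        window = estimate_wingbeat_window(stack)
    window = int(window)
    if len(stack) < window:
        raise ValueError(
            f"stack of {len(stack)} frames is shorter than the window "
            f"({window})"
        )

    # pass 1: provisional body from raw occupancy
    occ = _sliding_occupancy(stack, window)
    prov = (occ >= occupancy_fraction) & stack
    cms = np.array(
        [
            mask_centroid(prov[f]) if prov[f].any() else mask_centroid(stack[f])
            for f in range(len(stack))
        ]
    )

    # pass 2: align frames on the provisional CM, re-sum, shift masks back
    ref = np.nanmedian(cms, axis=0)
    disp = np.rint(np.nan_to_num(cms - ref)).astype(int)
    aligned = np.empty_like(stack)
    for f in range(len(stack)):
        aligned[f] = _integer_shift(stack[f], -disp[f, 0], -disp[f, 1])
    occ2 = _sliding_occupancy(aligned, window)
    body_aligned = occ2 >= occupancy_fraction

    frames = []
    for f in range(len(stack)):
        body = _integer_shift(body_aligned[f], disp[f, 0], disp[f, 1]) & stack[f]
        if boundary_regrow > 0 and body.any():
            from scipy.ndimage import binary_dilation

            body = binary_dilation(body, iterations=boundary_regrow) & stack[f]
        if not body.any():
            warnings.warn(f"camera {camera_id}, frame {f}: empty body mask")
            cm = mask_centroid(stack[f])
        else:
            cm = mask_centroid(body)
        frames.append(
            SegmentedFrame(
                camera_id=camera_id,
                frame=f,
                full_mask=stack[f],
                body_mask=body,
                wing_mask=stack[f] & ~body,
                body_cm_2d=cm,
            )
        )
    return frames
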