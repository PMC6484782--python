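"""Segmentation and fluorescence quantification.

Mirrors the wet-lab image-processing chain: the phase-contrast channel is
contrast-stretched, Gaussian low-pass filtered and fed to a circular Hough
transform; detected circles are painted into a labeled mask; per-cell mean
fluorescence is background-subtracted using a rectangle outside the
chamber; and per-cell GFP is normalized either by the calibration-phase
mCherry (control experiments) or by the calibration-phase GFP itself
(clearance experiments, so traces start near 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from skimage import draw, feature, filters, transform

__all__ = ["FrameStack", "SegmentationResult", "detect_cells", "quantify",
           "normalize", "write_frames", "read_frames"]


@dataclass
class FrameStack:
    """One time point: phase-contrast, GFP and RFP images plus the
    background rectangle ``(x0, y0, x1, y1)`` (px, top-left origin,
    half-open)."""

    phase: np.ndarray
    gfp: np.ndarray
    rfp: np.ndarray
    time: float = 0.0
    background_region: tuple[int, int, int, int] = (0, 0, 24, 24)

    def __post_init__(self) -> None:
        if not (self.phase.shape == self.gfp.shape == self.rfp.shape):
            raise ValueError("all channels must share one shape")
        x0, y0, x1, y1 = self.background_region
        h, w = self.phase.shape
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError("background_region outside image bounds")

    def background_mean(self, channel: str) -> float:
        x0, y0, x1, y1 = self.background_region
        return float(getattr(self, channel)[y0:y1, x0:x1].mean())


@dataclass
class SegmentationResult:
    centroids: list[tuple[float, float]]   # (x, y) px
    radii: list[float]
    mask: np.ndarray                       # 0 background, i for cell i

    def __post_init__(self) -> None:
        if len(self.centroids) != len(self.radii):
            raise ValueError("centroids and radii must have equal length")

    def __len__(self) -> int:
        return len(self.centroids)


def detect_cells(phase: np.ndarray, radius_range: tuple[int, int] = (4, 15),
                 sensitivity: float = 0.5, sigma: float = 1.0,
                 max_cells: int = 200) -> SegmentationResult:
    """Find cells in a phase-contrast image via the circular Hough transform.

    The image is Gaussian low-pass filtered, contrast-enhanced by a linear
    stretch of its 1st-99th percentiles, edge-detected, and the edge map
    scanned for circles over ``radius_range``.  ``sensitivity`` is the
    minimum normalized accumulator value — the fraction of a circle's
    perimeter supported by edge pixels — below which a peak is discarded;
    of two detections closer than ``0.8 * (r1 + r2)`` only the stronger is
    kept.  An image whose percentile range does not rise above its noise
    floor carries no structure and yields zero detections.  The labeled
    mask paints filled disks; later detections do not overwrite earlier
    labels.
    """
    rmin, rmax = radius_range
    if rmin < 2:
        raise ValueError("minimum Hough radius must be >= 2 px")
    img = filters.gaussian(phase.astype(float), sigma=sigma)
    lo, hi = np.percentile(img, [1.0, 99.0])
    noise_scale = 1.4826 * float(np.median(np.abs(img - np.median(img))))
    empty = SegmentationResult([], [], np.zeros(phase.shape, dtype=np.int32))
    if hi - lo <= 8.0 * noise_scale:
        # sparse scene: cells cover < 1% of pixels, so the percentile
        # stretch sees only background — stretch to the full range instead
        hi = float(img.max())
        if hi - lo <= 8.0 * noise_scale:
            return empty   # contrast within the noise floor: blank scene
    img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    edges = feature.canny(img, sigma=1.0, low_threshold=0.2, high_threshold=0.4)
    radii = np.arange(rmin, rmax + 1)
    accum = transform.hough_circle(edges, radii)
    if accum.max() < sensitivity:
        return empty
    strengths, cxs, cys, rs = transform.hough_circle_peaks(
        accum, radii, threshold=sensitivity,
        min_xdistance=rmin, min_ydistance=rmin,
        total_num_peaks=max_cells)
    # greedy suppression of overlapping circles, strongest first
    order = np.argsort(strengths)[::-1]
    keep: list[int] = []
    for i in order:
        ok = True
        for j in keep:
            dist = float(np.hypot(cxs[i] - cxs[j], cys[i] - cys[j]))
            if dist < 0.8 * (rs[i] + rs[j]):
                ok = False
                break
        if ok:
            keep.append(int(i))
    keep.sort(key=lambda i: float(strengths[i]), reverse=True)

    mask = np.zeros(phase.shape, dtype=np.int32)
    centroids, radii_out = [], []
    for label, i in enumerate(keep, start=1):
        rr, cc = draw.disk((float(cys[i]), float(cxs[i])), float(rs[i]),
                           shape=phase.shape)
        free = mask[rr, cc] == 0
        mask[rr[free], cc[free]] = label
        centroids.append((float(cxs[i]), float(cys[i])))
        radii_out.append(float(rs[i]))
    return SegmentationResult(centroids, radii_out, mask)


def quantify(frame: FrameStack, seg: SegmentationResult,
             ) -> list[tuple[float, float]]:
    """Background-subtracted mean (GFP, RFP) per segmented cell.

    Values may be slightly negative after background subtraction; they are
    kept, not clipped.
    """
    if seg.mask.shape != frame.gfp.shape:
        raise ValueError("segmentation mask does not match frame shape")
    n = len(seg)
    if n == 0:
        return []
    labels = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(seg.mask), seg.mask, labels)
    if np.any(counts == 0):
        raise ValueError("segmented cell with zero mask pixels")
    bg_g = frame.background_mean("gfp")
    bg_r = frame.background_mean("rfp")
    g = ndimage.mean(frame.gfp, seg.mask, labels) - bg_g
    r = ndimage.mean(frame.rfp, seg.mask, labels) - bg_r
    return [(float(gi), float(ri)) for gi, ri in zip(g, r)]


def normalize(gfp_series, calibration, mode: str = "control") -> np.ndarray:
    """Normalize a per-cell GFP series by its calibration-phase signal.

    ``mode="control"``: divide by the mean mCherry over the calibration
    window.  ``mode="clearance"``: divide by the mean GFP over the (5 min)
    calibration window so the trace starts near 1.
    """
    if mode not in ("control", "clearance"):
        raise ValueError("mode must be 'control' or 'clearance'")
    calib = float(np.mean(np.asarray(calibration, dtype=float)))
    if not calib > 0:
        raise ValueError("calibration mean must be positive")
    return np.asarray(gfp_series, dtype=float) / calib


# -- TIFF round trip --------------------------------------------------------

_TIFF_SCALE = 10.0  # a.u. -> uint16 counts


def write_frames(frames: list[FrameStack], path_prefix) -> dict[str, str]:
    """Write one multi-page 16-bit TIFF per channel (<prefix>_<chan>.tif)."""
    out = {}
    for chan in ("phase", "gfp", "rfp"):
        stack = np.stack([getattr(f, chan) for f in frames])
        data = np.clip(stack * _TIFF_SCALE, 0, 65535).astype(np.uint16)
        path = f"{path_prefix}_{chan}.tif"
        tifffile.imwrite(path, data)
        out[chan] = path
    return out


def read_frames(path_prefix, times=None,
                background_region=(0, 0, 24, 24)) -> list[FrameStack]:
    chans = {c: tifffile.imread(f"{path_prefix}_{c}.tif").astype(float) / _TIFF_SCALE
             for c in ("phase", "gfp", "rfp")}
    n = chans["phase"].shape[0]
    if times is None:
        times = [5.0 * i for i in range(n)]
    return [FrameStack(chans["phase"][i], chans["gfp"][i], chans["rfp"][i],
                       time=times[i], background_region=background_region)
            for i in range(n)]
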