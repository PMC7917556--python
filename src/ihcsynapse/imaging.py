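"""ROI detection on fluorescence movie stacks.

The segmentation recipe: build a dF image (mean of five response frames
minus mean of 15 baseline frames), median- or Gaussian-filter it, threshold
with the maximum-entropy (Kapur) criterion, split touching regions with a
marker-controlled watershed on the distance transform, and keep regions
above a minimum area.  One mask per cell is built from the strongest
stimulation and reused for every sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import DegenerateImageError, WindowError, SegmentationError


@dataclass
class DeltaFImage:
    """A response-minus-baseline image with the windows that produced it."""

    pixels: np.ndarray
    baseline_frames: tuple[int, int]
    response_frames: tuple[int, int]


@dataclass
class ROI:
    id: int
    pixel_mask: np.ndarray       # boolean, full frame
    centroid_xy: tuple[float, float]
    area_px: int
    best_plane: int | None = None


@dataclass
class ROISet:
    label_image: np.ndarray      # int, 0 = background
    rois: list[ROI]
    background_rect: tuple[int, int, int, int] | None = None  # r0, c0, h, w

    def __len__(self):
        return len(self.rois)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"roi_id": r.id, "x_px": r.centroid_xy[0], "y_px": r.centroid_xy[1],
              "area_px": r.area_px, "best_plane": r.best_plane}
             for r in self.rois])


def delta_f_image(movie: np.ndarray, baseline_frames: tuple[int, int],
                  response_frames: tuple[int, int]) -> DeltaFImage:
    """Pixelwise mean(response window) − mean(baseline window).

    Windows are half-open ``[start, stop)`` frame-index ranges and must be
    non-empty, inside the movie and non-overlapping.
    """
    n = movie.shape[0]
    for w in (baseline_frames, response_frames):
        if w[1] - w[0] < 1:
            raise WindowError(f"window {w} shorter than one frame")
        if w[0] < 0 or w[1] > n:
            raise WindowError(f"window {w} outside movie of {n} frames")
    if not (baseline_frames[1] <= response_frames[0]
            or response_frames[1] <= baseline_frames[0]):
        raise WindowError("baseline and response windows overlap")
    f0 = movie[baseline_frames[0]:baseline_frames[1]].mean(axis=0)
    f = movie[response_frames[0]:response_frames[1]].mean(axis=0)
    return DeltaFImage(pixels=f - f0, baseline_frames=tuple(baseline_frames),
                       response_frames=tuple(response_frames))


def max_entropy_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Maximum-entropy (Kapur) threshold of a gray-level image.

    The image is histogrammed into ``n_bins`` equal-width bins over its
    range; the returned threshold is the gray value whose split maximizes
    the sum of the Shannon entropies of the background and foreground
    histogram halves.  Pixels strictly above the threshold are foreground.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise DegenerateImageError("constant image has no threshold")
    hist, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    p = hist.astype(float) / hist.sum()
    c = np.cumsum(p)

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]

    best_h, best_t = -np.inf, 0
    for t in range(n_bins - 1):
        w0, w1 = c[t], 1.0 - c[t]
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = np.log(w0) - cum_plogp[t] / w0
        h1 = np.log(w1) - (total_plogp - cum_plogp[t]) / w1
        if h0 + h1 > best_h:
            best_h, best_t = h0 + h1, t
    # threshold at the upper edge of the chosen bin
    return float(edges[best_t + 1])


def detect_rois(dF: DeltaFImage | np.ndarray, filter_kind: str = "median",
                size_or_sigma: float = 5, min_area_px: int = 20,
                marker_min_distance: int = 3) -> ROISet:
    """Segment dF hot spots into labeled ROIs.

    filter (median size 4–6 or Gaussian sigma 1–3) → Kapur threshold →
    binary mask → watershed on the distance transform with local-maximum
    markers (minimum separation ``marker_min_distance`` px) → drop regions
    below ``min_area_px``.  A blank image yields an empty ROISet.
    """
    img = dF.pixels if isinstance(dF, DeltaFImage) else np.asarray(dF, float)
    if filter_kind == "median":
        size = int(size_or_sigma)
        if not 3 <= size <= 9:
            raise ValueError("median filter size expected in [3, 9]")
        filt = ndimage.median_filter(img, size=size)
    elif filter_kind == "gaussian":
        if not 0.5 <= size_or_sigma <= 5:
            raise ValueError("gaussian sigma expected in [0.5, 5]")
        filt = ndimage.gaussian_filter(img, sigma=size_or_sigma)
    else:
        raise ValueError(f"unknown filter kind {filter_kind!r}")

    try:
        thr = max_entropy_threshold(filt)
    except DegenerateImageError:
        return ROISet(label_image=np.zeros(img.shape, dtype=np.int32), rois=[])
    mask = filt > thr
    if not mask.any():
        return ROISet(label_image=np.zeros(img.shape, dtype=np.int32), rois=[])

    # markers: local maxima of the filtered intensity inside the mask.
    # (The distance transform of two touching spots is unimodal — their
    # union is convex — so intensity peaks are the only reliable seeds for
    # splitting overlapping boutons.)
    peaks = peak_local_max(filt, min_distance=marker_min_distance,
                           labels=mask, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(mask)
    labels = watershed(-filt, markers=markers, mask=mask)

    rois, label_image = [], np.zeros(img.shape, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        m = labels == prop.label
        label_image[m] = next_id
        cy, cx = prop.centroid
        rois.append(ROI(id=next_id, pixel_mask=m, centroid_xy=(cx, cy),
                        area_px=int(prop.area)))
        next_id += 1
    return ROISet(label_image=label_image, rois=rois)


def background_region(frame_shape: tuple[int, int], rois: ROISet | None = None,
                      pillar_side: str = "left",
                      size: int = 60) -> tuple[int, int, int, int]:
    """A ``size`` x ``size`` background rectangle at the pillar-side edge.

    Starts centered on the pillar edge and slides along that edge until it
    overlaps no ROI.  Returns (row0, col0, height, width).

    Raises
    ------
    SegmentationError
        Frame smaller than the region, or no ROI-free placement exists.
    WindowError is not used here; frame-size problems are segmentation-level.
    """
    rows, cols = frame_shape
    if rows < size or cols < size:
        raise SegmentationError(f"frame {frame_shape} smaller than "
                                f"{size}x{size} background region")
    label = (rois.label_image if rois is not None
             else np.zeros(frame_shape, dtype=np.int32))

    if pillar_side in ("left", "right"):
        c0 = 0 if pillar_side == "left" else cols - size
        starts = [rows // 2 - size // 2]
        starts += [s for k in range(1, rows) for s in
                   (starts[0] - k, starts[0] + k)]
        for r0 in starts:
            if 0 <= r0 <= rows - size and not label[r0:r0 + size,
                                                    c0:c0 + size].any():
                return (r0, c0, size, size)
    elif pillar_side in ("top", "bottom"):
        r0 = 0 if pillar_side == "top" else rows - size
        starts = [cols // 2 - size // 2]
        starts += [s for k in range(1, cols) for s in
                   (starts[0] - k, starts[0] + k)]
        for c0 in starts:
            if 0 <= c0 <= cols - size and not label[r0:r0 + size,
                                                    c0:c0 + size].any():
                return (r0, c0, size, size)
    else:
        raise ValueError(f"unknown pillar side {pillar_side!r}")
    raise SegmentationError("no ROI-free background placement on the "
                            f"{pillar_side} edge")


def background_trace(movie: np.ndarray,
                     rect: tuple[int, int, int, int]) -> np.ndarray:
    """Per-frame mean over the background rectangle."""
    r0, c0, h, w = rect
    return movie[:, r0:r0 + h, c0:c0 + w].mean(axis=(1, 2))


def best_plane(plane_dF: np.ndarray, roi: ROI,
               n_planes: int | None = None) -> int:
    """Plane with the maximum ROI-mean dF; ties go to the central plane.

    ``plane_dF`` is an array of per-plane dF images, shape
    (n_planes, rows, cols).
    """
    plane_dF = np.asarray(plane_dF, dtype=float)
    n = plane_dF.shape[0] if n_planes is None else n_planes
    means = np.array([plane_dF[p][roi.pixel_mask].mean() for p in range(n)])
    center = (n - 1) / 2.0
    best = np.flatnonzero(np.isclose(means, means.max(), rtol=0, atol=1e-12))
    # among exact ties, prefer the plane closest to the stack center
    return int(best[np.argmin(np.abs(best - center))])
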