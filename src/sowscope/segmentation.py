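"""Binary body masks from depth frames, overlap scoring, keypoint probes.

The original system segments the side view with a trained neural network;
its annotated barn imagery is not available, so this module defines the
mask contract (:class:`BodyMask`) behind which any external segmenter's
output can be dropped in, and ships a classical depth-threshold baseline
that is exact on synthetic scenes: foreground = valid pixels closer than
``background_depth − margin``, followed by morphological opening/closing
(radius-1 disk), hole filling, and keeping the largest connected
component.

Keypoint extraction turns a clean mask into the measurement probes that
the original workflow obtained from operator clicks: top view — a length
probe along the silhouette's principal axis and a width probe
perpendicular to it; side view — a height probe from the withers (the
topmost silhouette point) down to the ground line and a chest-depth probe
at the column of maximal vertical extent. Mask-derived probe endpoints
sit on pixel boundaries (±0.5 px beyond the extreme pixel centres) so the
endpoint distance estimates the true extent without half-pixel
truncation at each end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .depth_io import DepthFrame, LineProbe, to_meters


class SegmentationError(ValueError):
    """Raised on empty/degenerate masks or incompatible shapes."""


@dataclass(frozen=True)
class BodyMask:
    """A binary body mask aligned to its source frame."""

    mask: np.ndarray
    backend: str = "threshold_depth"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def segment_side(
    frame: DepthFrame, background_depth: float, margin: float = 0.05
) -> BodyMask:
    """Depth-threshold baseline segmentation.

    Foreground is every valid pixel with metric depth below
    ``background_depth − margin``; cleanup is opening then closing with a
    radius-1 disk, filling of enclosed holes (sensor dropouts inside the
    body), and retention of the largest connected component, so the
    result has exactly one foreground component.

    Works unchanged on top-view frames with the ground plane depth as
    ``background_depth``; the name follows the system workflow, where
    segmentation is a side-view stage.

    Raises
    ------
    SegmentationError
        If no foreground survives ("no animal detected").
    """
    if not (background_depth > margin > 0):
        raise SegmentationError(
            f"require background_depth > margin > 0, got {background_depth}, {margin}"
        )
    z = to_meters(frame)
    fg = np.nan_to_num(z, nan=np.inf) < (background_depth - margin)
    selem = morphology.disk(1)
    fg = morphology.opening(fg, selem)
    fg = morphology.closing(fg, selem)
    fg = ndimage.binary_fill_holes(fg)
    labels, nlab = ndimage.label(fg)
    if nlab == 0:
        raise SegmentationError("no animal detected (empty foreground)")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    keep = 1 + int(np.argmax(sizes))
    return BodyMask(mask=labels == keep, backend="threshold_depth")


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BodyMask):
        return mask.mask
    return np.asarray(mask).astype(bool)


def mask_overlap(pred, truth) -> tuple[float, float]:
    """Intersection-over-Union and Dice similarity of two masks.

    Both lie in [0, 1]; two empty masks score 1 by convention.
    """
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise SegmentationError(f"mask shapes differ: {p.shape} vs {t.shape}")
    inter = float(np.logical_and(p, t).sum())
    union = float(np.logical_or(p, t).sum())
    total = float(p.sum() + t.sum())
    if union == 0:
        return 1.0, 1.0
    return inter / union, 2.0 * inter / total


def _boundary_probe(center: np.ndarray, direction: np.ndarray, tmin: float, tmax: float, label: str) -> LineProbe:
    p0 = center + direction * (tmin - 0.5)
    p1 = center + direction * (tmax + 0.5)
    return LineProbe(p0=tuple(p0), p1=tuple(p1), label=label)


def extract_keypoints(
    mask, view: str, ground_row: float | None = None
) -> list[LineProbe]:
    """Derive measurement probes from a body mask.

    Top view: the length probe spans the extreme silhouette points along
    the principal axis (second-moment eigenvector), the width probe the
    extreme extent perpendicular to it; both pass through the centroid.
    Side view: the height probe runs from the withers — the topmost mask
    pixel, smallest column on ties — down to ``ground_row`` (which may be
    fractional); the chest-depth probe spans the maximal vertical extent;
    a side length probe over the horizontal extent is also returned.

    Raises
    ------
    SegmentationError
        For empty or single-pixel masks, or a missing ``ground_row`` in
        the side view.
    """
    m = _as_bool(mask)
    coords = np.argwhere(m).astype(np.float64)
    if coords.shape[0] < 2:
        raise SegmentationError("mask is empty or degenerate (needs >= 2 pixels)")

    if view == "top":
        center = coords.mean(axis=0)
        centred = coords - center
        cov = centred.T @ centred / coords.shape[0]
        eigvals, eigvecs = np.linalg.eigh(cov)
        major = eigvecs[:, np.argmax(eigvals)]
        minor = eigvecs[:, np.argmin(eigvals)]
        # Subpixel silhouette boundary (0.5-level contour of the padded mask):
        # median-unbiased against the ±0.5 px quantization of pixel centres.
        contours = measure.find_contours(np.pad(m, 1).astype(float), 0.5)
        boundary = np.vstack(contours) - 1.0 - center
        t_major = boundary @ major
        t_minor = boundary @ minor
        length_probe = LineProbe(
            p0=tuple(center + major * t_major.min()),
            p1=tuple(center + major * t_major.max()),
            label="length",
        )
        # Width = longest chord perpendicular to the principal axis: slab-wise
        # minor extent, so both chord endpoints share the same axial position
        # (a global min/max of minor projections overstates skewed silhouettes).
        span = t_major.max() - t_major.min()
        nbins = max(8, int(span / 2))
        edges = np.linspace(t_major.min(), t_major.max(), nbins + 1)
        idx = np.clip(np.digitize(t_major, edges) - 1, 0, nbins - 1)
        best = (0.0, 0.0, 0.0, 0.0)  # (chord, axial pos, tmin, tmax)
        for k in range(nbins):
            sel = idx == k
            if sel.sum() < 2:
                continue
            lo, hi = t_minor[sel].min(), t_minor[sel].max()
            if hi - lo > best[0]:
                best = (hi - lo, float(t_major[sel].mean()), lo, hi)
        if best[0] <= 0:
            raise SegmentationError("mask has no measurable perpendicular chord")
        width_probe = LineProbe(
            p0=tuple(center + major * best[1] + minor * best[2]),
            p1=tuple(center + major * best[1] + minor * best[3]),
            label="width",
        )
        return [length_probe, width_probe]

    if view == "side":
        if ground_row is None:
            raise SegmentationError("side-view keypoints require ground_row")
        rows = coords[:, 0].astype(int)
        cols = coords[:, 1].astype(int)
        top_row = rows.min()
        withers_col = cols[rows == top_row].min()  # tie -> smallest column
        height_probe = LineProbe(
            p0=(top_row - 0.5, float(withers_col)),
            p1=(float(ground_row), float(withers_col)),
            label="height",
        )
        # Column of maximal vertical extent for chest depth.
        best_col, best_extent, best_span = None, -1, None
        for col in np.unique(cols):
            rr = rows[cols == col]
            extent = rr.max() - rr.min() + 1
            if extent > best_extent:
                best_col, best_extent, best_span = col, extent, (rr.min(), rr.max())
        chest_probe = LineProbe(
            p0=(best_span[0] - 0.5, float(best_col)),
            p1=(best_span[1] + 0.5, float(best_col)),
            label="chest_depth",
        )
        mid_row = float(coords[:, 0].mean())
        length_probe = LineProbe(
            p0=(mid_row, cols.min() - 0.5),
            p1=(mid_row, cols.max() + 0.5),
            label="length",
        )
        return [height_probe, chest_probe, length_probe]

    raise SegmentationError(f"view must be 'top' or 'side', got {view!r}")


def write_mask(mask, path) -> None:
    """Write a mask as 8-bit PNG (0/255)."""
    import imageio.v3 as iio

    iio.imwrite(path, _as_bool(mask).astype(np.uint8) * 255)


def read_mask(path) -> BodyMask:
    """Read an 8-bit mask PNG (any nonzero pixel is foreground)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BodyMask(mask=arr > 0, backend="external")
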