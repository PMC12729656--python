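"""Depth-frame I/O, metric conversion, pseudo-color rendering and line probes.

A depth frame is a 2-D grid of raw 16-bit counts, one count = 1 mm
(``unit_scale`` = 0.001 m per count). A count of zero marks an invalid
pixel — a sensor hole — and never enters any average. Frames are stored
on disk as single-channel 16-bit grayscale PNG.

A :class:`LineProbe` is a labelled segment in pixel coordinates
(row, col, origin top-left). Probes stand in for the operator's
interactive endpoint clicks: the mean (or median) metric depth along the
rasterized segment supplies the ``z`` of the pinhole back-projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps
from skimage.draw import line as _bresenham

#: Depth unit scale: metres per raw count (1 count = 1 mm).
UNIT_SCALE = 0.001


class DepthFormatError(ValueError):
    """Raised when an image on disk is not a single-channel 16-bit frame."""


class NoDepthSupportError(ValueError):
    """Raised when a probe crosses no valid (non-zero) depth pixel."""


@dataclass(frozen=True)
class DepthFrame:
    """Raw 16-bit depth counts with unit semantics.

    Parameters
    ----------
    counts :
        2-D ``uint16`` array of raw depth counts. Zero marks an invalid pixel.
    unit_scale :
        Metres per count; 0.001 for millimetre counts.
    """

    counts: np.ndarray
    unit_scale: float = UNIT_SCALE

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise DepthFormatError(
                f"depth frame must be 2-D, got shape {counts.shape}"
            )
        if counts.dtype != np.uint16:
            if np.issubdtype(counts.dtype, np.integer) and counts.min() >= 0 and counts.max() <= 0xFFFF:
                counts = counts.astype(np.uint16)
            else:
                raise DepthFormatError(
                    f"depth counts must be uint16-compatible, got dtype {counts.dtype}"
                )
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of valid (non-hole) pixels."""
        return self.counts > 0

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean())


@dataclass(frozen=True)
class LineProbe:
    """A labelled measurement segment in (row, col) pixel coordinates.

    Endpoints may be fractional: mask-derived probes place endpoints on
    pixel *boundaries* (half-integer coordinates) so that the Euclidean
    endpoint distance equals the silhouette extent without the half-pixel
    truncation on each side.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    label: str = "reference"

    def __post_init__(self) -> None:
        p0 = (float(self.p0[0]), float(self.p0[1]))
        p1 = (float(self.p1[0]), float(self.p1[1]))
        if p0 == p1:
            raise ValueError(f"probe '{self.label}': endpoints coincide at {p0}")
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "p1", p1)

    @property
    def pixel_length(self) -> float:
        """Euclidean endpoint distance in pixels."""
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def to_dict(self) -> dict:
        return {"label": self.label, "p0": list(self.p0), "p1": list(self.p1)}

    @classmethod
    def from_dict(cls, d: dict) -> "LineProbe":
        return cls(p0=tuple(d["p0"]), p1=tuple(d["p1"]), label=d.get("label", "reference"))


def read_depth(path: str | Path) -> DepthFrame:
    """Read a 16-bit single-channel PNG as a depth frame.

    Raises
    ------
    DepthFormatError
        If the image is not single-channel 16-bit.
    """
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise DepthFormatError(
            f"{path}: expected single-channel depth image, got shape {arr.shape}"
        )
    if arr.dtype != np.uint16:
        raise DepthFormatError(
            f"{path}: expected 16-bit depth image, got dtype {arr.dtype}"
        )
    return DepthFrame(counts=arr)


def write_depth(frame: DepthFrame, path: str | Path) -> Path:
    """Write a depth frame as 16-bit grayscale PNG (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, frame.counts)
    return path


def to_meters(frame: DepthFrame) -> np.ndarray:
    """Convert raw counts to metric depth: depth_m = counts * unit_scale.

    Invalid (zero-count) pixels propagate as NaN, not as 0.0 m.
    """
    z = frame.counts.astype(np.float64) * frame.unit_scale
    z[~frame.valid] = np.nan
    return z


def pseudocolor(frame: DepthFrame, cmap: str = "jet") -> np.ndarray:
    """Render a contrast-stretched Jet pseudo-color image (uint8 RGB).

    The valid-depth range is stretched to the full colormap; invalid
    pixels render black. An all-invalid frame renders all black; a
    constant-depth frame renders a single uniform color.
    """
    counts = frame.counts.astype(np.float64)
    valid = frame.valid
    out = np.zeros(frame.shape + (3,), dtype=np.uint8)
    if not valid.any():
        return out
    lo, hi = counts[valid].min(), counts[valid].max()
    norm = np.zeros_like(counts) if hi == lo else (counts - lo) / (hi - lo)
    rgba = colormaps[cmap](np.clip(norm, 0.0, 1.0))
    out[valid] = (rgba[valid, :3] * 255).round().astype(np.uint8)
    return out


def rasterize_probe(probe: LineProbe, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Bresenham rasterization of a probe, both endpoints included.

    Fractional endpoints are rounded to the nearest pixel and clipped to
    the frame. Returns (rows, cols) index arrays.
    """
    r0, c0 = (int(round(v)) for v in probe.p0)
    r1, c1 = (int(round(v)) for v in probe.p1)
    nr, nc = shape
    r0, r1 = np.clip([r0, r1], 0, nr - 1)
    c0, c1 = np.clip([c0, c1], 0, nc - 1)
    return _bresenham(r0, c0, r1, c1)


def depth_along_probe(
    frame: DepthFrame, probe: LineProbe, stat: str = "mean"
) -> tuple[float, float]:
    """Average metric depth over a probe segment, holes excluded.

    Parameters
    ----------
    stat :
        ``"mean"`` (default, the minimal faithful reading of "average
        depth of the region") or ``"median"`` for robustness.

    Returns
    -------
    (z, valid_fraction) :
        Mean/median depth in metres over valid segment pixels, and the
        fraction of segment pixels that were valid.

    Raises
    ------
    NoDepthSupportError
        If no valid pixel lies on the segment.
    """
    rr, cc = rasterize_probe(probe, frame.shape)
    vals = frame.counts[rr, cc].astype(np.float64)
    ok = vals > 0
    if not ok.any():
        raise NoDepthSupportError(
            f"probe '{probe.label}': no valid depth pixel on segment"
        )
    reducer = {"mean": np.mean, "median": np.median}[stat]
    z = float(reducer(vals[ok]) * frame.unit_scale)
    return z, float(ok.mean())


def depth_quantile_along_probe(
    frame: DepthFrame, probe: LineProbe, q: float = 0.02
) -> float:
    """Low-quantile metric depth along a probe (robust near-surface depth).

    Used to locate the nearest body surface (e.g. the spine apex in the
    top view) without letting a few noisy counts dominate the minimum.
    """
    rr, cc = rasterize_probe(probe, frame.shape)
    vals = frame.counts[rr, cc].astype(np.float64)
    ok = vals > 0
    if not ok.any():
        raise NoDepthSupportError(
            f"probe '{probe.label}': no valid depth pixel on segment"
        )
    return float(np.quantile(vals[ok], q) * frame.unit_scale)


def probes_to_json(probes: Sequence[LineProbe], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([p.to_dict() for p in probes], indent=2))
    return path


def probes_from_json(path: str | Path) -> list[LineProbe]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [LineProbe.from_dict(d) for d in data]
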