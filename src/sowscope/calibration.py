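"""Pinhole and scale calibration, with their inverse measurement formulas.

Two calibration routes, one per view:

* Top view (pinhole): a reference segment of known physical length
  ``D_real`` (cm) spanning ``p_pixel`` pixels at mean depth ``z`` (m)
  yields the effective focal length ``f = p_pixel * z / (D_real / 100)``
  in pixels. The inverse converts any pixel span back to centimetres:
  ``D_real = p_pixel * z / f * 100``.

* Side view (similar triangles at a fixed plane): a reference of known
  length at the animal's sagittal plane yields a scale factor
  ``k = L_real / L_pixel`` in cm per pixel; physical length is then
  ``L_pixel * k``. The scale is only valid for fronto-parallel segments
  at the calibration distance; off-plane deviation is a documented error
  source, not corrected here.

Units are fixed throughout the package: depth in metres, body dimensions
in centimetres, with the m→cm conversion confined to these two formulas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


class CalibrationError(ValueError):
    """Raised on non-positive or otherwise unusable calibration inputs."""


@dataclass(frozen=True)
class CameraCalibration:
    """Top-view pinhole calibration: effective focal length in pixels."""

    focal_length: float
    view: str = "top"

    def __post_init__(self) -> None:
        if not self.focal_length > 0:
            raise CalibrationError(f"focal_length must be > 0, got {self.focal_length}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"view": self.view, "focal_length_px": self.focal_length}))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraCalibration":
        d = json.loads(Path(path).read_text())
        return cls(focal_length=d["focal_length_px"], view=d.get("view", "top"))


@dataclass(frozen=True)
class ScaleCalibration:
    """Side-view scale calibration: centimetres per pixel at the reference plane."""

    scale_factor: float
    reference_length: float | None = None
    reference_pixels: float | None = None
    view: str = "side"

    def __post_init__(self) -> None:
        if not self.scale_factor > 0:
            raise CalibrationError(f"scale_factor must be > 0, got {self.scale_factor}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"view": self.view, "scale_cm_per_px": self.scale_factor}))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaleCalibration":
        d = json.loads(Path(path).read_text())
        return cls(scale_factor=d["scale_cm_per_px"], view=d.get("view", "side"))


def calibrate_focal(p_pixel: float, z: float, d_real_cm: float) -> CameraCalibration:
    """Effective focal length from a reference segment: f = p·z/(D/100).

    Parameters
    ----------
    p_pixel : pixel span of the reference segment (> 0).
    z : mean depth of the segment in metres (> 0).
    d_real_cm : known physical length in centimetres (> 0).
    """
    for name, v in (("p_pixel", p_pixel), ("z", z), ("d_real_cm", d_real_cm)):
        if not v > 0:
            raise CalibrationError(f"calibrate_focal: {name} must be > 0, got {v}")
    return CameraCalibration(focal_length=p_pixel * z / (d_real_cm / 100.0))


def pixel_to_cm_top(p_pixel: float, z: float, cal: CameraCalibration) -> float:
    """Pinhole back-projection: D_real(cm) = p_pixel · z / f · 100."""
    if p_pixel < 0:
        raise CalibrationError(f"pixel_to_cm_top: p_pixel must be >= 0, got {p_pixel}")
    if not z > 0:
        raise CalibrationError(f"pixel_to_cm_top: z must be > 0, got {z}")
    return p_pixel * z / cal.focal_length * 100.0


def calibrate_scale(l_real_cm: float, l_pixel: float) -> ScaleCalibration:
    """Side-view scale factor: k = L_real / L_pixel (cm per pixel)."""
    for name, v in (("l_real_cm", l_real_cm), ("l_pixel", l_pixel)):
        if not v > 0:
            raise CalibrationError(f"calibrate_scale: {name} must be > 0, got {v}")
    return ScaleCalibration(
        scale_factor=l_real_cm / l_pixel,
        reference_length=l_real_cm,
        reference_pixels=l_pixel,
    )


def pixel_to_cm_side(l_pixel: float, cal: ScaleCalibration) -> float:
    """Side-view physical length: L(cm) = L_pixel · k."""
    if l_pixel < 0:
        raise CalibrationError(f"pixel_to_cm_side: l_pixel must be >= 0, got {l_pixel}")
    return l_pixel * cal.scale_factor
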