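"""Body-dimension measurement and chest-girth estimation.

Dimensions (all cm): body length L and width W from the top view via the
pinhole model, body height H and chest depth D from the side view via a
scale factor. Chest girth C is estimated from the cross-section ellipse
with semi-axes a = W/2 (major) and b = D/2 (minor) under four perimeter
models:

* ``ramanujan`` — C = π[3(a+b) − √((3a+b)(a+3b))], the default;
* ``simple_ellipse`` — C = π(a+b);
* ``stadium`` — a rectangle capped by two semicircles of diameter D:
  C = πD + 2(W−D), requiring W ≥ D;
* ``pig_empirical`` — an affine model C = c₀ + c₁(W+D) with configurable
  coefficients (defaults are a least-squares fit of exact perimeters over
  the synthetic shape prior; placeholders, not herd-derived values).

Perspective note. A convex body's silhouette is generated by tangent
rays, so a pixel span inverted at the depth of the body mid-plane ``d``
overestimates the true extent: the exact scale plane for an ellipsoid
with vertical semi-thickness ``b_m`` is at ``sqrt(d² − b_m²)`` (derived
in the methods note). The same effect inflates side-view extents read
off a fixed scale factor. ``measure_top`` therefore offers a ``plane``
depth mode that reconstructs the chest mid-plane from the near-surface
depth and the side view's chest depth and applies the tangent
correction, and ``invert_side_silhouette`` solves the side-view tangent
geometry exactly. The uncorrected readings (probe-mean depth, plain
scale factor) remain available as the literal transcription of the
field workflow; their bias on curved bodies is documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import CameraCalibration, ScaleCalibration, pixel_to_cm_side, pixel_to_cm_top
from .depth_io import DepthFrame, LineProbe, depth_along_probe, depth_quantile_along_probe
from .segmentation import BodyMask, extract_keypoints, segment_side


class MorphometryError(ValueError):
    """Raised on missing probes, bad axes or invalid girth inputs."""


GIRTH_METHODS = ("ramanujan", "simple_ellipse", "stadium", "pig_empirical")

#: Affine pig_empirical coefficients (c0 cm, c1 dimensionless), frozen from a
#: least-squares fit of quadrature ellipse perimeters over the default
#: synthetic shape prior. Placeholders standing in for a breed-fitted formula.
DEFAULT_EMPIRICAL_COEFFS = (0.1898, 1.5707)


@dataclass(frozen=True)
class BodyDimensions:
    """The pipeline's central record: L, W, H, D in cm (L_side optional)."""

    L: float
    W: float
    H: float
    D: float
    L_side: float | None = None

    def __post_init__(self) -> None:
        for name in ("L", "W", "H", "D"):
            v = getattr(self, name)
            if not v > 0:
                raise MorphometryError(f"dimension {name} must be > 0, got {v}")
        if self.D > self.H + 1e-9:
            raise MorphometryError(
                f"chest depth D={self.D:.2f} exceeds body height H={self.H:.2f}"
            )

    def to_dict(self) -> dict:
        return {"L": self.L, "W": self.W, "H": self.H, "D": self.D, "L_side": self.L_side}


@dataclass(frozen=True)
class GirthEstimate:
    """Chest girth estimate (cm) from one perimeter model."""

    method: str
    C: float
    a: float
    b: float


# ---------------------------------------------------------------------------
# Girth models


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's ellipse perimeter: π[3(a+b) − √((3a+b)(a+3b))]."""
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def girth(
    W: float,
    D: float,
    method: str = "ramanujan",
    empirical_coeffs: tuple[float, float] | None = None,
) -> GirthEstimate:
    """Estimate chest girth from body width and chest depth.

    W is always the major axis and D the minor (no auto-swap); the
    stadium model additionally requires W ≥ D and asks the caller to
    swap axes explicitly otherwise.
    """
    if not (W > 0 and D > 0):
        raise MorphometryError(f"girth: W and D must be > 0, got W={W}, D={D}")
    a, b = W / 2.0, D / 2.0
    if method == "ramanujan":
        C = ramanujan_perimeter(a, b)
    elif method == "simple_ellipse":
        C = math.pi * (a + b)
    elif method == "stadium":
        if W < D:
            raise MorphometryError(
                f"stadium girth requires W >= D (got W={W} < D={D}); "
                "swap the axes explicitly if that is intended"
            )
        C = math.pi * D + 2.0 * (W - D)
    elif method == "pig_empirical":
        c0, c1 = empirical_coeffs if empirical_coeffs is not None else DEFAULT_EMPIRICAL_COEFFS
        C = c0 + c1 * (W + D)
    else:
        raise MorphometryError(f"unknown girth method '{method}'")
    return GirthEstimate(method=method, C=float(C), a=a, b=b)


# ---------------------------------------------------------------------------
# Top view


def _find_probe(probes, label: str) -> LineProbe:
    for p in probes:
        if p.label == label:
            return p
    raise MorphometryError(f"missing required probe '{label}'")


def measure_top(
    frame: DepthFrame,
    cal: CameraCalibration,
    probes,
    depth_mode: str = "plane",
    chest_depth_cm: float | None = None,
    stat: str = "mean",
) -> tuple[float, float]:
    """Body length L and width W (cm) from a top-view frame.

    depth_mode
        ``"plane"`` (default): the pinhole inversion uses the depth of
        the chest mid-plane, reconstructed as ``d = z_near + D/2`` from
        the near-surface (spine) depth and the side view's chest depth
        ``chest_depth_cm``, with the silhouette tangent correction
        ``z_eff = sqrt(d² − (D/2)²)``. This is unbiased on convex bodies.
        ``"mean"``: the literal field reading — the average depth along
        each probe segment — which on a curved back sits above the
        mid-plane and shrinks the output accordingly.
    """
    length = _find_probe(probes, "length")
    width = _find_probe(probes, "width")
    if depth_mode == "mean":
        zl, _ = depth_along_probe(frame, length, stat=stat)
        zw, _ = depth_along_probe(frame, width, stat=stat)
    elif depth_mode == "plane":
        if chest_depth_cm is None or not chest_depth_cm > 0:
            raise MorphometryError(
                "depth_mode='plane' needs the side view's chest depth (cm)"
            )
        z_near = min(
            depth_quantile_along_probe(frame, length),
            depth_quantile_along_probe(frame, width),
        )
        b_m = chest_depth_cm / 200.0
        d = z_near + b_m
        z_eff = math.sqrt(max(d * d - b_m * b_m, 1e-12))
        zl = zw = z_eff
    else:
        raise MorphometryError(f"unknown depth_mode '{depth_mode}'")
    L = pixel_to_cm_top(length.pixel_length, zl, cal)
    W = pixel_to_cm_top(width.pixel_length, zw, cal)
    return L, W


# ---------------------------------------------------------------------------
# Side view


def measure_side(
    probes, cal: ScaleCalibration, ground_row: float | None = None
) -> tuple[float, float, float | None]:
    """Body height H, chest depth D (and side length) via the scale factor.

    Probes must carry labels ``height`` and ``chest_depth`` (``length``
    optional). If the height probe is to be built from a mask the caller
    must have supplied ``ground_row`` to keypoint extraction; passing it
    here instead rebuilds the probe distance from the stored withers row.
    """
    height = _find_probe(probes, "height")
    chest = _find_probe(probes, "chest_depth")
    if ground_row is not None:
        top = min(height.p0[0], height.p1[0])
        h_px = float(ground_row) - top
    else:
        h_px = height.pixel_length
    H = pixel_to_cm_side(h_px, cal)
    D = pixel_to_cm_side(chest.pixel_length, cal)
    try:
        length = _find_probe(probes, "length")
        L_side = pixel_to_cm_side(length.pixel_length, cal)
    except MorphometryError:
        L_side = None
    return H, D, L_side


@dataclass(frozen=True)
class SideGeometry:
    """Side-camera geometry needed for the exact silhouette inversion."""

    focal_length: float
    principal_row: float
    cam_height: float  # m, optical axis above ground
    distance: float  # m, camera to the animal's sagittal plane

    @property
    def ground_row(self) -> float:
        """Image row of the ground line at the animal's plane."""
        return self.principal_row + self.focal_length * self.cam_height / self.distance


def invert_side_silhouette(
    row_top: float,
    row_bottom: float,
    geom: SideGeometry,
    half_width_m: float,
    distance: float | None = None,
) -> tuple[float, float]:
    """Exact (H, D) in cm from one column's silhouette tangent rows.

    The upper/lower silhouette boundaries at a body column are images of
    rays tangent to that column's cross-section ellipse (vertical
    semi-axis h, horizontal/depth semi-axis w = ``half_width_m``, centre
    height zc at distance ``distance`` from the camera, default the rig's
    sagittal-plane standoff). A ray of slope m with apparent height z* at
    that plane is tangent iff (z* − zc)² = h² + m²w², giving two
    equations in (zc, h):

        zc = (z*₁ + z*₂)/2 − (m₁² − m₂²)·w² / (2(z*₁ − z*₂))
        h  = sqrt((z*₁ − zc)² − m₁²·w²)

    whence D = 2h and the column's top height zc + h (→ H at the withers).
    """
    f, cy = geom.focal_length, geom.principal_row
    d = geom.distance if distance is None else distance
    m1 = (cy - row_top) / f
    m2 = (cy - row_bottom) / f
    z1 = geom.cam_height + m1 * d
    z2 = geom.cam_height + m2 * d
    if z1 <= z2:
        raise MorphometryError("silhouette rows are inverted or degenerate")
    w2 = half_width_m * half_width_m
    zc = 0.5 * (z1 + z2) - (m1 * m1 - m2 * m2) * w2 / (2.0 * (z1 - z2))
    h_sq = (z1 - zc) ** 2 - m1 * m1 * w2
    if h_sq <= 0:
        raise MorphometryError(
            "tangent inversion failed (half_width too large for observed rows)"
        )
    h = math.sqrt(h_sq)
    return 100.0 * (zc + h), 200.0 * h


def invert_side_mask(
    side_frame: DepthFrame,
    side_mask: BodyMask,
    geom: SideGeometry,
    half_width_m: float,
    quantile: float = 0.99,
) -> tuple[float, float]:
    """(H, D) in cm by per-column tangent inversion over the whole mask.

    Each mask column contributes a two-tangent inversion
    (:func:`invert_side_silhouette`) whose working distance is anchored
    on that column's own near-surface depth plus ``half_width_m`` — this
    absorbs yaw and off-plane placement, which shift each cross-section's
    centre off the nominal sagittal plane. Body height and chest depth
    are the high quantile (default 0.99, a max that tolerates a stray
    column) of the per-column top heights and vertical extents.
    """
    m = side_mask.mask
    counts = side_frame.counts
    f = geom.focal_length
    tops, extents = [], []
    for c in np.flatnonzero(m.any(axis=0)):
        rows = np.flatnonzero(m[:, c])
        vals = counts[rows, c]
        vals = vals[vals > 0]
        if vals.size == 0 or rows.size < 3:
            continue
        near = float(np.quantile(vals, 0.02)) * side_frame.unit_scale
        dist = near + half_width_m
        try:
            top_z, extent = invert_side_silhouette(
                rows.min() - 0.5, rows.max() + 0.5, geom, half_width_m, distance=dist
            )
        except MorphometryError:
            continue  # grazing columns near the ends have no valid inversion
        tops.append(top_z)
        extents.append(extent)
    if len(tops) < 3:
        raise MorphometryError("too few valid mask columns for silhouette inversion")
    return float(np.quantile(tops, quantile)), float(np.quantile(extents, quantile))


# ---------------------------------------------------------------------------
# Dual-view fusion


def measure_dual_view(
    top_frame: DepthFrame,
    side_frame: DepthFrame,
    top_cal: CameraCalibration,
    side_cal: ScaleCalibration,
    side_geom: SideGeometry,
    top_background_m: float = 1.40,
    side_background_m: float = 1.00,
    margin_m: float = 0.05,
    perspective: bool = True,
) -> BodyDimensions:
    """Fully automated dual-view measurement of one animal.

    Both frames are segmented by depth threshold and probed from their
    masks. The side view is read first (scale factor) to seed the chest
    depth; the top view then measures L and W at the reconstructed chest
    mid-plane; finally, if ``perspective`` is set, the side silhouette is
    re-inverted exactly using the measured half-width, and the top view
    re-measured with the refined chest depth (the corrections are second
    order, so one refinement pass converges).
    """
    side_mask = segment_side(side_frame, side_background_m, margin_m)
    side_probes = extract_keypoints(side_mask, "side", ground_row=side_geom.ground_row)
    H, D, L_side = measure_side(side_probes, side_cal)

    top_mask = segment_side(top_frame, top_background_m, margin_m)
    top_probes = extract_keypoints(top_mask, "top")
    L, W = measure_top(top_frame, top_cal, top_probes, depth_mode="plane", chest_depth_cm=D)

    if perspective:
        H, D = invert_side_mask(side_frame, side_mask, side_geom, half_width_m=W / 200.0)
        L, W = measure_top(top_frame, top_cal, top_probes, depth_mode="plane", chest_depth_cm=D)
        if L_side is not None:
            # Same tangent-plane scale correction for the horizontal extent.
            d = side_geom.distance
            L_side *= math.sqrt(max(d * d - (W / 200.0) ** 2, 1e-12)) / d

    return BodyDimensions(L=L, W=W, H=H, D=D, L_side=L_side)
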