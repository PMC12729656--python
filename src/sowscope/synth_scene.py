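"""Synthetic pig scenes: cohort sampling, dual-view depth rendering, fixtures.

The animal's trunk is modelled as a single ellipsoid — semi-axes
``semi_length`` (along the body axis), ``semi_width`` (across) and
``semi_height`` (vertical, half the chest depth) — floating ``clearance``
centimetres above the ground plane (the legs are not modelled; the
clearance plays their role so body height is ground-referenced). The
ellipsoid is yawed about the vertical axis and offset in the measurement
zone. This deliberately simple geometry has exact closed-form ground
truth for every quantity the measurement pipeline estimates, so
measurement error is attributable to the pipeline alone.

Ground-truth chest girth is the exact perimeter of the vertical
cross-section ellipse with semi-axes (semi_width, semi_height), computed
by adaptive quadrature of the arc length — an oracle independent of the
closed-form approximations in :mod:`sowscope.morphometry`.

Rendering uses a pinhole camera: per pixel, the depth count is the
distance *along the optical axis* to the first intersection of the
pixel's ray with the ellipsoid, else with the ground plane (top view) or
a background plane behind the animal (side view). Depths are stored as
16-bit counts of 1 mm; 0 marks an invalid pixel. The side view renders
the animal against a background plane 0.30 m behind its sagittal plane
and no floor: a floor sweeping toward a side-mounted camera produces
near-camera depths that defeat depth-threshold segmentation, and the
physical system reads the ground line from geometry anyway.

World frame: right-handed, z up, ground plane z = 0, origin at the
measurement-zone centre. Image coordinates: origin top-left, (row, col),
0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .depth_io import DepthFrame, LineProbe, write_depth
from .weight_models import REFERENCE_INTERCEPT, REFERENCE_SLOPE, bw1


class SceneError(ValueError):
    """Raised on invalid generator parameters."""


class OutOfViewError(RuntimeError):
    """Raised when the animal does not fit inside the camera frustum."""


# ---------------------------------------------------------------------------
# Ground-truth geometry


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter by adaptive quadrature of the arc length.

    ``C = 4 * ∫_0^{π/2} sqrt(a² cos²t + b² sin²t) dt``. Serves as the
    package-internal oracle for every perimeter approximation.
    """
    if not (a > 0 and b > 0):
        raise SceneError(f"ellipse semi-axes must be > 0, got a={a}, b={b}")
    val, _ = quad(
        lambda t: np.sqrt((a * np.cos(t)) ** 2 + (b * np.sin(t)) ** 2),
        0.0,
        np.pi / 2,
        epsabs=1e-12,
        epsrel=1e-12,
    )
    return 4.0 * val


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one synthetic pig. All lengths in cm, weight in kg."""

    pig_id: str
    semi_length: float
    semi_width: float
    semi_height: float
    clearance: float
    center_xy: tuple[float, float] = (0.0, 0.0)
    yaw_deg: float = 0.0
    true_weight: float = field(default=0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("semi_length", "semi_width", "semi_height", "clearance"):
            v = getattr(self, name)
            if not v > 0:
                raise SceneError(f"{name} must be > 0, got {v}")
        aspect = self.true_L / self.true_W
        if not (1.5 <= aspect <= 4.5):
            raise SceneError(
                f"{self.pig_id}: aspect L/W={aspect:.2f} outside pig-like range [1.5, 4.5]"
            )

    # Exact dimensional truth -------------------------------------------------
    @property
    def true_L(self) -> float:
        return 2.0 * self.semi_length

    @property
    def true_W(self) -> float:
        return 2.0 * self.semi_width

    @property
    def true_D(self) -> float:
        return 2.0 * self.semi_height

    @property
    def true_H(self) -> float:
        return self.clearance + 2.0 * self.semi_height

    @property
    def true_C(self) -> float:
        """Exact girth: quadrature perimeter of the (semi_width, semi_height) ellipse."""
        return ellipse_perimeter(self.semi_width, self.semi_height)

    def to_row(self) -> dict:
        return {
            "pig_id": self.pig_id,
            "semi_length": self.semi_length,
            "semi_width": self.semi_width,
            "semi_height": self.semi_height,
            "clearance": self.clearance,
            "center_x": self.center_xy[0],
            "center_y": self.center_xy[1],
            "yaw_deg": self.yaw_deg,
            "true_L": self.true_L,
            "true_W": self.true_W,
            "true_D": self.true_D,
            "true_H": self.true_H,
            "true_C": self.true_C,
            "true_weight": self.true_weight,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CameraRig:
    """Pinhole camera for one view.

    ``standoff`` is the distance from the camera to the measurement
    plane: for the top view, the height above the ground (1.40 m); for
    the side view, the horizontal distance to the zone centre / animal
    sagittal plane (0.70 m). ``cam_height`` (side view only) is the mount
    height of the optical axis above the ground; ``background_offset``
    (side view only) is how far behind the sagittal plane the background
    plane sits.
    """

    view: str
    standoff: float
    focal_length: float
    image_size: tuple[int, int] = (480, 848)
    principal_point: tuple[float, float] | None = None
    cam_height: float = 0.40
    background_offset: float = 0.30

    def __post_init__(self) -> None:
        if self.view not in ("top", "side"):
            raise SceneError(f"view must be 'top' or 'side', got {self.view!r}")
        if not self.standoff > 0:
            raise SceneError(f"standoff must be > 0, got {self.standoff}")
        if not self.focal_length > 0:
            raise SceneError(f"focal_length must be > 0, got {self.focal_length}")
        if self.principal_point is None:
            rows, cols = self.image_size
            object.__setattr__(
                self, "principal_point", ((rows - 1) / 2.0, (cols - 1) / 2.0)
            )

    @property
    def background_depth(self) -> float:
        """Axial depth of the empty background (m)."""
        return self.standoff if self.view == "top" else self.standoff + self.background_offset

    def ground_row(self, sagittal_offset_m: float = 0.0) -> float:
        """Side view: image row of the ground line at the animal's plane."""
        if self.view != "side":
            raise SceneError("ground_row is defined for the side view only")
        dist = self.standoff + sagittal_offset_m
        return self.principal_point[0] + self.focal_length * self.cam_height / dist


def default_top_rig() -> CameraRig:
    return CameraRig(view="top", standoff=1.40, focal_length=420.0)


def default_side_rig() -> CameraRig:
    return CameraRig(view="side", standoff=0.70, focal_length=400.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Depth sensor noise: Gaussian with σ(z) = sigma_at_1m·z², plus holes."""

    sigma_at_1m: float = 0.002
    hole_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_at_1m < 0:
            raise SceneError(f"sigma_at_1m must be >= 0, got {self.sigma_at_1m}")
        if not (0 <= self.hole_rate < 1):
            raise SceneError(f"hole_rate must be in [0, 1), got {self.hole_rate}")


# ---------------------------------------------------------------------------
# Cohort sampling

#: Default shape prior (cm / degrees). Chosen to emulate finishing pigs of
#: roughly 30-100 kg with a chest shallower than it is wide (the girth
#: ellipse's published major axis is the top-view width) and trunk aspect
#: ratios within the pig-like band [1.5, 4.5].
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "semi_length": (30.0, 57.0),
    "semi_width": (12.0, 20.0),
    "depth_to_width": (0.75, 0.95),  # semi_height = ratio * semi_width
    "clearance": (20.0, 30.0),
    "center_x": (-10.0, 10.0),
    "center_y": (0.0, 0.0),
    "yaw_deg": (-8.0, 8.0),
}

#: Max trunk aspect ratio L/W accepted by rejection sampling.
_ASPECT_RANGE = (1.5, 4.5)


def generated_weight(true_C: float, true_L: float) -> float:
    """Noise-free generated weight: the herd fusion fit applied to BW1."""
    return REFERENCE_SLOPE * bw1(true_C, true_L) + REFERENCE_INTERCEPT


def sample_cohort(
    n: int,
    seed: int,
    param_ranges: dict | None = None,
    sigma_w: float = 2.0,
) -> list[SceneTruth]:
    """Sample ``n`` reproducible synthetic pigs.

    Each animal's weight is ``0.8294·BW1(true_C, true_L) + 11.16 + ε``
    with ε ~ Normal(0, σ_w) truncated at ±2σ_w; with the default ranges
    the truncation keeps every weight inside the 30–100 kg cohort
    inclusion band. Geometry is drawn uniformly from ``param_ranges``
    with rejection of non-pig-like aspect ratios.
    """
    if n < 1:
        raise SceneError(f"n must be >= 1, got {n}")
    if sigma_w < 0:
        raise SceneError(f"sigma_w must be >= 0, got {sigma_w}")
    ranges = dict(DEFAULT_RANGES)
    if param_ranges:
        unknown = set(param_ranges) - set(ranges)
        if unknown:
            raise SceneError(f"unknown parameter range(s): {sorted(unknown)}")
        ranges.update(param_ranges)
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise SceneError(f"range for {name} is not ordered: ({lo}, {hi})")
        if name not in ("center_x", "center_y", "yaw_deg") and lo <= 0:
            raise SceneError(f"range for {name} must be positive, got ({lo}, {hi})")

    rng = np.random.default_rng(seed)

    def draw(name: str) -> float:
        lo, hi = ranges[name]
        return float(lo if lo == hi else rng.uniform(lo, hi))

    cohort = []
    for i in range(n):
        for _ in range(1000):
            semi_length = draw("semi_length")
            semi_width = draw("semi_width")
            aspect = semi_length / semi_width
            if _ASPECT_RANGE[0] <= aspect <= _ASPECT_RANGE[1]:
                break
        else:  # pragma: no cover - only reachable with pathological ranges
            raise SceneError("could not sample a pig-like aspect ratio from the given ranges")
        semi_height = draw("depth_to_width") * semi_width
        scene = SceneTruth(
            pig_id=f"pig{i:03d}",
            semi_length=semi_length,
            semi_width=semi_width,
            semi_height=semi_height,
            clearance=draw("clearance"),
            center_xy=(draw("center_x"), draw("center_y")),
            yaw_deg=draw("yaw_deg"),
            seed=seed,
        )
        weight = generated_weight(scene.true_C, scene.true_L)
        if sigma_w > 0:
            eps = rng.normal(0.0, sigma_w)
            while abs(eps) > 2.0 * sigma_w:
                eps = rng.normal(0.0, sigma_w)
            weight += eps
        cohort.append(replace(scene, true_weight=float(weight)))
    return cohort


# ---------------------------------------------------------------------------
# Rendering


def _ray_grid(rig: CameraRig) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ray origin (3,) and directions (rows, cols, 3).

    Rays are parameterized by axial depth t: point(t) = origin + t * dir,
    with the component along the optical axis equal to ±1 so that t is
    the stored depth.
    """
    rows, cols = rig.image_size
    cy, cx = rig.principal_point
    f = rig.focal_length
    r = np.arange(rows, dtype=np.float64)[:, None]
    c = np.arange(cols, dtype=np.float64)[None, :]
    d = np.empty((rows, cols, 3), dtype=np.float64)
    if rig.view == "top":
        origin = np.array([0.0, 0.0, rig.standoff])
        d[..., 0] = np.broadcast_to((c - cx) / f, (rows, cols))  # x ~ col
        d[..., 1] = np.broadcast_to((r - cy) / f, (rows, cols))  # y ~ row
        d[..., 2] = -1.0
    else:
        origin = np.array([0.0, -rig.standoff, rig.cam_height])
        d[..., 0] = np.broadcast_to((c - cx) / f, (rows, cols))  # x ~ col
        d[..., 1] = 1.0
        d[..., 2] = np.broadcast_to((cy - r) / f, (rows, cols))  # z up ~ -row
    return origin, d


def _ellipsoid_hits(scene: SceneTruth, origin: np.ndarray, dirs: np.ndarray):
    """Smallest positive axial depth of ray-ellipsoid intersection, or NaN."""
    l, w, h = (
        scene.semi_length / 100.0,
        scene.semi_width / 100.0,
        scene.semi_height / 100.0,
    )
    cx_w, cy_w = (v / 100.0 for v in scene.center_xy)
    center = np.array([cx_w, cy_w, scene.clearance / 100.0 + h])
    psi = np.deg2rad(scene.yaw_deg)
    # Rows of R map world vectors onto body axes (u_length, u_width, u_up).
    R = np.array(
        [
            [np.cos(psi), np.sin(psi), 0.0],
            [-np.sin(psi), np.cos(psi), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    inv_axes = 1.0 / np.array([l, w, h])
    e = (R @ (origin - center)) * inv_axes
    s = np.einsum("ij,rcj->rci", R, dirs) * inv_axes
    A = np.sum(s * s, axis=-1)
    B = 2.0 * np.sum(e * s, axis=-1)
    Cq = float(np.sum(e * e) - 1.0)
    disc = B * B - 4.0 * A * Cq
    hit = disc >= 0.0
    t = np.full(A.shape, np.nan)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t_near = (-B - sq) / (2.0 * A)
    t[hit] = t_near[hit]
    t[t <= 0] = np.nan
    return t


def _render(scene: SceneTruth, rig: CameraRig) -> tuple[np.ndarray, np.ndarray]:
    origin, dirs = _ray_grid(rig)
    t_body = _ellipsoid_hits(scene, origin, dirs)
    hit = np.isfinite(t_body)
    if not hit.any():
        raise OutOfViewError(f"{scene.pig_id}: animal not visible in {rig.view} view")
    if hit[0, :].any() or hit[-1, :].any() or hit[:, 0].any() or hit[:, -1].any():
        raise OutOfViewError(
            f"{scene.pig_id}: animal silhouette touches the {rig.view}-view frame "
            "border (outside the camera frustum); refusing to crop silently"
        )
    depth = np.where(hit, t_body, rig.background_depth)
    counts = np.clip(np.rint(depth * 1000.0), 0, 0xFFFF).astype(np.uint16)
    return counts, hit


def render_depth(scene: SceneTruth, rig: CameraRig) -> DepthFrame:
    """Render a noise-free depth frame (counts of 1 mm) for one view.

    Raises :class:`OutOfViewError` if the silhouette does not fit fully
    inside the frame.
    """
    counts, _ = _render(scene, rig)
    return DepthFrame(counts=counts)


def render_silhouette(scene: SceneTruth, rig: CameraRig) -> np.ndarray:
    """Boolean ground-truth silhouette mask (ellipsoid-hit pixels)."""
    _, hit = _render(scene, rig)
    return hit


def apply_noise(frame: DepthFrame, spec: NoiseSpec) -> DepthFrame:
    """Perturb a frame with depth-dependent Gaussian noise and holes.

    σ(z) = sigma_at_1m · z² (consumer depth sensors degrade
    quadratically with range); a ``hole_rate`` fraction of pixels is
    zeroed. Reproducible for a given ``spec.seed``; a zero-noise,
    zero-hole spec returns counts identical to the input.
    """
    rng = np.random.default_rng(spec.seed)
    z = frame.counts.astype(np.float64) * frame.unit_scale
    valid = frame.counts > 0
    if spec.sigma_at_1m > 0:
        z = z + rng.normal(size=z.shape) * spec.sigma_at_1m * z**2
    counts = np.clip(np.rint(z / frame.unit_scale), 0, 0xFFFF).astype(np.uint16)
    counts[~valid] = 0
    if spec.hole_rate > 0:
        holes = rng.random(size=counts.shape) < spec.hole_rate
        counts[holes] = 0
    return DepthFrame(counts=counts, unit_scale=frame.unit_scale)


def reference_probe(
    rig: CameraRig, length_cm: float = 50.0, offset_m: float = 0.45
) -> tuple[LineProbe, float]:
    """Probe over a reference marker of known length, for calibration.

    Emulates the operator marking a segment of known physical length:
    top view — a bar of ``length_cm`` lying on the ground, off-centre by
    ``offset_m`` so it clears the animal; side view — a bar at the
    animal's sagittal plane at camera height. Returns the probe (exact
    projected endpoints) and the known length in cm.
    """
    f = rig.focal_length
    cy, cx = rig.principal_point
    half = length_cm / 200.0  # metres
    if rig.view == "top":
        z = rig.standoff
        r = cy + f * (-offset_m) / z
        probe = LineProbe(
            p0=(r, cx - f * half / z), p1=(r, cx + f * half / z), label="reference"
        )
    else:
        z = rig.standoff
        r = cy  # camera height
        probe = LineProbe(
            p0=(r, cx - f * half / z), p1=(r, cx + f * half / z), label="reference"
        )
    return probe, length_cm


# ---------------------------------------------------------------------------
# Fixture writing

TRUTH_COLUMNS = [
    "pig_id", "semi_length", "semi_width", "semi_height", "clearance",
    "center_x", "center_y", "yaw_deg",
    "true_L", "true_W", "true_D", "true_H", "true_C", "true_weight", "seed",
]


def cohort_to_frame(cohort: Sequence[SceneTruth]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in cohort], columns=TRUTH_COLUMNS)


def read_truth_csv(path: str | Path) -> list[SceneTruth]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SceneTruth(
                pig_id=str(row.pig_id),
                semi_length=row.semi_length,
                semi_width=row.semi_width,
                semi_height=row.semi_height,
                clearance=row.clearance,
                center_xy=(row.center_x, row.center_y),
                yaw_deg=row.yaw_deg,
                true_weight=row.true_weight,
                seed=None if pd.isna(row.seed) else int(row.seed),
            )
        )
    return out


def write_fixture(
    cohort: Sequence[SceneTruth],
    out_dir: str | Path,
    top_rig: CameraRig | None = None,
    side_rig: CameraRig | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> dict:
    """Write per-pig depth images, truth masks, a truth CSV and a manifest.

    For every animal: top and side 16-bit depth PNGs (noisy if ``noise``
    is given) and an 8-bit side-view truth mask from the noise-free
    render. Returns the manifest dict (also written as JSON).
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"fixture directory {out_dir} is not writable: {exc}") from exc

    top_rig = top_rig or default_top_rig()
    side_rig = side_rig or default_side_rig()
    if seed is None:
        seed = cohort[0].seed if cohort and cohort[0].seed is not None else 0

    files: list[str] = []
    for i, scene in enumerate(cohort):
        frames = {"top": render_depth(scene, top_rig), "side": render_depth(scene, side_rig)}
        mask = render_silhouette(scene, side_rig)
        if noise is not None:
            for view in frames:
                frames[view] = apply_noise(
                    frames[view], replace(noise, seed=noise.seed + 1000 * i + (view == "side"))
                )
        for view, frame in frames.items():
            name = f"{scene.pig_id}_{view}.png"
            write_depth(frame, out_dir / name)
            files.append(name)
        mask_name = f"{scene.pig_id}_mask.png"
        iio.imwrite(out_dir / mask_name, (mask.astype(np.uint8) * 255))
        files.append(mask_name)

    truth_name = "truth.csv"
    # %.17g guarantees float64 round-trip through the CSV.
    cohort_to_frame(cohort).to_csv(out_dir / truth_name, index=False, float_format="%.17g")
    files.append(truth_name)

    manifest = {
        "seed": seed,
        "n": len(cohort),
        "noise": None
        if noise is None
        else {"sigma_at_1m": noise.sigma_at_1m, "hole_rate": noise.hole_rate, "seed": noise.seed},
        "top_rig": {"standoff_m": top_rig.standoff, "focal_px": top_rig.focal_length,
                    "image_size": list(top_rig.image_size)},
        "side_rig": {"standoff_m": side_rig.standoff, "focal_px": side_rig.focal_length,
                     "cam_height_m": side_rig.cam_height,
                     "background_offset_m": side_rig.background_offset,
                     "image_size": list(side_rig.image_size)},
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
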