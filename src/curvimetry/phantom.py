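"""Synthetic bent-shaft phantom generator.

Real validation data for curvature measurement are photographs of
3D-printed shaft models with known, uniplanar hinging curvature.  This
module generates the equivalent synthetic scene: a two-limb bent capsule
of pediatric proportions (default 1.5 cm wide, ~5.5 cm long at
40 px/cm), photographed by a pinhole camera that may be tilted
horizontally (pan, -5..5 deg) and vertically (0..20 deg) about the
object center at a 22.5 cm working distance, with optional Gaussian
boundary raggedness emulating imperfect segmentation.

Every sample carries its exact ground-truth curvature angle — the angle
between the proximal and distal limb axes, 0 deg meaning straight — so
the downstream estimator can be scored without any manual annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage import draw, measure, morphology, transform

from .errors import InvalidSpecError, OutOfRangeError, PlacementError
from .types import BoundingBox

#: Pixel scale tying the phantom to physical model proportions.
PX_PER_CM = 40.0
#: Camera working distance in px units (midpoint of the 20-25 cm range).
WORKING_DISTANCE_PX = 22.5 * PX_PER_CM

#: The nine ground-truth model angles of the physical phantom set.
PANEL_ANGLES_DEG = (18.0, 33.0, 40.0, 50.0, 58.0, 60.0, 75.0, 86.0, 88.0)

HORIZONTAL_TILT_RANGE = (-5.0, 5.0)
VERTICAL_TILT_RANGE = (0.0, 20.0)

_FOREGROUND_GRAY = 60
_BACKGROUND_GRAY = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one synthetic shaft image.

    ``curvature_angle_deg`` is the deviation from straight: the acute
    angle between the two limb axes, in [0, 90].
    """

    curvature_angle_deg: float
    shaft_width_px: float = 60.0
    proximal_limb_len_px: float = 110.0
    distal_limb_len_px: float = 110.0
    bend_radius_px: float = 6.0
    horizontal_tilt_deg: float = 0.0
    vertical_tilt_deg: float = 0.0
    image_size_px: tuple[int, int] = (640, 640)
    boundary_noise_sigma_px: float = 0.0
    background_style: str = "flat"
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.curvature_angle_deg <= 90.0:
            raise InvalidSpecError(
                f"curvature_angle_deg={self.curvature_angle_deg} outside [0, 90]"
            )
        if self.shaft_width_px <= 0:
            raise InvalidSpecError(f"shaft_width_px={self.shaft_width_px} must be > 0")
        if self.proximal_limb_len_px <= 0:
            raise InvalidSpecError(
                f"proximal_limb_len_px={self.proximal_limb_len_px} must be > 0"
            )
        if self.distal_limb_len_px <= 0:
            raise InvalidSpecError(
                f"distal_limb_len_px={self.distal_limb_len_px} must be > 0"
            )
        if self.bend_radius_px < 0:
            raise InvalidSpecError(f"bend_radius_px={self.bend_radius_px} must be >= 0")
        lo, hi = HORIZONTAL_TILT_RANGE
        if not lo <= self.horizontal_tilt_deg <= hi:
            raise InvalidSpecError(
                f"horizontal_tilt_deg={self.horizontal_tilt_deg} outside [{lo}, {hi}]"
            )
        lo, hi = VERTICAL_TILT_RANGE
        if not lo <= self.vertical_tilt_deg <= hi:
            raise InvalidSpecError(
                f"vertical_tilt_deg={self.vertical_tilt_deg} outside [{lo}, {hi}]"
            )
        if self.boundary_noise_sigma_px < 0:
            raise InvalidSpecError(
                f"boundary_noise_sigma_px={self.boundary_noise_sigma_px} must be >= 0"
            )
        if self.background_style not in ("flat", "textured"):
            raise InvalidSpecError(
                f"background_style={self.background_style!r} not in {{flat, textured}}"
            )
        h, w = self.image_size_px
        ext_x, ext_y = self._planar_extents()
        if ext_x + 10 > w or ext_y + 10 > h:
            raise InvalidSpecError(
                "image_size_px too small: shaft extent "
                f"({ext_x:.0f}, {ext_y:.0f}) px leaves < 5 px margin in ({h}, {w})"
            )

    # -- geometry helpers ------------------------------------------------

    def _limb_dirs(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit limb-axis directions in image coords (x right, y down).

        Both limbs point away from the hinge and upward; the angle
        between the two axis *lines* equals ``curvature_angle_deg``.
        """
        half = np.deg2rad(self.curvature_angle_deg) / 2.0
        d_distal = np.array([np.cos(half), -np.sin(half)])
        d_proximal = np.array([-np.cos(half), -np.sin(half)])
        return d_proximal, d_distal

    def _segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Hinge and limb endpoints, centered inside the image."""
        d_p, d_d = self._limb_dirs()
        hinge = np.zeros(2)
        p_prox = hinge + self.proximal_limb_len_px * d_p
        p_dist = hinge + self.distal_limb_len_px * d_d
        r = self.shaft_width_px / 2.0
        pts = np.stack([hinge, p_prox, p_dist])
        lo = pts.min(axis=0) - r
        hi = pts.max(axis=0) + r
        h, w = self.image_size_px
        center_shift = np.array([w / 2.0, h / 2.0]) - (lo + hi) / 2.0
        return hinge + center_shift, p_prox + center_shift, p_dist + center_shift

    def _planar_extents(self) -> tuple[float, float]:
        d_p, d_d = self._limb_dirs()
        pts = np.stack(
            [
                np.zeros(2),
                self.proximal_limb_len_px * d_p,
                self.distal_limb_len_px * d_d,
            ]
        )
        span = pts.max(axis=0) - pts.min(axis=0) + self.shaft_width_px
        return float(span[0]), float(span[1])


@dataclass(frozen=True)
class PhantomSample:
    """One generated phantom: image, mask, tight box and ground truth."""

    image: np.ndarray
    mask: np.ndarray
    bbox: BoundingBox
    gt_angle_deg: float
    spec: PhantomSpec


def _segment_distance(xx, yy, a, b):
    """Distance from each grid point to the segment a-b (vectorized)."""
    ab = b - a
    denom = float(ab @ ab)
    px = xx - a[0]
    py = yy - a[1]
    t = np.clip((px * ab[0] + py * ab[1]) / denom, 0.0, 1.0)
    return np.hypot(px - t * ab[0], py - t * ab[1])


def _planar_mask(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the two-capsule union, then fillet the outer bend."""
    h, w = spec.image_size_px
    hinge, p_prox, p_dist = spec._segments()
    yy, xx = np.mgrid[0:h, 0:w]
    r = spec.shaft_width_px / 2.0
    d1 = _segment_distance(xx, yy, hinge, p_prox)
    d2 = _segment_distance(xx, yy, hinge, p_dist)
    mask = np.minimum(d1, d2) <= r
    br = int(round(spec.bend_radius_px))
    if br > 0 and spec.curvature_angle_deg > 0:
        # morphological opening rounds the convex outer-bend vertex into
        # a radial fillet while leaving the (already round) caps intact
        mask = ndi.binary_opening(mask, structure=morphology.disk(br))
    return mask


def tilt_homography(
    horizontal_tilt_deg: float,
    vertical_tilt_deg: float,
    center_xy: tuple[float, float],
    distance_px: float = WORKING_DISTANCE_PX,
) -> np.ndarray:
    """Forward homography of a pinhole camera tilted about the object.

    The object lies in the z = 0 plane through ``center_xy``; the camera
    sits at ``distance_px`` along the optical axis with focal length
    equal to that distance, so zero tilt is the exact identity.
    """
    hr = np.deg2rad(horizontal_tilt_deg)
    vr = np.deg2rad(vertical_tilt_deg)
    ry = np.array(
        [[np.cos(hr), 0, np.sin(hr)], [0, 1, 0], [-np.sin(hr), 0, np.cos(hr)]]
    )
    rx = np.array(
        [[1, 0, 0], [0, np.cos(vr), -np.sin(vr)], [0, np.sin(vr), np.cos(vr)]]
    )
    r = rx @ ry
    d = distance_px
    cx, cy = center_xy
    # image (x, y) -> Cartesian plane coords (X, Y) with y flipped
    a = np.array([[1, 0, -cx], [0, -1, cy], [0, 0, 1]], dtype=float)
    # plane point -> camera frame -> perspective projection (f = d)
    m = np.array(
        [
            [d * r[0, 0], d * r[0, 1], 0],
            [d * r[1, 0], d * r[1, 1], 0],
            [r[2, 0], r[2, 1], d],
        ]
    )
    b = np.array([[1, 0, cx], [0, -1, cy], [0, 0, 1]], dtype=float)
    return b @ m @ a


def apply_perspective_tilt(
    mask: np.ndarray,
    horizontal_tilt_deg: float,
    vertical_tilt_deg: float,
    distance_px: float = WORKING_DISTANCE_PX,
) -> np.ndarray:
    """Project a mask through the tilted-camera homography.

    Zero tilt returns the mask unchanged; the output is re-binarized at
    0.5 after bilinear resampling.
    """
    lo, hi = HORIZONTAL_TILT_RANGE
    if not lo <= horizontal_tilt_deg <= hi:
        raise OutOfRangeError(f"horizontal tilt {horizontal_tilt_deg} outside [{lo}, {hi}]")
    lo, hi = VERTICAL_TILT_RANGE
    if not lo <= vertical_tilt_deg <= hi:
        raise OutOfRangeError(f"vertical tilt {vertical_tilt_deg} outside [{lo}, {hi}]")
    if horizontal_tilt_deg == 0.0 and vertical_tilt_deg == 0.0:
        return mask.copy()
    ys, xs = np.nonzero(mask)
    center = (float(xs.mean()), float(ys.mean()))
    h = tilt_homography(horizontal_tilt_deg, vertical_tilt_deg, center, distance_px)
    tform = transform.ProjectiveTransform(matrix=h)
    warped = transform.warp(
        mask.astype(float), tform.inverse, order=1, preserve_range=True
    )
    return warped >= 0.5


def _roughen_boundary(
    mask: np.ndarray, sigma_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Displace the contour along its normals by correlated Gaussian noise.

    The displacement field is white noise smoothed along the contour
    (scale ~3 samples) and rescaled to standard deviation ``sigma_px``,
    emulating the ragged, locally correlated boundary of an imperfect
    segmentation without breaking the region into pieces.
    """
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)[:-1]  # drop duplicated closing point
    n = len(contour)
    tangent = np.gradient(contour, axis=0)
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent /= norm
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    noise = gaussian_filter1d(rng.standard_normal(n), sigma=3.0, mode="wrap")
    std = noise.std()
    if std > 0:
        noise *= sigma_px / std
    pts = contour + noise[:, None] * normal
    rough = np.zeros_like(mask)
    rr, cc = draw.polygon(pts[:, 0], pts[:, 1], shape=mask.shape)
    rough[rr, cc] = True
    return rough


def _render_image(
    mask: np.ndarray, style: str, rng: np.random.Generator
) -> np.ndarray:
    """Render the 8-bit grayscale photo: dark shaft on a light background."""
    h, w = mask.shape
    if style == "textured":
        bg = _BACKGROUND_GRAY + 20.0 * gaussian_filter(
            rng.standard_normal((h, w)), sigma=8.0
        )
        fg = _FOREGROUND_GRAY + 5.0 * rng.standard_normal((h, w))
        img = np.where(mask, fg, bg)
    else:
        img = np.where(mask, float(_FOREGROUND_GRAY), float(_BACKGROUND_GRAY))
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom sample from its full parametric description.

    The planar two-capsule shape is built first, then the perspective
    tilt is applied, then boundary noise; the returned mask always has
    exactly one connected component.  Deterministic given
    ``spec.rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    mask = _planar_mask(spec)
    if spec.horizontal_tilt_deg != 0.0 or spec.vertical_tilt_deg != 0.0:
        mask = apply_perspective_tilt(
            mask, spec.horizontal_tilt_deg, spec.vertical_tilt_deg
        )
    if spec.boundary_noise_sigma_px > 0:
        mask = _roughen_boundary(mask, spec.boundary_noise_sigma_px, rng)
    image = _render_image(mask, spec.background_style, rng)
    return PhantomSample(
        image=image,
        mask=mask,
        bbox=BoundingBox.from_mask(mask),
        gt_angle_deg=spec.curvature_angle_deg,
        spec=spec,
    )


def make_degraded(
    sample: PhantomSample, hole_count: int, hole_radius_px: int, rng_seed: int
) -> np.ndarray:
    """Punch ``hole_count`` circular interior holes into the sample mask.

    Holes are placed strictly inside the shaft (never touching its
    boundary), so flood-fill hole closure can recover the original mask
    exactly.  Returns the degraded mask; the original is untouched.
    """
    mask = sample.mask.copy()
    if hole_count == 0:
        return mask
    # centers must keep the full hole strictly interior
    dist = ndi.distance_transform_edt(mask)
    eligible = np.argwhere(dist > hole_radius_px + 1)
    if len(eligible) < hole_count:
        raise PlacementError(
            f"cannot place {hole_count} holes of radius {hole_radius_px}px "
            "strictly inside the mask"
        )
    rng = np.random.default_rng(rng_seed)
    centers = eligible[rng.choice(len(eligible), size=hole_count, replace=False)]
    for r0, c0 in centers:
        rr, cc = draw.disk((r0, c0), hole_radius_px, shape=mask.shape)
        mask[rr, cc] = False
    return mask


def generate_paper_panel(
    rng_seed: int,
    n_per_angle: int,
    angles_deg: tuple[float, ...] = PANEL_ANGLES_DEG,
    boundary_noise_sigma_px: float = 1.0,
    background_style: str = "flat",
) -> list[PhantomSample]:
    """Generate the evaluation panel: ``n_per_angle`` phantoms per model angle.

    Camera tilts are drawn uniformly from the capture ranges
    (horizontal -5..5 deg, vertical 0..20 deg); each sample gets an
    independent child seed, so the panel is deterministic given
    ``rng_seed``.
    """
    if n_per_angle < 1:
        raise InvalidSpecError(f"n_per_angle={n_per_angle} must be >= 1")
    master = np.random.default_rng(rng_seed)
    samples: list[PhantomSample] = []
    for angle in angles_deg:
        for _ in range(n_per_angle):
            spec = PhantomSpec(
                curvature_angle_deg=angle,
                horizontal_tilt_deg=float(master.uniform(*HORIZONTAL_TILT_RANGE)),
                vertical_tilt_deg=float(master.uniform(*VERTICAL_TILT_RANGE)),
                boundary_noise_sigma_px=boundary_noise_sigma_px,
                background_style=background_style,
                rng_seed=int(master.integers(0, 2**31 - 1)),
            )
            samples.append(generate_phantom(spec))
    return samples
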