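"""Curvature-angle estimation from a post-processed binary mask.

The measurement chain mirrors how a clinician reads a bent shaft: find
the four corner landmarks of the shaft region (minimum-eigenvalue
cornerness), fit straight lines to the shaft edges (Hough transform on
the mask contour), pick one line per limb from the two edge regions the
corner-derived canonical pose defines, and report the acute angle
between the two selected lines from their Cartesian slopes:

    theta = arctan| (m1 - m2) / (1 + m1 m2) |

with the vertical-line branch arctan(1 / |m_i|) when one slope is
infinite.  The result is the deviation from straight, in [0, 90] deg.

All slopes live in a Cartesian frame (y up); image rows are negated
when converting Hough (rho, theta) pairs, so that a line satisfies
x cos(theta) + y sin(theta) = rho with slope m = -cos(theta)/sin(theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import corner_peaks, corner_shi_tomasi
from skimage.transform import hough_line, hough_line_peaks

from .errors import (
    DegenerateShapeError,
    EmptyMaskError,
    NoLinesError,
    PipelineStageError,
    SelectionFailureError,
)
from .postprocess import postprocess_mask
from .types import as_mask

#: Distinguished slope value for vertical lines (sin(theta) = 0).
VERTICAL = float("inf")

# A cornerness maximum is admissible only where the contour's turning is
# locally concentrated: the turn across a short arc around the maximum
# must well exceed the contour's average turn over the same arc length.
# A disc turns at a uniform rate, so no maximum qualifies at any radius.
_TURN_CONCENTRATION = 1.6
_PEAK_ABS_FLOOR = 1e-3

_SQUARE = ndi.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class CornerSet:
    """The four shaft-region corner landmarks, strongest first.

    ``corners`` holds (x, y) image pixel coordinates.
    """

    corners: np.ndarray  # (4, 2) float, columns (x, y)
    cornerness: np.ndarray  # (4,) min-eigenvalue scores


@dataclass(frozen=True)
class ShaftLine:
    """One detected straight shaft edge.

    (rho, theta) are Cartesian-frame Hough parameters (y up, theta in
    [0, pi)); ``slope`` is the Cartesian slope or VERTICAL; ``votes``
    the accumulator count; ``endpoints`` the extremes of the supporting
    contour span.
    """

    rho: float
    theta: float
    slope: float
    endpoints: np.ndarray  # (2, 2) image coords (x, y)
    votes: int
    support_xy: np.ndarray = field(repr=False, default=None)  # (N, 2) image coords
    support_outward: np.ndarray = field(repr=False, default=None)  # (N, 2) Cartesian

    @property
    def span(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))


@dataclass(frozen=True)
class CurvatureEstimate:
    """Estimated curvature angle plus the evidence it came from."""

    angle_deg: float
    line_lower: ShaftLine
    line_upper: ShaftLine
    corners: CornerSet | None  # None on the near-straight fallback path
    diagnostics: dict


def _shaft_width_estimate(mask: np.ndarray) -> float:
    """Shaft width as twice the deepest interior inscribed radius."""
    return 2.0 * float(ndi.distance_transform_edt(mask).max())


def _contour(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: mask pixels with a 4-neighbor outside the mask."""
    eroded = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1))
    return mask & ~eroded


def _contour_turns(mask: np.ndarray, points_xy: np.ndarray, arc_px: float):
    """Local vs average contour turning at each query point.

    For every query point, finds the nearest vertex of the longest
    0.5-level contour and measures the absolute direction change
    between the two secants reaching ``arc_px`` backward and forward
    along the contour.  Returns (local turn, average turn over the same
    arc) in degrees; for a convex shape the average is 360 * 2 arc / P.
    """
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise DegenerateShapeError("mask has no 0.5-level contour")
    contour = max(contours, key=len)[:-1]
    seg = np.linalg.norm(np.diff(contour, axis=0, append=contour[:1]), axis=1)
    perimeter = float(seg.sum())
    step = max(1, int(round(arc_px / max(seg.mean(), 1e-9))))
    # per-vertex secant turn, vectorized over the whole contour
    back = np.roll(contour, step, axis=0)
    fwd = np.roll(contour, -step, axis=0)
    v1 = contour - back
    v2 = fwd - contour
    a = np.degrees(np.arctan2(v2[:, 0], v2[:, 1]) - np.arctan2(v1[:, 0], v1[:, 1]))
    vertex_turn = np.abs((a + 180.0) % 360.0 - 180.0)
    # a peak may sit a pixel or two off the true vertex: credit it with
    # the sharpest turn among contour vertices in a small window
    turns = np.empty(len(points_xy))
    pts_rc = points_xy[:, ::-1]  # (x, y) -> (row, col)
    for i, p in enumerate(pts_rc):
        d2 = ((contour - p) ** 2).sum(axis=1)
        near = d2 <= 16.0
        if not near.any():
            near = d2 == d2.min()
        turns[i] = vertex_turn[near].max()
    # the two secants span midpoints one arc apart, so the matching
    # uniform-turn baseline is 360 * arc / perimeter
    avg_turn = 360.0 * (step * float(seg.mean())) / perimeter
    return turns, avg_turn


def detect_corners(mask: np.ndarray, nms_radius: float | None = None) -> CornerSet:
    """Four corner landmarks of the shaft region.

    Cornerness is the minimum-eigenvalue (Shi-Tomasi) response of the
    structure tensor computed on the binary field with a Gaussian
    window (sigma 1, ~5x5 support), evaluated over the boundary band.
    A cornerness maximum is admissible only where the contour's turning
    is locally concentrated (well above the contour's average turn over
    the same arc), which rejects both flat edges and the uniform-rate
    ring of a disc at any radius; admissible maxima are ranked by turn
    concentration and thinned so no two returned corners lie within the
    suppression radius (default 0.75 shaft widths, so one rounded cap
    cannot contribute two corners).  Raises
    :class:`DegenerateShapeError` when fewer than four admissible,
    non-adjacent maxima exist (a disc, a very blunt blob).
    """
    mask = as_mask(mask)
    if not mask.any():
        raise EmptyMaskError("mask has no foreground pixels")
    response = corner_shi_tomasi(mask.astype(float), sigma=1.0)
    band = ndi.binary_dilation(_contour(mask), structure=_SQUARE, iterations=2)
    response = np.where(band, response, 0.0)
    width_est = _shaft_width_estimate(mask)
    if nms_radius is None:
        # wide enough that the two strongest maxima of one rounded cap
        # cannot both be returned as "corners"
        nms_radius = 0.75 * width_est
    # dense local maxima first: a pixel-scale noise bump may out-score
    # the true landmark inside one suppression neighborhood, so
    # admissibility and ranking must see every maximum
    peaks = corner_peaks(
        response,
        min_distance=3,
        threshold_abs=_PEAK_ABS_FLOOR,
        threshold_rel=0.0,
        num_peaks=256,
        exclude_border=False,
    )
    turns = np.empty(0)
    if len(peaks) > 0:
        pts_xy = peaks[:, ::-1].astype(float)
        turns, avg_turn = _contour_turns(mask, pts_xy, arc_px=0.3 * width_est)
        admissible = turns >= _TURN_CONCENTRATION * avg_turn
        peaks = peaks[admissible]
        turns = turns[admissible]
    # rank by turn concentration: geometric landmarks (bend vertices,
    # cap extremes) turn far more than pixel-scale boundary raggedness,
    # whose raw cornerness can nevertheless be large; then suppress
    # maxima adjacent to an already accepted one
    scores = response[peaks[:, 0], peaks[:, 1]] if len(peaks) else np.empty(0)
    order = np.lexsort((-scores, -turns))
    chosen: list[int] = []
    for i in order:
        p = peaks[i]
        if all(np.hypot(*(p - peaks[j])) >= nms_radius for j in chosen):
            chosen.append(i)
        if len(chosen) == 4:
            break
    if len(chosen) < 4:
        raise DegenerateShapeError(
            f"only {len(chosen)} admissible, mutually non-adjacent cornerness "
            "maxima (need 4); contour turning is not locally concentrated"
        )
    pts = peaks[chosen][:, ::-1].astype(float)  # (row, col) -> (x, y)
    return CornerSet(corners=pts, cornerness=scores[chosen])


def _image_to_cartesian_line(theta_img: float, rho_img: float) -> tuple[float, float]:
    """Convert skimage Hough (theta, rho) in image coords to Cartesian (y up)."""
    theta = -theta_img
    rho = rho_img
    if theta < 0:
        theta += math.pi
        rho = -rho
    elif theta >= math.pi:
        theta -= math.pi
        rho = -rho
    return theta, rho


def _slope_from_theta(theta: float, eps: float = 1e-9) -> float:
    s = math.sin(theta)
    if abs(s) < eps:
        return VERTICAL
    return -math.cos(theta) / s


def detect_lines(
    mask: np.ndarray,
    threshold_factor: float = 0.3,
    num_peaks: int = 24,
) -> list[ShaftLine]:
    """Hough-transform line candidates on the mask contour.

    Accumulator resolution is 1 px in rho and 1 deg in theta; the vote
    threshold is ``threshold_factor`` times the longer-limb length
    estimate (half the major-axis extent of the shaft), which keeps the
    detector resolution-independent.  Candidates are returned sorted by
    votes, strongest first, each carrying its supporting contour pixels
    and their outward normals for the selection stage.
    """
    mask = as_mask(mask)
    if not mask.any():
        raise NoLinesError("empty mask: no contour to fit lines to")
    contour = _contour(mask)
    rows, cols = np.nonzero(contour)

    # longer-limb estimate: half the extent along the principal axis
    pts = np.column_stack([cols, rows]).astype(float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    limb_est = (proj.max() - proj.min()) / 2.0
    vote_threshold = max(5.0, threshold_factor * limb_est)

    theta_bins = np.deg2rad(np.arange(-90.0, 90.0, 1.0))
    hspace, angles, dists = hough_line(contour, theta=theta_bins)
    accum, thetas_img, rhos_img = hough_line_peaks(
        hspace,
        angles,
        dists,
        min_distance=5,
        min_angle=3,
        threshold=vote_threshold,
        num_peaks=num_peaks,
    )
    if len(accum) == 0:
        raise NoLinesError(
            f"no Hough peak above vote threshold {vote_threshold:.1f}"
        )

    # outward normal field from the smoothed mask gradient (Cartesian y up)
    smooth = ndi.gaussian_filter(mask.astype(float), sigma=2.0)
    gy, gx = np.gradient(smooth)
    out_x = -gx
    out_y = gy  # image-row gradient flips sign in Cartesian
    nrm = np.hypot(out_x, out_y)
    nrm[nrm == 0] = 1.0
    out_x /= nrm
    out_y /= nrm

    lines: list[ShaftLine] = []
    for votes, th_img, rho_img in zip(accum, thetas_img, rhos_img):
        # distance of contour pixels to the line, in image coords
        dist = np.abs(cols * math.cos(th_img) + rows * math.sin(th_img) - rho_img)
        sel = dist <= 2.5
        sx, sy = cols[sel], rows[sel]
        if sx.size == 0:
            continue
        if sx.size >= 5:
            # refine the accumulator-cell line by total least squares on
            # its support, removing the 1-deg / 1-px quantization
            sup = np.column_stack([sx, sy]).astype(float)
            mean = sup.mean(axis=0)
            _, _, vvt = np.linalg.svd(sup - mean, full_matrices=False)
            normal = vvt[1]
            th_ref = math.atan2(normal[1], normal[0])
            # wrap the refined normal angle next to the accumulator bin
            diff = (th_ref - th_img + math.pi / 2) % math.pi - math.pi / 2
            if abs(diff) <= math.radians(2.0):
                th_img = th_img + diff
                rho_img = float(mean @ [math.cos(th_img), math.sin(th_img)])
        theta, rho = _image_to_cartesian_line(float(th_img), float(rho_img))
        # endpoints: extremes of the support along the line direction
        direction = np.array([-math.sin(th_img), math.cos(th_img)])
        t = sx * direction[0] + sy * direction[1]
        i0, i1 = int(np.argmin(t)), int(np.argmax(t))
        endpoints = np.array(
            [[sx[i0], sy[i0]], [sx[i1], sy[i1]]], dtype=float
        )
        lines.append(
            ShaftLine(
                rho=rho,
                theta=theta,
                slope=_slope_from_theta(theta),
                endpoints=endpoints,
                votes=int(votes),
                support_xy=np.column_stack([sx, sy]).astype(float),
                support_outward=np.column_stack(
                    [out_x[sy, sx], out_y[sy, sx]]
                ),
            )
        )
    if not lines:
        raise NoLinesError("no Hough peak retained any contour support")
    lines.sort(key=lambda l: (-l.votes, -l.span, abs(l.rho)))
    return lines


def _canonical_frame(
    corners: CornerSet, support_pool: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, str]:
    """Rotation into the canonical pose: limbs left-right, bend opening
    downward (outer-bend apex up, Cartesian y up).

    Orientation comes from the principal axis of the pooled supporting
    contour pixels (far more stable under boundary noise than the
    corner quadrilateral); the apex side from the sign of the pooled
    mid-axis profile's extremum; the hinge position from the corner
    bend pair, clamped to the central span and falling back to the
    profile extremum.  Returns (rotation matrix applied to Cartesian
    coordinates, Cartesian centroid of the pool, hinge x, and which
    source fixed the hinge: "corner", "profile" or "center").
    """
    pool = support_pool.astype(float).copy()
    pool[:, 1] = -pool[:, 1]  # image y -> Cartesian y
    center = pool.mean(axis=0)
    centered = pool - center
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    rot = np.array([[axis[0], axis[1]], [-axis[1], axis[0]]])  # axis -> +x
    rp = centered @ rot.T

    # mid-axis profile: mean y per x-bin; its extremum marks the bend
    # apex (above the mean on the apex side)
    nbins = max(8, int((rp[:, 0].max() - rp[:, 0].min()) / 8))
    edges = np.linspace(rp[:, 0].min(), rp[:, 0].max() + 1e-9, nbins + 1)
    idx = np.clip(np.digitize(rp[:, 0], edges) - 1, 0, nbins - 1)
    cnt = np.bincount(idx, minlength=nbins)
    mean_y = np.where(
        cnt > 0, np.bincount(idx, weights=rp[:, 1], minlength=nbins), np.nan
    ) / np.maximum(cnt, 1)
    dev = mean_y - np.nanmean(mean_y)
    ext = int(np.nanargmax(np.abs(dev)))
    if dev[ext] < 0:  # apex below axis: flip so the bend opens downward
        rot = np.array([[1.0, 0.0], [0.0, -1.0]]) @ rot
        rp = centered @ rot.T
    profile_hinge_x = float(0.5 * (edges[ext] + edges[ext + 1]))

    # hinge from the corner bend pair (the two closest corners), kept
    # only if it lies in the central span of the shaft
    cpts = corners.corners.astype(float).copy()
    cpts[:, 1] = -cpts[:, 1]
    best = None
    for i in range(4):
        for j in range(i + 1, 4):
            d = float(np.linalg.norm(cpts[i] - cpts[j]))
            if best is None or d < best[0]:
                best = (d, i, j)
    _, bi, bj = best
    bend_mid = ((cpts[bi] + cpts[bj]) / 2.0 - center) @ rot.T
    lo, hi = rp[:, 0].min(), rp[:, 0].max()
    central = lambda x: lo + 0.2 * (hi - lo) <= x <= hi - 0.2 * (hi - lo)
    hinge_x = float(bend_mid[0])
    source = "corner"
    if not central(hinge_x):
        if central(profile_hinge_x):
            hinge_x, source = profile_hinge_x, "profile"
        else:
            hinge_x, source = 0.0, "center"
    return rot, center, hinge_x, source


def select_lines(
    candidates: list[ShaftLine], corners: CornerSet
) -> tuple[ShaftLine, ShaftLine]:
    """Pick one optimal edge line from each of the two shaft limbs.

    The corner-derived canonical pose (bend opening downward, limbs
    left-right) splits the candidates by limb: in that pose the left
    limb's edges rise toward the apex (positive slope) and the right
    limb's fall (negative slope), so the sign of a candidate's
    canonical slope identifies its limb without needing a precise
    hinge position.  Within the left limb the concave (inner-bottom)
    edge is preferred, within the right limb the convex (outer-upper)
    edge — but when noise leaves only one edge of a limb above the
    vote threshold, that edge is accepted: any edge of a limb is
    parallel to its axis, so the angle is unchanged.  The optimal line
    of a limb maximizes votes, ties broken by longer supported span,
    then by smaller \\|rho\\|.  Returns (left-limb, right-limb) lines,
    the preferred pair being (inner-bottom, outer-upper).
    """
    if len(candidates) < 2:
        raise SelectionFailureError(
            f"need >= 2 candidate lines, got {len(candidates)}"
        )
    # deduplicate: contour pixels supporting several candidates must
    # weigh once, or over-represented edges skew the pose
    pool = np.unique(np.concatenate([l.support_xy for l in candidates]), axis=0)
    rot, _, _, _ = _canonical_frame(corners, pool)
    min_slope = math.tan(math.radians(2.0))
    limbs: dict[str, list[tuple[ShaftLine, bool]]] = {"left": [], "right": []}
    for line in candidates:
        d = rot @ np.array([-math.sin(line.theta), math.cos(line.theta)])
        if abs(d[0]) < 1e-9:
            continue  # perpendicular to the shaft axis: spurious
        slope_c = d[1] / d[0]
        if abs(slope_c) < min_slope:
            continue  # parallel to the axis: no limb is identifiable
        limb = "left" if slope_c > 0 else "right"
        nrm = line.support_outward @ rot.T
        n = len(nrm)
        n_down = int(np.count_nonzero(nrm[:, 1] < -0.3))
        n_up = int(np.count_nonzero(nrm[:, 1] > 0.3))
        preferred_side = (limb == "left" and n_down >= 0.5 * n) or (
            limb == "right" and n_up >= 0.5 * n
        )
        limbs[limb].append((line, preferred_side))

    # a limb's lines must be competitive with the strongest candidate:
    # on a straight shaft only weak oblique noise lines carry a slope,
    # and selection must fail over to the parallel-edge path instead
    vmax = max(l.votes for l in candidates)
    for name in ("left", "right"):
        if not limbs[name] or max(l.votes for l, _ in limbs[name]) < 0.3 * vmax:
            raise SelectionFailureError(
                f"no competitive candidate line in the {name} limb "
                f"({'inner-bottom' if name == 'left' else 'outer-upper'} region)"
            )

    def best(entries: list[tuple[ShaftLine, bool]]) -> ShaftLine:
        # prefer the region-consistent side only among competitive
        # lines: a weak spurious edge must not displace the strong one
        vbest = max(l.votes for l, _ in entries)
        pref = [l for l, ok in entries if ok and l.votes >= 0.8 * vbest]
        pool_ = pref if pref else [l for l, _ in entries]
        return min(pool_, key=lambda l: (-l.votes, -l.span, abs(l.rho)))

    return best(limbs["left"]), best(limbs["right"])


def _slope_family_pair(lines: list[ShaftLine]) -> tuple[ShaftLine, ShaftLine]:
    """Last-resort pairing: strongest line of each of the two slope families.

    Line angles (mod pi) are split at their two largest circular gaps,
    which separates the two limb directions; each family holds both
    parallel edges of one limb.  With a single family (straight shaft)
    the two strongest candidates are returned.
    """
    if len(lines) < 2:
        raise SelectionFailureError("fewer than 2 candidate lines")
    thetas = np.array([l.theta for l in lines]) % math.pi
    order = np.argsort(thetas)
    gaps = np.diff(thetas[order], append=thetas[order][0] + math.pi)
    cut_a, cut_b = np.argsort(gaps)[-2:]
    if gaps[min(cut_a, cut_b, key=lambda c: gaps[c])] < math.radians(5.0):
        # all candidates near-parallel (straight shaft): no second
        # angular family exists, take the two strongest edges
        best = sorted(lines, key=lambda l: -l.votes)
        return best[0], best[1]
    lo, hi = sorted((cut_a, cut_b))
    fam1 = [lines[i] for i in order[lo + 1 : hi + 1]]
    fam2 = [lines[i] for i in np.concatenate([order[hi + 1 :], order[: lo + 1]])]
    if not fam1 or not fam2:
        best = sorted(lines, key=lambda l: -l.votes)
        return best[0], best[1]
    pick = lambda fam: max(fam, key=lambda l: (l.votes, l.span))
    return pick(fam1), pick(fam2)


def angle_between(m1: float, m2: float) -> float:
    """Acute angle in degrees between two lines given Cartesian slopes.

    Total function: VERTICAL (infinite slope) is handled by the
    arctan(1/|m|) branch, two verticals give 0, and perpendicular
    slopes (1 + m1 m2 = 0) give 90.  Result always in [0, 90].
    """
    v1 = math.isinf(m1)
    v2 = math.isinf(m2)
    if v1 and v2:
        return 0.0
    if v1 or v2:
        m = m2 if v1 else m1
        if m == 0.0:
            return 90.0
        return math.degrees(math.atan(1.0 / abs(m)))
    denom = 1.0 + m1 * m2
    if denom == 0.0:
        return 90.0
    return math.degrees(math.atan(abs((m1 - m2) / denom)))


def estimate_curvature(
    mask: np.ndarray, median_passes: int = 1
) -> CurvatureEstimate:
    """Full measurement chain from a raw binary mask to a curvature angle.

    fill holes -> median + Gaussian smoothing -> largest component ->
    corner detection -> Hough line candidates -> per-region line
    selection -> slope-formula angle.  If line selection fails at the
    default vote threshold, the Hough threshold is relaxed once (0.3 ->
    0.15 of the limb-length estimate) before the error propagates.
    Raises :class:`PipelineStageError` naming the failing stage.
    """
    try:
        clean = postprocess_mask(mask, median_passes=median_passes)
    except EmptyMaskError as e:
        raise PipelineStageError("postprocess", e) from e

    corners = None
    try:
        corners = detect_corners(clean)
    except DegenerateShapeError:
        # near-straight shaft: no bend vertices exist; fall back to the
        # parallel-edge path below instead of failing outright
        pass
    except EmptyMaskError as e:
        raise PipelineStageError("corners", e) from e

    def _theta_spread_deg(ls: list[ShaftLine]) -> float:
        th = np.sort(np.array([l.theta for l in ls]) % math.pi)
        gaps = np.diff(th, append=th[0] + math.pi)
        return math.degrees(math.pi - gaps.max())

    relaxed = False
    try:
        lines = detect_lines(clean, threshold_factor=0.3)
    except NoLinesError:
        relaxed = True
        try:
            lines = detect_lines(clean, threshold_factor=0.15)
        except NoLinesError as e:
            raise PipelineStageError("lines", e) from e
    if not relaxed and corners is not None and _theta_spread_deg(lines) < 5.0:
        # every candidate is near-parallel although the shape has
        # corners: one limb's edges fell below the vote threshold
        try:
            wide = detect_lines(clean, threshold_factor=0.15)
        except NoLinesError:
            wide = lines
        if _theta_spread_deg(wide) >= 5.0:
            lines = wide
            relaxed = True

    selection_fallback = False
    if corners is None:
        # no corner landmarks (near-straight shaft): pair the two
        # candidate slope families directly
        try:
            lower, upper = _slope_family_pair(lines)
        except SelectionFailureError as e:
            raise PipelineStageError("select", e) from e
        selection_fallback = True
    else:
        try:
            lower, upper = select_lines(lines, corners)
        except SelectionFailureError:
            if not relaxed:
                try:
                    lines = detect_lines(clean, threshold_factor=0.15)
                except NoLinesError as e:
                    raise PipelineStageError("lines", e) from e
            try:
                lower, upper = select_lines(lines, corners)
            except SelectionFailureError:
                # corner-guided regions failed even at the relaxed vote
                # threshold; fall back to slope-family pairing
                try:
                    lower, upper = _slope_family_pair(lines)
                except SelectionFailureError as e:
                    raise PipelineStageError("select", e) from e
                selection_fallback = True

    angle = angle_between(lower.slope, upper.slope)
    return CurvatureEstimate(
        angle_deg=angle,
        line_lower=lower,
        line_upper=upper,
        corners=corners,
        diagnostics={
            "n_candidates": len(lines),
            "relaxed_threshold": relaxed,
            "corner_fallback": corners is None,
            "selection_fallback": selection_fallback,
            "lower_votes": lower.votes,
            "upper_votes": upper.votes,
        },
    )
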