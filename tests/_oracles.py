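"""Independent geometric oracles used by the test suite.

These deliberately avoid the package's measurement chain (no Hough
transform, no corner detection): the curvature oracle works purely from
principal axes of the two limb pixel sets, and the flood-fill oracle is
a brute-force breadth-first search from the image border.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy import ndimage as ndi


def principal_axis_deg(points: np.ndarray) -> float:
    """Orientation (deg, Cartesian, mod 180) of a point set's major axis."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    vx, vy = vt[0]
    return math.degrees(math.atan2(vy, vx)) % 180.0


def _acute_between_lines_deg(a1: float, a2: float) -> float:
    d = abs(a1 - a2) % 180.0
    return min(d, 180.0 - d)


def _centerline_slope(u: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Least-squares line w = a + b u through binned centerline points.

    For an oblique capsule limb every u cross-section is symmetric
    about the limb axis, so the per-bin mean of w traces the mid-axis
    exactly, immune to the rounded caps and oblique cuts that bias a
    raw principal axis of a short stub.
    """
    bins = np.round(u / 3.0).astype(int)
    bins -= bins.min()
    counts = np.bincount(bins)
    sums_u = np.bincount(bins, weights=u)
    sums_w = np.bincount(bins, weights=w)
    ok = counts > 0
    cu = sums_u[ok] / counts[ok]
    cw = sums_w[ok] / counts[ok]
    b, a = np.polyfit(cu, cw, 1)
    return a, b


def limb_axes_angle_deg(mask: np.ndarray) -> float:
    """Curvature angle from the axes of the two limb pixel sets.

    The mask is rotated into its own principal frame; the hinge is
    located as the extremum of the mid-axis profile; each limb's axis
    is initialized by centerline regression away from the hinge, then
    refined by reassigning every pixel to the nearer axis line and
    recomputing the principal axis of each limb set.  Returns the
    acute angle between the two limb axis lines, in degrees
    (0 = straight).
    """
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, -rows]).astype(float)  # Cartesian y up
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = centered @ vt[0]
    w = centered @ vt[1]

    # mid-axis profile: mean w per u-bin; hinge at its extremum
    nbins = max(8, int((u.max() - u.min()) / 4))
    bins = np.linspace(u.min(), u.max() + 1e-9, nbins + 1)
    idx = np.clip(np.digitize(u, bins) - 1, 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=w, minlength=nbins)
    valid = counts > 0
    prof = np.where(valid, sums / np.maximum(counts, 1), np.nan)
    prof_c = prof - np.nanmean(prof)
    hinge_bin = int(np.nanargmax(np.abs(prof_c)))
    hinge_u = 0.5 * (bins[hinge_bin] + bins[hinge_bin + 1])

    width = 2.0 * float(ndi.distance_transform_edt(mask).max())
    half = width / 2.0

    def limb_angle_deg(uu: np.ndarray, ww: np.ndarray) -> float:
        """Axis angle of one limb, from the hinge-free straight band.

        ``uu`` increases away from the hinge (hinge at uu ~ 0).  The cap
        clips the band's far edge from u_end - (w/2) sin(theta) on, so
        the usable window end depends on the slope itself: refine it
        iteratively from an initial conservative fit.
        """
        lo = half + 2.0
        theta = 0.0
        b = 0.0
        for _ in range(3):
            end_u = uu.max() - half * (1.0 + math.sin(abs(theta))) - 2.0
            end_u = max(end_u, lo + 15.0)
            sel = (uu > lo) & (uu < end_u)
            _, b = _centerline_slope(uu[sel], ww[sel])
            theta = math.atan(b)
        return math.degrees(theta)

    right = u - hinge_u
    left = hinge_u - u  # mirrored so the hinge is at 0 for both limbs
    if (right > half + 17).sum() < 30 or (left > half + 17).sum() < 30:
        hinge_u = 0.0
        right = u
        left = -u
    a_right = limb_angle_deg(right[right > 0], w[right > 0])
    a_left = -limb_angle_deg(left[left > 0], w[left > 0])  # un-mirror
    return _acute_between_lines_deg(a_right % 180.0, a_left % 180.0)


def border_flood_fill(mask: np.ndarray) -> np.ndarray:
    """Brute-force hole filling: BFS background from the border (4-conn).

    Any False pixel not reached from the border is a hole and becomes
    True.  Used as the independent oracle for ``fill_holes``.
    """
    h, w = mask.shape
    reached = np.zeros_like(mask, dtype=bool)
    q: deque[tuple[int, int]] = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not reached[r, c]:
                reached[r, c] = True
                q.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not reached[r, c]:
                reached[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not reached[rr, cc]:
                reached[rr, cc] = True
                q.append((rr, cc))
    return mask | ~reached


def brute_force_hough(points_rc: np.ndarray, shape: tuple[int, int]):
    """Tiny brute-force (rho, theta) Hough accumulator (1 px, 1 deg).

    Returns (accumulator, thetas_rad, rhos) in image coordinates, for
    cross-checking peak families on small fixtures.
    """
    thetas = np.deg2rad(np.arange(-90.0, 90.0, 1.0))
    diag = int(np.ceil(np.hypot(*shape)))
    rhos = np.arange(-diag, diag + 1)
    acc = np.zeros((len(rhos), len(thetas)), dtype=int)
    for r, c in points_rc:
        rho_vals = c * np.cos(thetas) + r * np.sin(thetas)
        ridx = np.round(rho_vals).astype(int) + diag
        acc[ridx, np.arange(len(thetas))] += 1
    return acc, thetas, rhos
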