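"""Independent brute-force oracles used to cross-check the metric geometry.

Everything here is deliberately written from first principles (gift-wrapping
hull, hand-rolled marching squares, all-pairs distances) so it shares no code
path with the package implementations it validates.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter


def diamond_points(mask: np.ndarray) -> np.ndarray:
    """Pixel-center +/- half-step offsets of all true pixels (the point set
    underlying pixel-square convex-hull accounting)."""
    ii, jj = np.nonzero(mask)
    pts = []
    for di, dj in ((0.5, 0.0), (-0.5, 0.0), (0.0, 0.5), (0.0, -0.5)):
        pts.append(np.stack([ii + di, jj + dj], axis=1))
    return np.unique(np.concatenate(pts), axis=0)


def _prefilter_extremes(pts: np.ndarray) -> np.ndarray:
    """Keep only per-row/per-column extreme points (a superset of the hull
    vertices: any point strictly between two same-row points is a convex
    combination of them)."""
    keep = []
    for axis in (0, 1):
        other = 1 - axis
        for v in np.unique(pts[:, axis]):
            sel = pts[pts[:, axis] == v]
            keep.append(sel[np.argmin(sel[:, other])])
            keep.append(sel[np.argmax(sel[:, other])])
    return np.unique(np.asarray(keep), axis=0)


def brute_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull polygon (CCW) by exhaustive gift wrapping.

    At each step every candidate point is examined against every other via
    cross products; the result is verified by checking that all input points
    lie inside or on the polygon.
    """
    pts = _prefilter_extremes(np.unique(np.asarray(points, dtype=float), axis=0))
    n = len(pts)
    if n <= 2:
        return pts
    def _cross2(u, v):
        return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]

    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    hull = [start]
    current = start
    while True:
        candidate = (current + 1) % n
        for j in range(n):
            if j == current:
                continue
            cross = _cross2(pts[candidate] - pts[current], pts[j] - pts[current])
            if cross < -1e-12 or (
                abs(cross) <= 1e-12
                and np.linalg.norm(pts[j] - pts[current])
                > np.linalg.norm(pts[candidate] - pts[current])
            ):
                candidate = j
        current = candidate
        if current == start:
            break
        hull.append(current)
        if len(hull) > n:  # pragma: no cover - cycle guard
            raise RuntimeError("gift wrapping failed to terminate")
    poly = pts[hull]
    # O(n^3)-style verification: every point on the inner side of every edge
    for k in range(len(poly)):
        a, b = poly[k], poly[(k + 1) % len(poly)]
        cross = _cross2(b - a, pts - a)
        assert (cross >= -1e-9).all(), "point outside brute-force hull"
    return poly


def shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def points_in_polygon(poly: np.ndarray, shape: tuple, eps: float = 1e-9) -> np.ndarray:
    """Ray-casting test of every pixel center against a polygon; boundary
    pixels (within ``eps`` of an edge) count as inside."""
    ii, jj = np.mgrid[: shape[0], : shape[1]]
    px = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
    inside = np.zeros(len(px), dtype=bool)
    on_edge = np.zeros(len(px), dtype=bool)
    n = len(poly)
    for k in range(n):
        a, b = poly[k], poly[(k + 1) % n]
        # crossing test on the j (x) axis with i (y) as the ray direction
        cond = (a[0] > px[:, 0]) != (b[0] > px[:, 0])
        denom = b[0] - a[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = a[1] + (px[:, 0] - a[0]) * (b[1] - a[1]) / denom
        inside ^= cond & (px[:, 1] < x_cross)
        # boundary proximity
        ab = b - a
        t = np.clip(((px - a) @ ab) / max(ab @ ab, 1e-30), 0.0, 1.0)
        d = np.linalg.norm(px - (a + t[:, None] * ab), axis=1)
        on_edge |= d <= eps
    return (inside | on_edge).reshape(shape)


def convex_area_oracle(mask: np.ndarray) -> float:
    """Pixel count of the rasterized brute-force hull of the diamond points."""
    poly = brute_hull(diamond_points(mask))
    if len(poly) < 3:
        return float(np.count_nonzero(mask))
    return float(points_in_polygon(poly, mask.shape).sum())


def solidity_oracle(mask: np.ndarray) -> float:
    return float(np.count_nonzero(mask)) / convex_area_oracle(mask)


_EDGE_LUT = {
    # case index (b0=top-left, b1=top-right, b2=bottom-right, b3=bottom-left)
    # -> list of (edge_in, edge_out) pairs; edges 0=top,1=right,2=bottom,3=left
    1: [(3, 0)], 2: [(0, 1)], 3: [(3, 1)], 4: [(1, 2)],
    6: [(0, 2)], 7: [(3, 2)], 8: [(2, 3)], 9: [(2, 0)],
    11: [(2, 1)], 12: [(1, 3)], 13: [(1, 0)], 14: [(0, 3)],
}


def _edge_point(i, j, edge, f, level):
    """Sub-pixel crossing point on one cell edge by linear interpolation."""
    if edge == 0:
        a, b = f[i, j], f[i, j + 1]
        t = (level - a) / (b - a)
        return (i, j + t)
    if edge == 1:
        a, b = f[i, j + 1], f[i + 1, j + 1]
        t = (level - a) / (b - a)
        return (i + t, j + 1)
    if edge == 2:
        a, b = f[i + 1, j], f[i + 1, j + 1]
        t = (level - a) / (b - a)
        return (i + 1, j + t)
    a, b = f[i, j], f[i + 1, j]
    t = (level - a) / (b - a)
    return (i + t, j)


def traced_contour_length(mask: np.ndarray, sigma_px: float = 1.0,
                          level: float = 0.5) -> float:
    """Total polygon length of all iso-contours of the smoothed mask,
    accumulated cell by cell with a hand-rolled marching-squares pass."""
    f = np.pad(np.asarray(mask, dtype=np.float64), 3)
    if sigma_px > 0:
        f = gaussian_filter(f, sigma_px)
    total = 0.0
    ni, nj = f.shape
    for i in range(ni - 1):
        for j in range(nj - 1):
            b0 = f[i, j] > level
            b1 = f[i, j + 1] > level
            b2 = f[i + 1, j + 1] > level
            b3 = f[i + 1, j] > level
            case = (b0 << 0) | (b1 << 1) | (b2 << 2) | (b3 << 3)
            if case in (0, 15):
                continue
            if case in (5, 10):
                # saddle: resolve with the cell-center average, as the
                # standard sub-pixel tracer does
                center_high = (f[i, j] + f[i, j + 1] + f[i + 1, j] + f[i + 1, j + 1]) / 4.0 > level
                if case == 5:
                    pairs = [(3, 0), (1, 2)] if center_high else [(3, 2), (1, 0)]
                else:
                    pairs = [(0, 1), (2, 3)] if center_high else [(0, 3), (2, 1)]
            else:
                pairs = _EDGE_LUT[case]
            for e_in, e_out in pairs:
                p = _edge_point(i, j, e_in, f, level)
                q = _edge_point(i, j, e_out, f, level)
                total += float(np.hypot(p[0] - q[0], p[1] - q[1]))
    return total


def circularity_oracle(mask: np.ndarray) -> float:
    area = float(np.count_nonzero(mask))
    perim = traced_contour_length(mask)
    return 4.0 * np.pi * area / perim ** 2


def min_thickness_oracle(label_slice: np.ndarray, pixel_spacing_mm: float,
                         inner_labels=(2, 3), background_label=0) -> float:
    """All-pairs minimum distance from inner-boundary pixels to background."""
    lab = np.asarray(label_slice)
    inner = np.isin(lab, inner_labels)
    background = lab == background_label
    if not inner.any() or not background.any():
        return float("nan")
    bi = np.stack(np.nonzero(inner), axis=1)
    bg = np.stack(np.nonzero(background), axis=1)
    # touching (8-adjacent) means perforation
    d2 = (
        (bi[:, None, 0] - bg[None, :, 0]) ** 2
        + (bi[:, None, 1] - bg[None, :, 1]) ** 2
    )
    dmin = np.sqrt(d2.min())
    if dmin <= np.sqrt(2.0) + 1e-9:
        return 0.0
    # restrict to boundary pixels of the inner region
    boundary = []
    ni, nj = lab.shape
    inner_set = inner
    for (i, j) in bi:
        nb = inner_set[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2]
        if nb.size < 9 or not nb.all():
            boundary.append((i, j))
    bd = np.asarray(boundary)
    d2b = (
        (bd[:, None, 0] - bg[None, :, 0]) ** 2
        + (bd[:, None, 1] - bg[None, :, 1]) ** 2
    )
    return float(np.sqrt(d2b.min())) * pixel_spacing_mm


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t statistic and two-tailed p."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * tdist.sf(abs(t_stat), na + nb - 2)
    return t_stat, p
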