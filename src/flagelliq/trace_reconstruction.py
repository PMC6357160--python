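"""Rough per-frame flagellar trace: blur → threshold → skeletonize → order.

Each frame is Gaussian-blurred, binarized with a histogram threshold
(Li, Triangle or Otsu on a 256-bin histogram, matching the 8-bit histogram
semantics those algorithms were published on), optionally blurred again and
re-binarized, thinned to a 1-px skeleton, and reduced to a single ordered,
head-first point list. Points are (x, y) pixel coordinates, x = column,
y = row, pixel centres at integers.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize as _sk_skeletonize

from flagelliq.imaging_io import RoiMask
from flagelliq.settings import Settings

HEAD_DISK_RADIUS_PX = 8.0  # radius of the circular head/tip intensity ROI


# ---------------------------------------------------------------------------
# blurring and thresholding
# ---------------------------------------------------------------------------

def gaussian_blur(
    frame: np.ndarray,
    sigma: float,
    roi: RoiMask | None = None,
    only_inside_roi: bool = False,
) -> np.ndarray:
    """Isotropic Gaussian smoothing; optionally applied only inside the ROI.

    When restricted, pixels outside the ROI keep their original values; this
    lets a user blur the bright head strongly without washing out the thin
    flagellum elsewhere.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    blurred = ndi.gaussian_filter(np.asarray(frame, dtype=np.float64), sigma)
    if roi is not None and only_inside_roi:
        out = np.asarray(frame, dtype=np.float64).copy()
        out[roi.mask] = blurred[roi.mask]
        return out
    return blurred


def _histogram_256(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram spanning the frame's min–max; returns (counts, centers)."""
    lo, hi = float(frame.min()), float(frame.max())
    counts, edges = np.histogram(frame, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(np.float64), centers


def _otsu_bin(counts: np.ndarray) -> int:
    """Threshold bin maximizing between-class variance (foreground = bins above)."""
    n = counts.sum()
    idx = np.arange(counts.size)
    w0 = np.cumsum(counts)
    m0 = np.cumsum(counts * idx)
    total_mean = m0[-1] / n
    w0n = w0 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / (n - w0)
        var_between = w0n * (1 - w0n) * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=-np.inf)
    return int(np.argmax(var_between))


def _li_bin(counts: np.ndarray, centers: np.ndarray) -> int:
    """Threshold bin minimizing Li's cross-entropy, by scan over all bins.

    The criterion for cutting after bin t is
    ``-(m0(t)·µ0·log µ0 + m1(t)·µ1·log µ1)`` up to terms independent of t,
    where µ0/µ1 are the mean intensities below/above the cut; minimizing it
    over every candidate bin is exact on the binned histogram.
    """
    g = centers - centers.min()
    g = g + max(g.max(), 1.0) / 256.0  # keep log argument positive
    w = counts
    cw = np.cumsum(w)
    cm = np.cumsum(w * g)
    best_t, best_val = 0, np.inf
    for t in range(counts.size - 1):
        w0, w1 = cw[t], cw[-1] - cw[t]
        if w0 <= 0 or w1 <= 0:
            continue
        mu0, mu1 = cm[t] / w0, (cm[-1] - cm[t]) / w1
        val = -(cm[t] * np.log(mu0) + (cm[-1] - cm[t]) * np.log(mu1))
        if val < best_val:
            best_val, best_t = val, t
    return best_t


def _triangle_bin(counts: np.ndarray) -> int:
    """Threshold bin by the triangle geometric construction.

    A line is drawn from the histogram peak to the far end of the non-empty
    histogram range on the longer tail side; the threshold is the bin whose
    histogram point lies furthest from that line.
    """
    nz = np.nonzero(counts)[0]
    first, last = nz[0], nz[-1]
    peak = int(np.argmax(counts))
    # longer tail decides direction; mirror so the tail is to the right
    if peak - first > last - peak:
        counts = counts[::-1]
        peak = counts.size - 1 - peak
        last = counts.size - 1 - first
        flipped = True
    else:
        flipped = False
    # line from (peak, h[peak]) to (last, h[last])
    x = np.arange(peak, last + 1, dtype=float)
    y = counts[peak : last + 1].astype(float)
    dx, dy = last - peak, counts[last] - counts[peak]
    norm = np.hypot(dx, dy)
    if norm == 0:
        t = peak
    else:
        # perpendicular distance of each histogram point from the line
        dist = np.abs(dy * (x - peak) - dx * (y - counts[peak])) / norm
        t = peak + int(np.argmax(dist))
    if flipped:
        t = counts.size - 1 - t
    return int(t)


def auto_threshold(
    frame: np.ndarray, method: str, roi: RoiMask | None = None
) -> np.ndarray:
    """Global histogram threshold; returns the boolean foreground mask.

    The threshold is computed on a 256-bin histogram spanning the frame's
    min–max range; pixels strictly above the threshold value are foreground.
    If a ROI is given, foreground outside it is cleared (the flagellum is
    only searched inside the ROI).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.max() == frame.min():
        raise ValueError("no threshold exists for a constant frame")
    counts, centers = _histogram_256(frame)
    if method == "otsu":
        t = _otsu_bin(counts)
    elif method == "li":
        t = _li_bin(counts, centers)
    elif method == "triangle":
        t = _triangle_bin(counts)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = frame > centers[t]
    if roi is not None:
        mask &= roi.mask
    return mask


# ---------------------------------------------------------------------------
# skeletonization and path extraction
# ---------------------------------------------------------------------------

def skeletonize(binary: np.ndarray) -> np.ndarray:
    """1-px-wide 8-connected medial-axis skeleton by iterative thinning."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError("no object found")
    return _sk_skeletonize(binary)


def _skeleton_graph(points: np.ndarray):
    """Sparse 8-connected pixel graph with Euclidean step weights."""
    index = {tuple(p): i for i, p in enumerate(points)}
    rows, cols, weights = [], [], []
    for i, (r, c) in enumerate(points):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    w = np.hypot(dr, dc)
                    rows.append(i)
                    cols.append(j)
                    weights.append(w)
    n = len(points)
    g = coo_matrix((weights, (rows, cols)), shape=(n, n))
    return (g + g.T).tocsr()


def extract_skeleton_path(skeleton: np.ndarray) -> np.ndarray:
    """Single ordered pixel path through the skeleton, as (n, 2) x/y array.

    Branch resolution: keep the largest connected component, then the longest
    endpoint-to-endpoint path (Dijkstra on the 8-connected pixel graph with
    Euclidean step weights); side branches are discarded. A closed loop
    (no endpoints) is rejected.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        raise ValueError("no object found")
    labels, n_labels = ndi.label(skeleton, structure=np.ones((3, 3), dtype=int))
    if n_labels > 1:
        sizes = ndi.sum_labels(skeleton, labels, index=np.arange(1, n_labels + 1))
        keep = 1 + int(np.argmax(sizes))
        skeleton = labels == keep
    rc = np.argwhere(skeleton)  # (row, col)
    if rc.shape[0] == 1:
        return rc[:, ::-1].astype(float)
    graph = _skeleton_graph(rc)
    degrees = np.asarray((graph > 0).sum(axis=1)).ravel()
    endpoints = np.nonzero(degrees == 1)[0]
    if endpoints.size == 0:
        raise ValueError("cyclic skeleton: no endpoints found")
    dist, predecessors = dijkstra(
        graph, indices=endpoints, return_predecessors=True
    )
    finite = np.where(np.isfinite(dist), dist, -np.inf)
    src_i, dst = np.unravel_index(np.argmax(finite), finite.shape)
    # walk predecessors back from dst to endpoints[src_i]
    path = [int(dst)]
    while predecessors[src_i, path[-1]] >= 0:
        path.append(int(predecessors[src_i, path[-1]]))
    path_rc = rc[path[::-1]]
    return path_rc[:, ::-1].astype(float)  # (x, y)


# ---------------------------------------------------------------------------
# ordering, orientation, start-point policy, upscaling
# ---------------------------------------------------------------------------

def _path_length(points: np.ndarray, order: np.ndarray) -> float:
    p = points[order]
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def _held_karp_path(points: np.ndarray) -> np.ndarray:
    """Exact minimum-length Hamiltonian path by dynamic programming (n <= 12)."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    full = 1 << n
    cost = np.full((full, n), np.inf)
    parent = np.full((full, n), -1, dtype=int)
    for i in range(n):
        cost[1 << i, i] = 0.0
    for mask in range(full):
        for last in range(n):
            c = cost[mask, last]
            if not np.isfinite(c):
                continue
            for nxt in range(n):
                if mask & (1 << nxt):
                    continue
                nm = mask | (1 << nxt)
                nc = c + d[last, nxt]
                if nc < cost[nm, nxt]:
                    cost[nm, nxt] = nc
                    parent[nm, nxt] = last
    mask = full - 1
    last = int(np.argmin(cost[mask]))
    order = [last]
    while parent[mask, last] >= 0:
        prev = parent[mask, last]
        mask ^= 1 << last
        last = int(prev)
        order.append(last)
    return np.array(order[::-1], dtype=int)


def _nearest_neighbor_chain(d: np.ndarray, start: int) -> np.ndarray:
    n = d.shape[0]
    visited = np.zeros(n, dtype=bool)
    order = [start]
    visited[start] = True
    cur = start
    for _ in range(n - 1):
        row = np.where(visited, np.inf, d[cur])
        cur = int(np.argmin(row))
        visited[cur] = True
        order.append(cur)
    return np.array(order, dtype=int)


def sort_point_list(points: np.ndarray) -> np.ndarray:
    """Order points so the summed consecutive Euclidean distance is minimal.

    Small lists (n <= 12) are solved exactly by dynamic programming; larger
    lists — in practice near-1-D skeleton pixel sets that usually arrive
    already ordered — use nearest-neighbour chaining from candidate end
    points, keeping the shortest of the chains and the input order.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        return points.copy()
    if n <= 12:
        order = _held_karp_path(points)
        return points[order]
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    centroid = points.mean(axis=0)
    far1 = int(np.argmax(np.linalg.norm(points - centroid, axis=1)))
    far2 = int(np.argmax(d[far1]))
    candidates = {0, n - 1, far1, far2}
    best_order = np.arange(n)
    best_len = _path_length(points, best_order)
    for start in candidates:
        order = _nearest_neighbor_chain(d, start)
        length = _path_length(points, order)
        if length < best_len:
            best_len, best_order = length, order
    return points[best_order]


def _disk_mean(frame: np.ndarray, center_xy: np.ndarray, radius: float) -> float:
    """Mean intensity of pixels within `radius` of the (x, y) centre."""
    h, w = frame.shape
    cx, cy = center_xy
    x0, x1 = max(0, int(np.floor(cx - radius))), min(w - 1, int(np.ceil(cx + radius)))
    y0, y1 = max(0, int(np.floor(cy - radius))), min(h - 1, int(np.ceil(cy + radius)))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    if not inside.any():
        return float(frame[int(round(cy)), int(round(cx))])
    return float(frame[y0 : y1 + 1, x0 : x1 + 1][inside].mean())


def orient_head_first(
    points: np.ndarray, frame: np.ndarray, roi_radius: float = HEAD_DISK_RADIUS_PX
) -> np.ndarray:
    """Put the head end first: dark-field images are brightest at the head.

    Mean intensities in circular disks around the two ends are compared and
    the list is inverted iff the first end is dimmer. Equal means keep the
    current order (deterministic tie-break).
    """
    points = np.asarray(points, dtype=float)
    first = _disk_mean(frame, points[0], roi_radius)
    last = _disk_mean(frame, points[-1], roi_radius)
    if first < last:
        return points[::-1].copy()
    return points


def _disk_com(frame: np.ndarray, center_xy: np.ndarray, radius: float) -> np.ndarray:
    """Intensity-weighted centroid of the disk around the (x, y) centre."""
    h, w = frame.shape
    cx, cy = center_xy
    x0, x1 = max(0, int(np.floor(cx - radius))), min(w - 1, int(np.ceil(cx + radius)))
    y0, y1 = max(0, int(np.floor(cy - radius))), min(h - 1, int(np.ceil(cy + radius)))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    weights = frame[y0 : y1 + 1, x0 : x1 + 1] * inside
    total = weights.sum()
    if total <= 0:
        return np.asarray(center_xy, dtype=float)
    return np.array([(weights * xs).sum() / total, (weights * ys).sum() / total])


def apply_start_point_policy(
    points: np.ndarray,
    frame: np.ndarray,
    settings: Settings,
    all_frame_starts: np.ndarray | None = None,
) -> np.ndarray:
    """Optionally prepend the head centre of mass and/or unify start points.

    The head-COM point (flag F) is prepended first; unification (flag G,
    a second pass over the whole movie) then replaces the first point with
    the across-frames mean start position.
    """
    points = np.asarray(points, dtype=float)
    if settings.add_head_com_first_point:
        com = _disk_com(frame, points[0], HEAD_DISK_RADIUS_PX)
        if np.linalg.norm(com - points[0]) > 1e-12:
            points = np.vstack([com, points])
    if settings.unify_start_points and all_frame_starts is not None:
        mean_start = np.asarray(all_frame_starts, dtype=float).mean(axis=0)
        points = points.copy()
        points[0] = mean_start
    return points


def upscale_point_list(points: np.ndarray, fold: int) -> np.ndarray:
    """Insert ``fold - 1`` equidistant points between each consecutive pair.

    Output length is ``fold * n - (fold - 1)``; endpoints and total polyline
    length are preserved exactly.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    points = np.asarray(points, dtype=float)
    if fold == 1 or len(points) < 2:
        return points.copy()
    frac = np.arange(fold) / fold
    segs = points[:-1, None, :] + frac[None, :, None] * (
        points[1:, None, :] - points[:-1, None, :]
    )
    return np.vstack([segs.reshape(-1, 2), points[-1]])


# ---------------------------------------------------------------------------
# full rough-trace chain
# ---------------------------------------------------------------------------

def rough_trace(
    frame: np.ndarray,
    settings: Settings,
    roi: RoiMask | None = None,
) -> np.ndarray:
    """Full rough reconstruction of one frame: ordered head-first point list.

    blur → threshold → (optional re-blur of the binary mask, re-binarized at
    0.5) → skeletonize → longest-path extraction → minimal-length ordering →
    head-first orientation → start-point policy (head COM) → linear upscaling.
    """
    blurred = gaussian_blur(
        frame, settings.gauss_sigma, roi, settings.blur_only_inside_roi
    )
    binary = auto_threshold(blurred, settings.threshold_method, roi)
    if settings.repeat_gauss_after_binarization:
        binary = ndi.gaussian_filter(binary.astype(float), settings.gauss_sigma) > 0.5
        if not binary.any():
            raise ValueError("no object found after re-binarization")
    skeleton = skeletonize(binary)
    points = extract_skeleton_path(skeleton)
    points = sort_point_list(points)
    points = orient_head_first(points, frame)
    points = apply_start_point_policy(points, frame, settings)
    return upscale_point_list(points, settings.upscaling_fold)
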