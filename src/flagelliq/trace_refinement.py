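"""Sub-pixel refinement of the rough trace.

At every rough-trace point a line normal to the local tangent is laid
through the image, the intensity profile along the line is sampled at 1-px
steps by bilinear interpolation and fitted to a Gaussian with baseline,
``y = baseline + a·exp(-(x-c)²/(2d²))``. The fitted centre ``c`` shifts the
point onto the true ridge of the flagellum; the width ``d`` serves as the
uncalibrated relative-z proxy (defocused segments image wider) and the
height ``a`` as the local intensity.

A fit is accepted only if all four criteria hold:

* ``r² > 0.8``
* ``a > 0``
* ``d < 2 × normal radius``
* ``|c| < normal radius``

The full refinement runs two passes: fit/centre/outlier removal, then
median-projection xy smoothing, arc lengths, renewed outlier removal,
renewed tangents and fits, optional criteria-based point filtering, and
arc-length-restricted smoothing of the widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from flagelliq.settings import Settings
from flagelliq.trace import FlagellarTrace
from flagelliq.trace_reconstruction import HEAD_DISK_RADIUS_PX

MIN_PROFILE_SAMPLES = 5


@dataclass
class GaussFit:
    """Result of one normal-profile Gaussian fit."""

    a: float
    c: float
    d: float
    r2: float
    baseline: float
    accepted: bool


# ---------------------------------------------------------------------------
# tangents and normals
# ---------------------------------------------------------------------------

def compute_tangents_normals(
    points: np.ndarray, max_vector_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point unit tangents and normals from symmetric finite differences.

    The tangent at point i is the unit vector from point ``i-k`` to ``i+k``
    with ``k = max_vector_length // 2``; near the ends the support indices
    are clamped into range (one-sided at the very ends). The normal is the
    tangent rotated by +90°, ``n = (-t_y, t_x)``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    k = max(1, max_vector_length // 2)
    lo = np.clip(np.arange(n) - k, 0, n - 1)
    hi = np.clip(np.arange(n) + k, 0, n - 1)
    vec = points[hi] - points[lo]
    norms = np.linalg.norm(vec, axis=1)
    # coincident support points: widen to the nearest distinct neighbours
    for i in np.nonzero(norms == 0)[0]:
        a, b = lo[i], hi[i]
        while a > 0 or b < n - 1:
            a, b = max(a - 1, 0), min(b + 1, n - 1)
            v = points[b] - points[a]
            if np.linalg.norm(v) > 0:
                vec[i] = v
                norms[i] = np.linalg.norm(v)
                break
        else:  # pragma: no cover - all points coincident
            vec[i] = (1.0, 0.0)
            norms[i] = 1.0
    norms[norms == 0] = 1.0
    tangents = vec / norms[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return tangents, normals


# ---------------------------------------------------------------------------
# normal-profile sampling
# ---------------------------------------------------------------------------

def bilinear_sample(frame: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the frame at floating (x, y) positions.

    Each value is interpolated from the four surrounding pixels weighted by
    distance; positions outside the frame return NaN.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    h, w = frame.shape
    x, y = xy[:, 0], xy[:, 1]
    valid = (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    out = np.full(xy.shape[0], np.nan)
    if valid.any():
        xv, yv = x[valid], y[valid]
        x0 = np.clip(np.floor(xv).astype(int), 0, w - 2)
        y0 = np.clip(np.floor(yv).astype(int), 0, h - 2)
        fx, fy = xv - x0, yv - y0
        out[valid] = (
            frame[y0, x0] * (1 - fx) * (1 - fy)
            + frame[y0, x0 + 1] * fx * (1 - fy)
            + frame[y0 + 1, x0] * (1 - fx) * fy
            + frame[y0 + 1, x0 + 1] * fx * fy
        )
    return out


def sample_normal_profile(
    frame: np.ndarray,
    point: np.ndarray,
    normal: np.ndarray,
    normal_radius_um: float,
    pixel_size: float,
    smooth: bool = False,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Intensity profile along the normal line through a point.

    Samples at signed offsets ``j`` px for ``j = -R…+R`` with
    ``R = round(normal_radius_um / pixel_size)``; each sample is bilinearly
    interpolated. Samples falling outside the frame truncate the profile
    (the returned flag marks truncation). With ``smooth``, a 3-tap moving
    average is applied before fitting.

    Returns ``(offsets_px, values, truncated)``.
    """
    radius_px = int(round(normal_radius_um / pixel_size))
    offsets = np.arange(-radius_px, radius_px + 1, dtype=float)
    xy = np.asarray(point, dtype=float)[None, :] + offsets[:, None] * np.asarray(
        normal, dtype=float
    )[None, :]
    values = bilinear_sample(frame, xy)
    keep = ~np.isnan(values)
    truncated = not keep.all()
    offsets, values = offsets[keep], values[keep]
    if smooth and values.size >= 3:
        padded = np.concatenate([values[:1], values, values[-1:]])
        values = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    return offsets, values, truncated


# ---------------------------------------------------------------------------
# batched Gaussian fitting (Levenberg–Marquardt)
# ---------------------------------------------------------------------------

def _model(offsets: np.ndarray, p: np.ndarray) -> np.ndarray:
    b, a, c, d = p[..., 0:1], p[..., 1:2], p[..., 2:3], p[..., 3:4]
    return b + a * np.exp(-((offsets - c) ** 2) / (2 * d**2))


def fit_gaussian_profiles(
    offsets: np.ndarray,
    values: np.ndarray,
    mask: np.ndarray,
    normal_radius_px: float,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares Gaussian-with-baseline fit of many profiles at once.

    ``offsets``/``values`` are ``(n_profiles, n_samples)``; ``mask`` marks
    valid samples (truncated profiles are padded). A batched
    Levenberg–Marquardt iteration (damped normal equations, iteration cap
    ``max_iter``) minimizes the masked squared residual of
    ``baseline + a·exp(-(x-c)²/(2d²))``.

    Initialization: baseline = profile minimum, a = max - min, c = offset of
    the maximum, d = half the normal radius.

    Returns ``(params (n,4) as [baseline, a, c, d], r2 (n,), accepted (n,))``.
    The width is reported positive. Acceptance applies the four criteria and
    additionally requires convergence to finite parameters and at least
    ``MIN_PROFILE_SAMPLES`` valid samples.
    """
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = values.shape[0]
    wm = mask.astype(float)
    counts = wm.sum(axis=1)
    safe = np.where(mask, values, np.nan)

    with np.errstate(invalid="ignore"):
        vmin = np.nanmin(np.where(mask, values, np.inf), axis=1)
        vmax = np.nanmax(np.where(mask, values, -np.inf), axis=1)
    vmin = np.where(np.isfinite(vmin), vmin, 0.0)
    vmax = np.where(np.isfinite(vmax), vmax, 0.0)
    argmax = np.nanargmax(np.where(mask, values, -np.inf), axis=1)
    params = np.column_stack(
        [
            vmin,
            vmax - vmin,
            offsets[np.arange(n), argmax],
            np.full(n, max(normal_radius_px / 2.0, 0.5)),
        ]
    )

    def cost(p: np.ndarray) -> np.ndarray:
        r = (values - _model(offsets, p)) * wm
        return (r**2).sum(axis=1)

    lam = np.full(n, 1e-3)
    cur_cost = cost(params)
    active = counts >= MIN_PROFILE_SAMPLES
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        todo = active & ~converged
        if not todo.any():
            break
        b, a, c, d = (params[:, i] for i in range(4))
        d_safe = np.where(np.abs(d) < 1e-3, 1e-3, d)
        u = offsets - c[:, None]
        e = np.exp(-(u**2) / (2 * d_safe[:, None] ** 2))
        f = b[:, None] + a[:, None] * e
        r = (values - f) * wm
        # Jacobian columns: d f / d(b, a, c, d)
        jb = wm
        ja = e * wm
        jc = a[:, None] * e * u / d_safe[:, None] ** 2 * wm
        jd = a[:, None] * e * u**2 / d_safe[:, None] ** 3 * wm
        J = np.stack([jb, ja, jc, jd], axis=2)  # (n, m, 4)
        JTJ = np.einsum("nmi,nmj->nij", J, J)
        JTr = np.einsum("nmi,nm->ni", J, r)
        diag = np.einsum("nii->ni", JTJ)
        damped = JTJ + lam[:, None, None] * np.eye(4) * np.maximum(
            diag[:, None, :], 1e-12
        )
        try:
            delta = np.linalg.solve(damped, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            delta = np.zeros_like(params)
        trial = params + delta
        trial_cost = cost(trial)
        improved = todo & (trial_cost < cur_cost) & np.isfinite(trial_cost)
        params = np.where(improved[:, None], trial, params)
        lam = np.where(improved, lam / 3.0, np.where(todo, lam * 5.0, lam))
        step = np.linalg.norm(delta, axis=1)
        converged |= improved & (
            (cur_cost - trial_cost) <= 1e-12 * np.maximum(cur_cost, 1e-12)
        )
        converged |= todo & (step < 1e-10)
        converged |= todo & (lam > 1e12)
        cur_cost = np.where(improved, trial_cost, cur_cost)

    params[:, 3] = np.abs(params[:, 3])
    mean = np.where(counts > 0, np.nansum(safe, axis=1) / np.maximum(counts, 1), 0.0)
    ss_tot = np.nansum((safe - mean[:, None]) ** 2, axis=1)
    ss_res = cur_cost
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)

    a, c, d = params[:, 1], params[:, 2], params[:, 3]
    accepted = (
        active
        & np.isfinite(params).all(axis=1)
        & (r2 > 0.8)
        & (a > 0)
        & (d < 2 * normal_radius_px)
        & (np.abs(c) < normal_radius_px)
    )
    return params, r2, accepted


def fit_gaussian_profile(
    offsets: np.ndarray, values: np.ndarray, normal_radius_px: float
) -> GaussFit:
    """Fit a single normal-line intensity profile; see :func:`fit_gaussian_profiles`."""
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size < MIN_PROFILE_SAMPLES:
        return GaussFit(np.nan, np.nan, np.nan, 0.0, np.nan, False)
    params, r2, accepted = fit_gaussian_profiles(
        offsets[None, :], values[None, :], np.ones((1, values.size), bool),
        normal_radius_px,
    )
    b, a, c, d = params[0]
    return GaussFit(a, c, d, float(r2[0]), b, bool(accepted[0]))


# ---------------------------------------------------------------------------
# centring, outlier removal, smoothing, arc lengths
# ---------------------------------------------------------------------------

def center_correct(
    points: np.ndarray,
    normals: np.ndarray,
    centers: np.ndarray,
    accepted: np.ndarray,
    head_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Shift each accepted point by ``c·n`` onto the fitted profile centre.

    Points with rejected fits stay in place; points flagged as head points
    are exempt from correction.
    """
    shift = np.where(accepted[:, None], centers[:, None], 0.0)
    if head_mask is not None:
        shift = np.where(head_mask[:, None], 0.0, shift)
    return points + np.nan_to_num(shift) * normals


def remove_outliers(points: np.ndarray) -> np.ndarray:
    """Boolean keep-mask from the triplet rule.

    An interior point is dropped when its distance to the previous point
    strictly exceeds its distance to the next point (a symptom of a stray
    detection pulled off the curve); endpoints are never dropped. One sweep
    over the current list, all violations marked simultaneously.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    keep = np.ones(n, dtype=bool)
    if n < 3:
        return keep
    gaps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep[1:-1] = ~(gaps[:-1] > gaps[1:])
    return keep


def _project_to_line(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.dot(p - a, ab) / np.dot(ab, ab)
    return a + t * ab


def smooth_xy(points: np.ndarray, neighbor_count: int) -> np.ndarray:
    """Median-projection smoothing of the point list.

    For each point, up to ``neighbor_count`` upstream and downstream points
    (excluding the point itself, fewer at the ends) are paired in all
    combinations; the point is orthogonally projected onto the line through
    every pair, and replaced by the projection whose displacement is nearest
    to the median displacement (lower median for even counts; ties resolved
    to the lowest pair index). The median, rather than the mean, keeps
    individual off-curve neighbours from dragging the point. All
    replacements are computed from the original list.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    out = points.copy()
    for i in range(n):
        lo, hi = max(0, i - neighbor_count), min(n, i + neighbor_count + 1)
        idx = [j for j in range(lo, hi) if j != i]
        if len(idx) < 2:
            continue
        pairs = list(combinations(idx, 2))
        a = points[[p[0] for p in pairs]]
        b = points[[p[1] for p in pairs]]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        valid = denom > 0
        if not valid.any():
            continue
        a, ab, denom = a[valid], ab[valid], denom[valid]
        t = np.einsum("ij,ij->i", points[i] - a, ab) / denom
        proj = a + t[:, None] * ab
        disp = np.linalg.norm(proj - points[i], axis=1)
        order = np.argsort(disp, kind="stable")
        median = disp[order[(len(disp) - 1) // 2]]  # lower median
        out[i] = proj[int(np.argmin(np.abs(disp - median)))]
    return out


def compute_arc_lengths(points: np.ndarray, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length in µm; duplicate consecutive points are merged.

    Returns ``(keep_mask, arc_lengths_um)`` where ``arc_lengths_um`` applies
    to the kept points and starts at 0.
    """
    points = np.asarray(points, dtype=float)
    gaps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], gaps > 0])
    kept = points[keep]
    seg = np.linalg.norm(np.diff(kept, axis=0), axis=1) * pixel_size
    return keep, np.concatenate([[0.0], np.cumsum(seg)])


def smooth_z_widths(
    widths: np.ndarray,
    arc_lengths_um: np.ndarray,
    neighbor_count: int,
    arc_distance_limit_um: float,
) -> np.ndarray:
    """Median-projection smoothing of the width signal d(l).

    The xy scheme applied to the 1-D series: for every pair of eligible
    neighbours (within ``neighbor_count`` indices and within
    ``arc_distance_limit_um`` of arc length, valid fit), the width at ``l_i``
    is linearly inter-/extrapolated from the pair, and the candidate whose
    displacement from ``d_i`` is nearest the median displacement wins.
    With fewer than 2 eligible neighbours (in particular with limit 0) the
    width is kept unsmoothed. NaN widths (rejected fits) stay NaN.
    """
    widths = np.asarray(widths, dtype=float)
    arc = np.asarray(arc_lengths_um, dtype=float)
    n = widths.size
    out = widths.copy()
    valid = np.isfinite(widths)
    for i in range(n):
        if not valid[i]:
            continue
        lo, hi = max(0, i - neighbor_count), min(n, i + neighbor_count + 1)
        idx = [
            j
            for j in range(lo, hi)
            if j != i and valid[j] and abs(arc[j] - arc[i]) <= arc_distance_limit_um
        ]
        if len(idx) < 2:
            continue
        cand, disp = [], []
        for j, k in combinations(idx, 2):
            if arc[k] == arc[j]:
                continue
            w = widths[j] + (widths[k] - widths[j]) * (arc[i] - arc[j]) / (
                arc[k] - arc[j]
            )
            cand.append(w)
            disp.append(abs(w - widths[i]))
        if len(cand) < 1:
            continue
        disp = np.asarray(disp)
        order = np.argsort(disp, kind="stable")
        median = disp[order[(len(disp) - 1) // 2]]
        out[i] = cand[int(np.argmin(np.abs(disp - median)))]
    return out


# ---------------------------------------------------------------------------
# full two-pass refinement
# ---------------------------------------------------------------------------

def _fit_all(
    frame: np.ndarray,
    points: np.ndarray,
    normals: np.ndarray,
    settings: Settings,
    pixel_size: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample and fit the normal profile at every point; returns (params, r2, accepted)."""
    radius_px = int(round(settings.normal_radius_um / pixel_size))
    offsets = np.arange(-radius_px, radius_px + 1, dtype=float)
    xy = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    values = bilinear_sample(frame, xy.reshape(-1, 2)).reshape(len(points), -1)
    mask = ~np.isnan(values)
    values = np.nan_to_num(values)
    if settings.smooth_normal_profile:
        padded = np.concatenate([values[:, :1], values, values[:, -1:]], axis=1)
        smoothed = (padded[:, :-2] + padded[:, 1:-1] + padded[:, 2:]) / 3.0
        values = np.where(mask, smoothed, values)
    return fit_gaussian_profiles(
        np.broadcast_to(offsets, values.shape), values, mask,
        settings.normal_radius_um / pixel_size,
    )


def _head_mask(points: np.ndarray, head_point: np.ndarray) -> np.ndarray:
    return np.linalg.norm(points - head_point, axis=1) < HEAD_DISK_RADIUS_PX


def refine_trace(
    frame: np.ndarray,
    rough_points: np.ndarray,
    settings: Settings,
    pixel_size: float,
) -> FlagellarTrace:
    """Two-pass sub-pixel refinement of a rough point list.

    Pass 1: tangents/normals → normal-profile Gaussian fits → centre
    correction of accepted points → triplet outlier removal.
    Pass 2: median-projection xy smoothing → arc lengths → outlier removal →
    renewed tangents/normals → renewed fits and centring → optional removal
    of criteria-failing points → arc-length-restricted width smoothing.

    Head points (within the head-disk radius of the first point) are exempt
    from centring and deletion when ``exclude_head_from_correction`` is set.
    """
    points = np.asarray(rough_points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 rough points")
    head_point = points[0].copy()

    def head_mask(p: np.ndarray) -> np.ndarray | None:
        return _head_mask(p, head_point) if settings.exclude_head_from_correction else None

    # ---- pass 1 ----
    tangents, normals = compute_tangents_normals(points, settings.max_vector_length_points)
    params, r2, accepted = _fit_all(frame, points, normals, settings, pixel_size)
    points = center_correct(points, normals, params[:, 2], accepted, head_mask(points))
    keep = remove_outliers(points)
    hm = head_mask(points)
    if hm is not None:
        keep |= hm
    points = points[keep]

    # ---- pass 2 ----
    points = smooth_xy(points, settings.smoothing_neighbor_count)
    keep, arc = compute_arc_lengths(points, pixel_size)
    points = points[keep]
    keep = remove_outliers(points)
    hm = head_mask(points)
    if hm is not None:
        keep |= hm
    points = points[keep]
    tangents, normals = compute_tangents_normals(points, settings.max_vector_length_points)
    params, r2, accepted = _fit_all(frame, points, normals, settings, pixel_size)
    points = center_correct(points, normals, params[:, 2], accepted, head_mask(points))
    if settings.filter_points_by_fits:
        keep = accepted.copy()
        hm = head_mask(points)
        if hm is not None:
            keep |= hm
        keep[0] = keep[-1] = True
        points, tangents, normals = points[keep], tangents[keep], normals[keep]
        params, r2, accepted = params[keep], r2[keep], accepted[keep]
    keep, arc = compute_arc_lengths(points, pixel_size)
    points, tangents, normals = points[keep], tangents[keep], normals[keep]
    params, r2, accepted = params[keep], r2[keep], accepted[keep]

    baseline, a, c, d = params.T
    a = np.where(accepted, a, np.nan)
    c = np.where(accepted, c, np.nan)
    d = np.where(accepted, d, np.nan)
    z_width = smooth_z_widths(
        d, arc, settings.smoothing_neighbor_count, settings.z_smoothing_arc_distance_um
    )
    return FlagellarTrace(
        x=points[:, 0],
        y=points[:, 1],
        tangent=tangents,
        normal=normals,
        arc_length_um=arc,
        fit_a=a,
        fit_c=c,
        fit_d=d,
        fit_r2=r2,
        fit_baseline=baseline,
        accepted=accepted,
        z_width=z_width,
        intensity=a,
        pixel_size=pixel_size,
    )
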