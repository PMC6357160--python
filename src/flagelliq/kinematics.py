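"""Head and flagellar kinematic parameters derived from refined traces.

Angle convention (used everywhere in the package): angles are measured from
the image x-axis toward positive y; with the image y-axis pointing down
(row-down), a vector pointing "up" on screen therefore has a negative angle.
All angles are reported in degrees.

Head parameters: head position (= first trace point), orientation angle Θ of
the head-midpiece vector (first point → point at a reference arc length),
and the rolling signal (maximum intensity on a cross-sectioning line through
the head — the head's scattering intensity oscillates while the cell rotates
around its longitudinal axis).

Flagellar parameters, per arc-length position: head-frame coordinates,
tangential angle, geometric curvature κ (turning rate of the tangent, rad/µm)
and curvature angle cA (angle between the local tangent and the tangent a
fixed arc length upstream, degrees).
"""

from __future__ import annotations

import numpy as np

from flagelliq.trace import FlagellarTrace
from flagelliq.trace_refinement import bilinear_sample


def signed_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Signed angle from v1 to v2, degrees, sign from the 2-D cross product."""
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return float(np.degrees(np.arctan2(cross, dot)))


def head_midpiece_vector(
    trace: FlagellarTrace, reference_arc_length_um: float
) -> tuple[np.ndarray, float]:
    """Head-midpiece vector v and orientation angle Θ for one frame.

    v points from the first trace point to the point at the reference arc
    length (linearly interpolated on the polyline); Θ is its angle to the
    image x-axis in degrees. A trace shorter than the reference arc length
    cannot define v and raises.
    """
    if trace.length_um < reference_arc_length_um:
        raise ValueError(
            f"trace arc length {trace.length_um:.2f} µm is shorter than the "
            f"reference arc length {reference_arc_length_um:.2f} µm"
        )
    ref = trace.point_at_arc_length(reference_arc_length_um)
    v = ref - trace.points[0]
    theta = float(np.degrees(np.arctan2(v[1], v[0])))
    return v, theta


def unwrap_degrees(series: np.ndarray) -> np.ndarray:
    """Unwrap a time series of angles: successive values adjusted by ±360°
    so each step is below 180° in magnitude; NaNs are passed through."""
    series = np.asarray(series, dtype=float)
    out = series.copy()
    finite = np.isfinite(series)
    if finite.sum() >= 2:
        out[finite] = np.degrees(np.unwrap(np.radians(series[finite])))
    return out


def transform_to_head_frame(
    trace: FlagellarTrace, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trace coordinates in the head frame, µm.

    The head frame originates at the first trace point with its x-axis along
    the head-midpiece vector v (rigid transform: translate by -p₁, rotate by
    -Θ). Returns ``(x_um, y_um)`` per point; the reference point itself maps
    to ``(|v|·pixel_size, ≈0)``.
    """
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("head-midpiece vector has zero length")
    ux, uy = v / norm
    rel = trace.points - trace.points[0]
    x = (rel[:, 0] * ux + rel[:, 1] * uy) * trace.pixel_size
    y = (-rel[:, 0] * uy + rel[:, 1] * ux) * trace.pixel_size
    return x, y


def tangential_angle(trace: FlagellarTrace) -> np.ndarray:
    """Per-point angle of the tangent to the image x-axis, degrees,
    unwrapped along arc length so it is continuous spatially."""
    angles = np.degrees(np.arctan2(trace.tangent[:, 1], trace.tangent[:, 0]))
    return np.degrees(np.unwrap(np.radians(angles)))


def _tangent_pair_angle(
    trace: FlagellarTrace, s1: float, s2: float
) -> tuple[float, float]:
    """Signed angle (deg) between tangents at arc lengths s1 < s2 and their
    actual arc separation (µm), both clamped into the trace."""
    s1 = float(np.clip(s1, 0.0, trace.length_um))
    s2 = float(np.clip(s2, 0.0, trace.length_um))
    t1 = trace.tangent_at_arc_length(s1)
    t2 = trace.tangent_at_arc_length(s2)
    return signed_angle_deg(t1, t2), s2 - s1


def curvature(trace: FlagellarTrace, reference_distance_um: float) -> np.ndarray:
    """Geometric curvature κ(s) in rad/µm at every trace point.

    κ is the signed angle between the tangents at ``s - Q/2`` and ``s + Q/2``
    divided by their arc separation, with ``Q = reference_distance_um``. Near
    the ends the support is clamped into the trace, i.e. a smaller distance
    is used. The sign follows the 2-D cross product of the two tangents.
    Points whose clamped support collapses report NaN.
    """
    half = reference_distance_um / 2.0
    out = np.full(len(trace), np.nan)
    for i, s in enumerate(trace.arc_length_um):
        angle, ds = _tangent_pair_angle(trace, s - half, s + half)
        if ds > 0:
            out[i] = np.radians(angle) / ds
    return out


def curvature_angle(trace: FlagellarTrace, reference_distance_um: float) -> np.ndarray:
    """Curvature angle cA(s), degrees, at every trace point.

    cA is the signed angle between the tangent at ``s`` and the tangent at
    ``s - Q`` (``Q = reference_distance_um``). For ``s < Q`` the nearest
    available upstream point — the trace start — provides the reference
    tangent, i.e. the support is shortened.
    """
    out = np.full(len(trace), np.nan)
    for i, s in enumerate(trace.arc_length_um):
        s_up = max(s - reference_distance_um, 0.0)
        t_up = trace.tangent_at_arc_length(s_up)
        out[i] = signed_angle_deg(t_up, trace.tangent[i])
    return out


def head_rolling_signal(
    frame: np.ndarray,
    p1: np.ndarray,
    v: np.ndarray,
    radius_px: float,
    thickness: int = 9,
) -> float:
    """Maximum intensity on the cross-sectioning line through the head.

    The line is centred on the head point, oriented normal to the
    head-midpiece vector, of half-length ``radius_px``; it is sampled at
    1-px steps with bilinear interpolation, each step averaged across the
    fixed 9-px thickness (along v). Steps that leave the frame are dropped
    (truncated line).
    """
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("head-midpiece vector has zero length")
    u = np.asarray(v, dtype=float) / norm  # along-axis unit vector
    n = np.array([-u[1], u[0]])  # cross-line direction
    steps = np.arange(-round(radius_px), round(radius_px) + 1, dtype=float)
    lateral = np.arange(thickness, dtype=float) - (thickness - 1) / 2.0
    pts = (
        np.asarray(p1, dtype=float)[None, None, :]
        + steps[:, None, None] * n[None, None, :]
        + lateral[None, :, None] * u[None, None, :]
    )
    values = bilinear_sample(frame, pts.reshape(-1, 2)).reshape(steps.size, thickness)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(values, axis=1)
    if np.all(np.isnan(means)):
        raise ValueError("cross-sectioning line lies entirely outside the frame")
    return float(np.nanmax(means))
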