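"""Synthetic dark-field sperm movies with exact ground truth.

The renderer emulates what a dark-field camera sees: a bright elliptical
head blob (optionally intensity-modulated at a rolling frequency — the
scattering signature of a cell rotating about its longitudinal axis), a
flagellum drawn as a travelling bending wave whose cross-section is a
Gaussian of arc-length-dependent width σ(s) (defocus makes out-of-plane
segments image wider), a constant background and additive noise.

The prescribed centerline lives in a body frame attached to the head: the
lateral displacement is

    y(s, t) = A(s) · sin(2π(f·t − s/λ) + φ)  +  harmonic terms,

with amplitude envelope A(s), beat frequency f, wavelength λ; harmonic
terms add components at integer multiples of f, optionally gated to a
distal arc-length range. The whole body frame may rotate rigidly
(oscillating orientation angle θ(t)) and the head may translate (swimming).
An optional out-of-plane oscillation moves the flagellum through the focal
plane at a set frequency: the rendered width follows
σ_eff = √(σ(s)² + z(t)²), which is even in z — one full z-cycle therefore
produces two width maxima, the classic focal-plane-crossing artefact.

All randomness (noise) is driven by a seed recorded in the ground truth;
two renders with the same parameters and seed are bit-identical.

Waveforms are kinematic prescriptions; no hydrodynamics is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from flagelliq.imaging_io import ImageStack
from flagelliq.trace import FlagellarTrace


@dataclass
class Harmonic:
    """Additional waveform component at ``multiple`` × beat frequency.

    Active only between ``gate_start_um`` and ``gate_end_um`` of arc length
    (the gate edges are smoothed over 2 µm to avoid kinks)."""

    multiple: float
    amplitude_um: float
    gate_start_um: float = 0.0
    gate_end_um: float = np.inf


@dataclass
class SynthParams:
    """Parameters of a synthetic movie. Defaults emulate a freely rolling
    human sperm recorded at 500 fps behind a 20× objective (0.55 µm/px)."""

    n_frames: int = 100
    fps: float = 500.0
    shape: tuple[int, int] = (160, 224)  # rows, columns
    pixel_size: float = 0.55
    flagellum_length_um: float = 55.0
    amplitude_um: float = 6.0
    amplitude_ramp_um: float = 25.0  # arc length over which A(s) ramps to max
    amplitude_ramp_start_um: float = 0.0  # arc length where the envelope starts rising
    beat_frequency_hz: float = 27.0
    wavelength_um: float = 40.0
    phase: float = 0.0
    harmonics: tuple[Harmonic, ...] = ()
    theta_mean_deg: float = 0.0
    theta_amplitude_deg: float = 0.0
    theta_frequency_hz: float = 0.0
    #: extra rigid-rotation components as (amplitude_deg, frequency_hz) pairs,
    #: e.g. a small fast wobble on top of a slow rolling-driven yaw
    theta_components: tuple[tuple[float, float], ...] = ()
    head_position_px: tuple[float, float] | None = None  # default: left-centre
    head_velocity_um_s: tuple[float, float] = (0.0, 0.0)
    tube_intensity: float = 120.0
    tube_sigma_head_px: float = 2.0
    tube_sigma_tip_px: float = 2.0
    z_amplitude_px: float = 0.0  # out-of-plane excursion, in width units
    z_frequency_hz: float = 0.0
    z_gate_start_um: float = 0.0
    head_axes_px: tuple[float, float] = (4.0, 2.5)
    head_intensity: float = 250.0
    rolling_depth: float = 0.0  # fractional head-intensity modulation
    rolling_frequency_hz: float = 0.0
    noise_sigma: float = 0.0
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_frequency_hz >= self.fps / 2:
            raise ValueError("beat frequency must satisfy the Nyquist bound fps/2")
        if self.rolling_frequency_hz >= self.fps / 2:
            raise ValueError("rolling frequency must satisfy the Nyquist bound fps/2")
        if min(self.tube_sigma_head_px, self.tube_sigma_tip_px) <= 0.5:
            raise ValueError("tube sigma must exceed 0.5 px to be resolvable")


def mouse_tethered_params(**overrides) -> SynthParams:
    """Head-tethered mouse-like preset: 200 fps, 16× (0.6875 µm/px), 11 Hz beat."""
    defaults = dict(
        n_frames=200,
        fps=200.0,
        shape=(192, 256),
        pixel_size=0.6875,
        flagellum_length_um=100.0,
        amplitude_um=10.0,
        amplitude_ramp_um=40.0,
        beat_frequency_hz=11.0,
        wavelength_um=70.0,
        theta_mean_deg=0.0,
        rolling_depth=0.0,
        background_level=10.0,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)


def human_swimming_params(**overrides) -> SynthParams:
    """Freely swimming human-like preset: 500 fps, 20× (0.55 µm/px), rolling at
    9 Hz with three beat cycles per roll (27 Hz)."""
    defaults = dict(
        n_frames=500,
        fps=500.0,
        shape=(160, 224),
        pixel_size=0.55,
        flagellum_length_um=55.0,
        amplitude_um=5.0,
        amplitude_ramp_um=25.0,
        beat_frequency_hz=27.0,
        wavelength_um=40.0,
        rolling_depth=0.3,
        rolling_frequency_hz=9.0,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)


@dataclass
class GroundTruth:
    """Exact per-frame geometry of a rendered movie.

    ``centerline_px[t]`` is the densely sampled true centerline (step 0.25 px
    along the body axis), ``sigma_px[t]`` the true tube width at each sample,
    ``theta_deg[t]`` the true body-frame orientation and ``head_px[t]`` the
    true head position. Frequencies and the full parameter set are carried
    along for end-to-end recovery checks.
    """

    params: SynthParams
    s_um: np.ndarray  # arc-axis sample positions, µm (shared across frames)
    centerline_px: np.ndarray  # (T, S, 2) as (x, y)
    sigma_px: np.ndarray  # (T, S)
    theta_deg: np.ndarray  # (T,)
    head_px: np.ndarray  # (T, 2)
    seed: int = 0

    def arc_lengths_um(self, frame: int) -> np.ndarray:
        """True cumulative arc length of the dense centerline, µm."""
        seg = np.linalg.norm(np.diff(self.centerline_px[frame], axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)]) * self.params.pixel_size

    def length_um(self, frame: int) -> float:
        return float(self.arc_lengths_um(frame)[-1])

    def scoring_polyline(self, frame: int, head_extension_px: float | None = None) -> np.ndarray:
        """True centerline extended through the head and past the tip.

        The skeleton of the rendered cell runs through the bright head blob,
        so the detected trace legitimately starts before the flagellum's
        s = 0; for distance scoring the body axis is continued straight
        behind the head (the head sits on the axis). Likewise the Gaussian
        tube has a rounded luminous cap past the last centerline sample, so
        the curve is continued ~2σ beyond the tip along the end tangent."""
        if head_extension_px is None:
            head_extension_px = 3.0 * max(self.params.head_axes_px)
        th = np.radians(self.theta_deg[frame])
        u = np.array([np.cos(th), np.sin(th)])
        steps = np.arange(head_extension_px, 0.0, -0.25)
        ext = self.head_px[frame] - steps[:, None] * u
        line = self.centerline_px[frame]
        tip_dir = line[-1] - line[-2]
        tip_dir = tip_dir / np.linalg.norm(tip_dir)
        tip_len = 2.0 * float(self.sigma_px[frame][-1])
        tip = line[-1] + np.arange(0.25, tip_len, 0.25)[:, None] * tip_dir
        return np.vstack([ext, line, tip])

    def curvature_angle_deg(self, frame: int, reference_distance_um: float) -> np.ndarray:
        """Analytic-resolution curvature angle of the true centerline."""
        pts = self.centerline_px[frame]
        arc = self.arc_lengths_um(frame)
        tan = np.gradient(pts, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        angles = np.unwrap(np.arctan2(tan[:, 1], tan[:, 0]))
        upstream = np.interp(np.maximum(arc - reference_distance_um, 0.0), arc, angles)
        return np.degrees(angles - upstream)


def _body_wave(params: SynthParams, s_um: np.ndarray, t: float) -> np.ndarray:
    """Lateral displacement y(s, t) of the body-frame waveform, µm."""
    envelope = params.amplitude_um * np.clip(
        (s_um - params.amplitude_ramp_start_um) / max(params.amplitude_ramp_um, 1e-9),
        0.0,
        1.0,
    )
    phase = 2 * np.pi * (
        params.beat_frequency_hz * t - s_um / params.wavelength_um
    ) + params.phase
    y = envelope * np.sin(phase)
    for h in params.harmonics:
        gate = np.clip((s_um - h.gate_start_um) / 2.0, 0.0, 1.0) * np.clip(
            (h.gate_end_um - s_um) / 2.0, 0.0, 1.0
        )
        ph = 2 * np.pi * (
            h.multiple * params.beat_frequency_hz * t - s_um / params.wavelength_um
        )
        y = y + h.amplitude_um * gate * np.sin(ph)
    return y


def ground_truth(params: SynthParams) -> GroundTruth:
    """Evaluate the prescribed geometry (no imaging) for every frame."""
    h, w = params.shape
    head0 = (
        np.array(params.head_position_px, dtype=float)
        if params.head_position_px is not None
        else np.array([w * 0.15, h * 0.5])
    )
    step_um = 0.25 * params.pixel_size
    s_um = np.arange(0.0, params.flagellum_length_um + step_um / 2, step_um)
    times = np.arange(params.n_frames) / params.fps
    theta = params.theta_mean_deg + params.theta_amplitude_deg * np.sin(
        2 * np.pi * params.theta_frequency_hz * times
    )
    for amp_deg, freq_hz in params.theta_components:
        theta = theta + amp_deg * np.sin(2 * np.pi * freq_hz * times)
    centerline = np.empty((params.n_frames, s_um.size, 2))
    sigma = np.empty((params.n_frames, s_um.size))
    heads = np.empty((params.n_frames, 2))
    sigma_s = params.tube_sigma_head_px + (
        params.tube_sigma_tip_px - params.tube_sigma_head_px
    ) * s_um / params.flagellum_length_um
    for i, t in enumerate(times):
        y_um = _body_wave(params, s_um, t)
        th = np.radians(theta[i])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        body = np.column_stack([s_um, y_um]) / params.pixel_size
        head = head0 + np.array(params.head_velocity_um_s) * t / params.pixel_size
        centerline[i] = head + body @ rot.T
        heads[i] = head
        z = params.z_amplitude_px * np.sin(2 * np.pi * params.z_frequency_hz * t)
        gate = np.clip((s_um - params.z_gate_start_um) / 2.0, 0.0, 1.0)
        sigma[i] = np.sqrt(sigma_s**2 + (gate * z) ** 2)
    return GroundTruth(params, s_um, centerline, sigma, theta, heads, params.seed)


def render_movie(
    params: SynthParams, seed: int | None = None
) -> tuple[ImageStack, GroundTruth]:
    """Render the movie described by ``params``; returns (stack, ground truth).

    Raises if the flagellum leaves the frame (with a 3-px margin) in any
    frame — enlarge the image or shorten the flagellum in that case.
    """
    if seed is not None:
        params = replace(params, seed=seed)
    gt = ground_truth(params)
    h, w = params.shape
    margin = 3.0
    if (
        gt.centerline_px[..., 0].min() < margin
        or gt.centerline_px[..., 0].max() > w - 1 - margin
        or gt.centerline_px[..., 1].min() < margin
        or gt.centerline_px[..., 1].max() > h - 1 - margin
    ):
        raise ValueError("flagellum exits the frame: increase image size")
    rng = np.random.default_rng(params.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((params.n_frames, h, w))
    times = np.arange(params.n_frames) / params.fps
    for i in range(params.n_frames):
        structure = np.zeros((h, w))
        pts = gt.centerline_px[i]
        sig = gt.sigma_px[i]
        # Gaussian cross-sections along the centerline, max-blended so tight
        # bends do not brighten by self-interference
        for (px, py), s in zip(pts, sig):
            r = max(3.0 * s, 2.0)
            x0, x1 = int(np.floor(px - r)), int(np.ceil(px + r)) + 1
            y0, y1 = int(np.floor(py - r)), int(np.ceil(py + r)) + 1
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, w), min(y1, h)
            sub_x = xx[y0:y1, x0:x1] - px
            sub_y = yy[y0:y1, x0:x1] - py
            stamp = params.tube_intensity * np.exp(
                -(sub_x**2 + sub_y**2) / (2 * s**2)
            )
            np.maximum(structure[y0:y1, x0:x1], stamp, out=structure[y0:y1, x0:x1])
        # elliptical head blob, oriented along the body axis
        hx, hy = gt.head_px[i]
        th = np.radians(gt.theta_deg[i])
        ca, sa = np.cos(th), np.sin(th)
        rel_x = (xx - hx) * ca + (yy - hy) * sa
        rel_y = -(xx - hx) * sa + (yy - hy) * ca
        ax, ay = params.head_axes_px
        head_intensity = params.head_intensity * (
            1.0
            + params.rolling_depth
            * np.sin(2 * np.pi * params.rolling_frequency_hz * times[i])
        )
        head = head_intensity * np.exp(
            -(rel_x**2 / (2 * ax**2) + rel_y**2 / (2 * ay**2))
        )
        frame = params.background_level + np.maximum(structure, head)
        if params.poisson_scale > 0:
            frame = rng.poisson(frame * params.poisson_scale) / params.poisson_scale
        if params.noise_sigma > 0:
            frame = frame + rng.normal(0.0, params.noise_sigma, frame.shape)
        frames[i] = np.maximum(frame, 0.0)
    stack = ImageStack(frames, params.fps, params.pixel_size)
    return stack, gt


# ---------------------------------------------------------------------------
# scoring against the ground truth
# ---------------------------------------------------------------------------

def polyline_distances(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Exact distance of each point to a densely sampled polyline.

    Nearest vertex found by a k-d tree, then refined to the true distance to
    the segments adjacent to that vertex (removes discretisation bias)."""
    tree = cKDTree(polyline)
    _, idx = tree.query(points)
    out = np.empty(len(points))
    for k, (p, i) in enumerate(zip(points, idx)):
        best = np.linalg.norm(p - polyline[i])
        for j in (i - 1, i):
            if 0 <= j < len(polyline) - 1:
                a, b = polyline[j], polyline[j + 1]
                ab = b - a
                t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
                best = min(best, np.linalg.norm(p - (a + t * ab)))
        out[k] = best
    return out


@dataclass
class TruthScore:
    """Error report of pipeline output against the renderer's ground truth."""

    rms_centerline_error_px: float
    max_centerline_error_px: float
    arc_length_relative_error: float
    theta_rms_error_deg: float


def _arc_position_on_polyline(p: np.ndarray, polyline: np.ndarray) -> float:
    """Arc position (in px, from the polyline start) of the projection of p."""
    seg = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    tree = cKDTree(polyline)
    _, i = tree.query(p)
    best_d, best_s = np.inf, 0.0
    for j in (int(i) - 1, int(i)):
        if 0 <= j < len(polyline) - 1 and seg_len[j] > 0:
            a, ab = polyline[j], seg[j]
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            d = np.linalg.norm(p - (a + t * ab))
            if d < best_d:
                best_d, best_s = d, cum[j] + t * seg_len[j]
    return best_s


def score_against_truth(
    traces: list[FlagellarTrace | None],
    theta_deg: np.ndarray | None,
    gt: GroundTruth,
) -> TruthScore:
    """Centerline / arc-length / Θ errors of a full pipeline run.

    Centerline error uses accepted trace points only (rejected fits carry no
    sub-pixel information) against the head-extended true centerline (the
    detected trace legitimately starts inside the head). Arc-length error
    compares the trace's total length with the true curve length over the
    matched extent, i.e. from the projection of the trace start to the tip.
    Θ error compares the unwrapped recovered series with the true body-frame
    orientation where both are defined.
    """
    if len(traces) != gt.centerline_px.shape[0]:
        raise ValueError("frame counts of traces and ground truth differ")
    sq, n_pts = 0.0, 0
    max_err = 0.0
    arc_errs = []
    for i, trace in enumerate(traces):
        if trace is None or len(trace) == 0:
            continue
        poly = gt.scoring_polyline(i)
        pts = trace.points[trace.accepted] if trace.accepted.any() else trace.points
        d = polyline_distances(pts, poly)
        sq += float((d**2).sum())
        n_pts += d.size
        max_err = max(max_err, float(d.max()))
        start_px = _arc_position_on_polyline(trace.points[0], poly)
        end_px = _arc_position_on_polyline(trace.points[-1], poly)
        true_um = abs(end_px - start_px) * gt.params.pixel_size
        arc_errs.append(abs(trace.length_um - true_um) / true_um)
    rms = np.sqrt(sq / n_pts) if n_pts else np.nan
    theta_rms = np.nan
    if theta_deg is not None:
        rec = np.asarray(theta_deg, dtype=float)
        true = gt.theta_deg
        ok = np.isfinite(rec)
        if ok.any():
            diff = rec[ok] - true[ok]
            diff = diff - 360.0 * np.round(diff.mean() / 360.0)
            theta_rms = float(np.sqrt(np.mean(diff**2)))
    return TruthScore(
        rms_centerline_error_px=float(rms),
        max_centerline_error_px=max_err,
        arc_length_relative_error=float(np.mean(arc_errs)) if arc_errs else np.nan,
        theta_rms_error_deg=theta_rms,
    )
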