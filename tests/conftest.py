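"""Shared fixtures: small synthetic renders and analytic trace builders."""

from __future__ import annotations

import numpy as np
import pytest

from flagelliq.settings import Settings
from flagelliq.trace import FlagellarTrace
from flagelliq.trace_refinement import compute_arc_lengths, compute_tangents_normals


def make_trace(points_px: np.ndarray, pixel_size: float = 1.0) -> FlagellarTrace:
    """FlagellarTrace from bare points: geometry only, no fits."""
    points_px = np.asarray(points_px, dtype=float)
    tangents, normals = compute_tangents_normals(points_px, 4)
    keep, arc = compute_arc_lengths(points_px, pixel_size)
    points_px = points_px[keep]
    tangents, normals = tangents[keep], normals[keep]
    n = len(points_px)
    nan = np.full(n, np.nan)
    return FlagellarTrace(
        x=points_px[:, 0],
        y=points_px[:, 1],
        tangent=tangents,
        normal=normals,
        arc_length_um=arc,
        fit_a=nan.copy(),
        fit_c=nan.copy(),
        fit_d=nan.copy(),
        fit_r2=np.zeros(n),
        fit_baseline=nan.copy(),
        accepted=np.ones(n, dtype=bool),
        z_width=nan.copy(),
        intensity=nan.copy(),
        pixel_size=pixel_size,
    )


def circle_trace(
    radius_um: float,
    pixel_size: float = 1.0,
    span_deg: float = 90.0,
    step_px: float = 0.5,
) -> FlagellarTrace:
    """Analytic circular-arc trace (dense sampling, known curvature 1/R)."""
    radius_px = radius_um / pixel_size
    n = max(int(np.radians(span_deg) * radius_px / step_px), 8)
    angles = np.linspace(0.0, np.radians(span_deg), n)
    pts = np.column_stack(
        [100 + radius_px * np.cos(angles), 100 + radius_px * np.sin(angles)]
    )
    return make_trace(pts, pixel_size)


@pytest.fixture(scope="session")
def mouse_settings() -> Settings:
    return Settings.mouse()


@pytest.fixture(scope="session")
def human_settings() -> Settings:
    return Settings.human()


@pytest.fixture(scope="session")
def small_mouse_render():
    """5-frame noise-free tethered render with its ground truth (shared)."""
    from flagelliq.synthetic_renderer import mouse_tethered_params, render_movie

    params = mouse_tethered_params(n_frames=5)
    return render_movie(params)


@pytest.fixture(scope="session")
def small_mouse_run(small_mouse_render, mouse_settings):
    from flagelliq.pipeline import analyze_stack

    stack, _ = small_mouse_render
    return analyze_stack(stack, mouse_settings)


@pytest.fixture(scope="session")
def mouse_beat_movie():
    """200-frame tethered render beating at 11 Hz (1 Hz frequency bins) with
    its analysed run — the workhorse for frequency-recovery checks."""
    from flagelliq.pipeline import analyze_stack
    from flagelliq.synthetic_renderer import mouse_tethered_params, render_movie

    params = mouse_tethered_params(n_frames=200, beat_frequency_hz=11.0)
    stack, gt = render_movie(params)
    run = analyze_stack(stack, Settings.mouse())
    return stack, gt, run


@pytest.fixture(scope="session")
def theta_beat_movie():
    """200-frame render with a rigid Θ oscillation (200° + 15°·sin(2π·11 t))
    and a proximally quiet waveform, analysed with head correction enabled."""
    from flagelliq.pipeline import analyze_stack
    from flagelliq.synthetic_renderer import mouse_tethered_params, render_movie

    params = mouse_tethered_params(
        n_frames=200,
        beat_frequency_hz=11.0,
        amplitude_um=8.0,
        amplitude_ramp_start_um=15.0,
        amplitude_ramp_um=30.0,
        theta_mean_deg=200.0,
        theta_amplitude_deg=15.0,
        theta_frequency_hz=11.0,
        head_position_px=(215.0, 120.0),
        shape=(192, 256),
    )
    stack, gt = render_movie(params)
    settings = Settings.mouse().replace(exclude_head_from_correction=False)
    run = analyze_stack(stack, settings)
    return stack, gt, run
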