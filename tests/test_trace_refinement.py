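"""Sub-pixel refinement: tangents, profile sampling, Gaussian fits, smoothing."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from flagelliq.settings import Settings
from flagelliq.trace_refinement import (
    bilinear_sample,
    center_correct,
    compute_arc_lengths,
    compute_tangents_normals,
    fit_gaussian_profile,
    fit_gaussian_profiles,
    remove_outliers,
    sample_normal_profile,
    smooth_xy,
    smooth_z_widths,
)

# ---------------------------------------------------------------------------
# tangents / normals
# ---------------------------------------------------------------------------


def test_tangents_straight_line_and_ends():
    pts = np.column_stack([np.arange(20.0), np.full(20, 5.0)])
    t, n = compute_tangents_normals(pts, 6)
    np.testing.assert_allclose(t, np.tile([1.0, 0.0], (20, 1)))
    np.testing.assert_allclose(n, np.tile([0.0, 1.0], (20, 1)))
    # first point uses the one-sided forward difference
    t1, _ = compute_tangents_normals(pts[:5], 8)
    np.testing.assert_allclose(t1[0], [1.0, 0.0])


def test_tangents_quarter_circle_accuracy():
    angles = np.linspace(0, np.pi / 2, 200)
    pts = 50 * np.column_stack([np.cos(angles), np.sin(angles)])
    t, n = compute_tangents_normals(pts, 6)
    analytic = np.column_stack([-np.sin(angles), np.cos(angles)])
    dots = np.clip(np.abs((t * analytic).sum(axis=1)), 0, 1)
    err_deg = np.degrees(np.arccos(dots[5:-5]))
    assert err_deg.max() < 2.0
    # unit vectors, n is t rotated by +90 degrees
    np.testing.assert_allclose(np.linalg.norm(t, axis=1), 1.0)
    np.testing.assert_allclose(n, np.column_stack([-t[:, 1], t[:, 0]]))


# ---------------------------------------------------------------------------
# bilinear sampling and normal profiles
# ---------------------------------------------------------------------------


def test_bilinear_identity_and_symmetry():
    frame = np.arange(16.0).reshape(4, 4)
    assert bilinear_sample(frame, np.array([[2.0, 1.0]]))[0] == frame[1, 2]
    quad = np.array([[0.0, 0.0], [100.0, 100.0]])
    assert bilinear_sample(quad, np.array([[0.5, 0.5]]))[0] == pytest.approx(50.0)
    assert np.isnan(bilinear_sample(frame, np.array([[-1.0, 0.0]]))[0])


def test_normal_profile_across_rendered_tube():
    """Profile across a Gaussian ridge (sigma 2 px, peak 100, centre offset
    0.3 px from the sample point) peaks within 2% of 100 at the true offset."""
    yy = np.arange(40.0)
    frame = np.tile(100.0 * np.exp(-((yy - 20.3) ** 2) / (2 * 4.0)), (40, 1)).T
    offsets, values, truncated = sample_normal_profile(
        frame, point=(20.0, 20.0), normal=(0.0, 1.0), normal_radius_um=5.0,
        pixel_size=1.0,
    )
    assert not truncated
    assert offsets.size == 11
    assert values.max() == pytest.approx(100.0, rel=0.02)
    fit = fit_gaussian_profile(offsets, values, normal_radius_px=5.0)
    assert fit.accepted
    assert fit.c == pytest.approx(0.3, abs=0.05)
    # a profile leaving the frame is truncated and flagged
    _, short, trunc = sample_normal_profile(
        frame, point=(20.0, 2.0), normal=(0.0, 1.0), normal_radius_um=5.0,
        pixel_size=1.0,
    )
    assert trunc and short.size < 11


# ---------------------------------------------------------------------------
# Gaussian fitting
# ---------------------------------------------------------------------------


def _gauss(x, b, a, c, d):
    return b + a * np.exp(-((x - c) ** 2) / (2 * d**2))


def test_fit_recovers_exact_parameters():
    x = np.arange(-9.0, 10.0)
    y = _gauss(x, 2.0, 120.0, 0.7, 1.8)
    fit = fit_gaussian_profile(x, y, normal_radius_px=9.0)
    assert fit.accepted
    assert fit.baseline == pytest.approx(2.0, rel=1e-3)
    assert fit.a == pytest.approx(120.0, rel=1e-3)
    assert fit.c == pytest.approx(0.7, rel=1e-3)
    assert fit.d == pytest.approx(1.8, rel=1e-3)
    assert fit.r2 > 0.999


def test_fit_matches_scipy_curve_fit_on_noisy_profiles():
    """Batched Levenberg–Marquardt agrees with scipy.optimize.curve_fit."""
    rng = np.random.default_rng(5)
    x = np.arange(-9.0, 10.0)
    for _ in range(20):
        y = _gauss(x, rng.uniform(0, 10), rng.uniform(50, 150),
                   rng.uniform(-2, 2), rng.uniform(1, 3))
        y = y + rng.normal(0, 1.0, x.size)
        fit = fit_gaussian_profile(x, y, normal_radius_px=9.0)
        p0 = [y.min(), y.max() - y.min(), x[np.argmax(y)], 4.5]
        ref, _ = curve_fit(_gauss, x, y, p0=p0, maxfev=2000)
        assert fit.a == pytest.approx(ref[1], rel=1e-3, abs=1e-3)
        assert fit.c == pytest.approx(ref[2], rel=1e-3, abs=1e-3)
        assert fit.d == pytest.approx(abs(ref[3]), rel=1e-3, abs=1e-3)


def test_pure_noise_profiles_rejected():
    """The r² > 0.8 criterion rejects at least 95% of structureless profiles."""
    rng = np.random.default_rng(6)
    x = np.arange(-9.0, 10.0)
    n = 100
    values = rng.normal(50.0, 5.0, size=(n, x.size))
    _, _, accepted = fit_gaussian_profiles(
        np.tile(x, (n, 1)), values, np.ones((n, x.size), bool), normal_radius_px=9.0
    )
    assert accepted.mean() <= 0.05


def test_negative_dip_rejected():
    x = np.arange(-9.0, 10.0)
    y = _gauss(x, 100.0, -60.0, 0.0, 2.0)  # dark dip on bright baseline
    fit = fit_gaussian_profile(x, y, normal_radius_px=9.0)
    assert not fit.accepted


def test_criteria_on_width_and_center():
    x = np.arange(-5.0, 6.0)
    wide = _gauss(x, 0.0, 50.0, 0.0, 20.0)  # d >= 2 * radius
    assert not fit_gaussian_profile(x, wide, normal_radius_px=5.0).accepted
    short = np.array([1.0, 2.0, 3.0])
    assert not fit_gaussian_profile(short, short, normal_radius_px=5.0).accepted


# ---------------------------------------------------------------------------
# centring, outlier removal, smoothing
# ---------------------------------------------------------------------------


def test_center_correct_shift_and_exemptions():
    pts = np.array([[10.0, 10.0], [20.0, 10.0]])
    normals = np.array([[0.0, 1.0], [0.0, 1.0]])
    centers = np.array([1.4, 0.0])
    accepted = np.array([True, True])
    out = center_correct(pts, normals, centers, accepted)
    np.testing.assert_allclose(out, [[10.0, 11.4], [20.0, 10.0]])
    # rejected and head-flagged points stay put
    out = center_correct(pts, normals, centers, np.array([False, True]))
    np.testing.assert_allclose(out, pts)
    out = center_correct(pts, normals, centers, accepted, np.array([True, False]))
    np.testing.assert_allclose(out, pts)


def test_remove_outliers_triplet_rule():
    keep = remove_outliers(np.array([(0.0, 0.0), (5.0, 0.0), (6.0, 0.0)]))
    np.testing.assert_array_equal(keep, [True, False, True])
    equal = np.column_stack([np.arange(10.0), np.zeros(10)])
    assert remove_outliers(equal).all()  # equality does not trigger strict >


def test_remove_outliers_injected_points():
    """Stray detections (shifted forward and off-curve) are removed with at
    most one collateral removal."""
    x = np.arange(200.0)
    pts = np.column_stack([x, np.zeros(200)])
    injected = [50, 100, 150]
    for i in injected:
        pts[i] += (0.45, 0.25)  # forward+lateral displacement: gap before > gap after
    keep = remove_outliers(pts)
    assert not keep[injected].any()
    false_removals = (~keep).sum() - len(injected)
    assert false_removals <= 1


def test_smooth_xy_line_fixed_point_and_denoising():
    line = np.column_stack([np.arange(30.0), 2.0 * np.arange(30.0)])
    np.testing.assert_allclose(smooth_xy(line, 5), line, atol=1e-9)
    noisy = line.copy()
    noisy[15, 1] += 1.0
    out = smooth_xy(noisy, 5)
    # off-line displacement after smoothing (the projection may slide along
    # the line; what matters is the distance back to the line y = 2x)
    off_line = abs(2.0 * out[15, 0] - out[15, 1]) / np.sqrt(5.0)
    assert off_line < 0.2


def test_smooth_xy_matches_direct_pair_projection_oracle():
    """The replacement equals the projection whose displacement is nearest
    the (lower) median, recomputed here by brute force for one point."""
    from itertools import combinations

    rng = np.random.default_rng(8)
    pts = np.column_stack([np.arange(12.0), rng.normal(0, 0.3, 12)])
    i, nc = 6, 3
    idx = [j for j in range(i - nc, i + nc + 1) if j != i]
    projections, disps = [], []
    for aj, bj in combinations(idx, 2):
        a, b = pts[aj], pts[bj]
        ab = b - a
        proj = a + np.dot(pts[i] - a, ab) / np.dot(ab, ab) * ab
        projections.append(proj)
        disps.append(np.linalg.norm(proj - pts[i]))
    disps = np.array(disps)
    median = np.sort(disps)[(len(disps) - 1) // 2]
    expected = projections[int(np.argmin(np.abs(disps - median)))]
    out = smooth_xy(pts, nc)
    np.testing.assert_allclose(out[i], expected, atol=1e-12)


def test_arc_lengths():
    pts = np.column_stack([np.arange(10.0), np.zeros(10)])
    keep, arc = compute_arc_lengths(pts, 0.55)
    assert keep.all()
    np.testing.assert_allclose(arc, 0.55 * np.arange(10))
    # quarter circle radius 20 px at 0.5 px steps: within 0.5% of analytic
    n = int(np.pi / 2 * 20 / 0.5)
    angles = np.linspace(0, np.pi / 2, n)
    circ = 20 * np.column_stack([np.cos(angles), np.sin(angles)])
    _, arc = compute_arc_lengths(circ, 0.7)
    assert arc[-1] == pytest.approx(np.pi / 2 * 20 * 0.7, rel=0.005)
    # duplicates merged
    dup = np.array([(0.0, 0.0), (0.0, 0.0), (3.0, 0.0)])
    keep, arc = compute_arc_lengths(dup, 1.0)
    np.testing.assert_array_equal(keep, [True, False, True])
    np.testing.assert_allclose(arc, [0.0, 3.0])


def test_smooth_z_widths():
    arc = np.arange(30.0)
    const = np.full(30, 2.0)
    np.testing.assert_allclose(smooth_z_widths(const, arc, 5, 10.0), const)
    ramp = 1.0 + 0.05 * arc
    spiked = ramp.copy()
    spiked[15] += 2.0
    out = smooth_z_widths(spiked, arc, 5, 10.0)
    assert abs(out[15] - ramp[15]) <= 0.2 * 2.0  # spike reduced >= 80%
    # zero arc-distance limit disables smoothing
    np.testing.assert_array_equal(smooth_z_widths(spiked, arc, 5, 0.0), spiked)
    # NaN widths (rejected fits) stay NaN and do not poison neighbours
    holey = ramp.copy()
    holey[10] = np.nan
    out = smooth_z_widths(holey, arc, 5, 10.0)
    assert np.isnan(out[10]) and np.isfinite(np.delete(out, 10)).all()


# ---------------------------------------------------------------------------
# two-pass contract
# ---------------------------------------------------------------------------


def test_second_pass_does_not_degrade_accuracy(small_mouse_render, mouse_settings):
    """After smoothing/refit, accepted-point RMS distance to the true
    centerline is no worse than after the first fit/centre pass."""
    from flagelliq.synthetic_renderer import polyline_distances
    from flagelliq.trace_reconstruction import rough_trace
    from flagelliq.trace_refinement import _fit_all, _head_mask, refine_trace

    stack, gt = small_mouse_render
    frame = stack.frames[0]
    px = stack.pixel_size
    pts = rough_trace(frame, mouse_settings)
    _, normals = compute_tangents_normals(pts, mouse_settings.max_vector_length_points)
    params, _, accepted = _fit_all(frame, pts, normals, mouse_settings, px)
    head = (
        _head_mask(pts, pts[0])
        if mouse_settings.exclude_head_from_correction
        else None
    )
    pass1 = center_correct(pts, normals, params[:, 2], accepted, head)
    rms1 = np.sqrt(
        (polyline_distances(pass1[accepted], gt.scoring_polyline(0)) ** 2).mean()
    )
    trace = refine_trace(frame, pts, mouse_settings, px)
    rms2 = np.sqrt(
        (
            polyline_distances(
                trace.points[trace.accepted], gt.scoring_polyline(0)
            )
            ** 2
        ).mean()
    )
    assert rms2 <= rms1 + 1e-9
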