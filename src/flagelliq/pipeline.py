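"""End-to-end analysis of one single-cell movie.

``analyze_stack`` runs the whole chain — background correction, per-frame
rough reconstruction and sub-pixel refinement, head and flagellar kinematic
parameters, kymographs, and frequency analysis — and returns an
:class:`AnalysisRun` that the reporting layer serialises to a result folder.
Frames where no flagellum can be reconstructed are logged and carried as
missing (their kymograph columns stay masked; short gaps are interpolated
by the frequency analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flagelliq import frequency_analysis as fa
from flagelliq import kinematics as kin
from flagelliq.imaging_io import ImageStack, RoiMask, correct_background
from flagelliq.kymographs_reporting import Kymograph, build_kymograph
from flagelliq.settings import Settings
from flagelliq.trace import FlagellarTrace
from flagelliq.trace_reconstruction import rough_trace
from flagelliq.trace_refinement import refine_trace

#: flagellar parameters assembled into kymographs
FLAGELLAR_PARAMETERS = (
    "head_frame_x_um",
    "head_frame_y_um",
    "tangential_angle_deg",
    "curvature_rad_per_um",
    "curvature_angle_deg",
    "z_width_px",
    "intensity",
)

#: flagellar parameters whose kymographs are frequency-analysed
FREQUENCY_PARAMETERS = ("curvature_angle_deg", "z_width_px", "head_frame_y_um")


@dataclass
class AnalysisRun:
    """Complete result set of one analysed movie."""

    settings: Settings
    fps: float
    pixel_size: float
    background_mode: str
    traces: list[FlagellarTrace | None]
    head_x_px: np.ndarray
    head_y_px: np.ndarray
    theta_deg: np.ndarray  # unwrapped over time
    rolling_max: np.ndarray
    per_frame_parameters: dict[str, list[tuple[np.ndarray, np.ndarray] | None]]
    kymographs: dict[str, Kymograph]
    head_frequencies: dict[str, fa.SpectrumSummary]
    flagellar_frequencies: dict[str, list[fa.SpectrumSummary | None]]
    log: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.traces)

    def trace_table(self) -> pd.DataFrame:
        rows = []
        for f, trace in enumerate(self.traces):
            if trace is None:
                continue
            for i in range(len(trace)):
                rows.append(
                    dict(
                        frame=f,
                        index=i,
                        x_px=trace.x[i],
                        y_px=trace.y[i],
                        arc_length_um=trace.arc_length_um[i],
                        fit_a=trace.fit_a[i],
                        fit_c=trace.fit_c[i],
                        fit_d=trace.fit_d[i],
                        fit_r2=trace.fit_r2[i],
                        accepted=bool(trace.accepted[i]),
                        z_width=trace.z_width[i],
                        intensity=trace.intensity[i],
                    )
                )
        return pd.DataFrame(rows)

    def head_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                frame=np.arange(self.n_frames),
                x_px=self.head_x_px,
                y_px=self.head_y_px,
                x_um=self.head_x_px * self.pixel_size,
                y_um=self.head_y_px * self.pixel_size,
                theta_deg=self.theta_deg,
                rolling_max=self.rolling_max,
            )
        )

    def head_frequency_table(self) -> pd.DataFrame:
        rows = [
            dict(
                parameter=name,
                primary_hz=s.primary_hz,
                secondary_hz=s.secondary_hz,
                com_hz=s.com_hz,
            )
            for name, s in self.head_frequencies.items()
        ]
        return pd.DataFrame(rows)

    def flagellar_frequency_table(self) -> pd.DataFrame:
        rows = []
        for name, summaries in self.flagellar_frequencies.items():
            centers = self.kymographs[name].bin_centers_um
            for center, s in zip(centers, summaries):
                if s is None:
                    continue
                rows.append(
                    dict(
                        parameter=name,
                        arc_length_um=center,
                        primary_hz=s.primary_hz,
                        secondary_hz=s.secondary_hz,
                        com_hz=s.com_hz,
                    )
                )
        return pd.DataFrame(rows)


def _resample_on_grid(
    pf: tuple[np.ndarray, np.ndarray] | None, bin_width_um: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Linearly interpolate one frame's (arc, value) series onto bin centres.

    Only grid positions inside the trace's own arc span are produced, so a
    short frame still leaves its distal bins masked."""
    if pf is None:
        return None
    arc, val = pf
    ok = np.isfinite(val) & np.isfinite(arc)
    if ok.sum() < 2:
        return pf
    grid = (np.arange(int(arc[ok].max() / bin_width_um) + 1) + 0.5) * bin_width_um
    grid = grid[(grid >= arc[ok].min()) & (grid <= arc[ok].max())]
    if grid.size == 0:
        return pf
    return grid, np.interp(grid, arc[ok], val[ok])


def _reconstruct_all(
    stack: ImageStack, settings: Settings, roi: RoiMask | None, log: list[str]
) -> list[np.ndarray | None]:
    """Rough traces for every frame, honouring the unify-start-points pass."""
    rough: list[np.ndarray | None] = []
    for f in range(stack.n_frames):
        try:
            rough.append(rough_trace(stack.frames[f], settings, roi))
        except ValueError as err:
            log.append(f"frame {f}: rough reconstruction failed ({err})")
            rough.append(None)
    if settings.unify_start_points:
        starts = np.array([r[0] for r in rough if r is not None])
        if len(starts):
            mean_start = starts.mean(axis=0)
            for r in rough:
                if r is not None:
                    r[0] = mean_start
    return rough


def analyze_stack(
    stack: ImageStack,
    settings: Settings,
    roi: RoiMask | None = None,
    background: str = "none",
    rolling_ball_radius_px: float = 10.0,
    kymograph_bin_width_um: float | None = None,
) -> AnalysisRun:
    """Run the full analysis chain on a calibrated single-cell stack."""
    log: list[str] = [
        f"frames={stack.n_frames} fps={stack.fps} pixel_size={stack.pixel_size} "
        f"background={background}"
    ]
    stack = correct_background(stack, background, rolling_ball_radius_px)
    rough = _reconstruct_all(stack, settings, roi, log)

    traces: list[FlagellarTrace | None] = []
    for f, pts in enumerate(rough):
        if pts is None:
            traces.append(None)
            continue
        try:
            traces.append(
                refine_trace(stack.frames[f], pts, settings, stack.pixel_size)
            )
        except ValueError as err:
            log.append(f"frame {f}: refinement failed ({err})")
            traces.append(None)

    n = stack.n_frames
    head_x = np.full(n, np.nan)
    head_y = np.full(n, np.nan)
    theta = np.full(n, np.nan)
    rolling = np.full(n, np.nan)
    per_frame: dict[str, list] = {name: [None] * n for name in FLAGELLAR_PARAMETERS}

    for f, trace in enumerate(traces):
        if trace is None:
            continue
        head_x[f], head_y[f] = trace.points[0]
        try:
            v, th = kin.head_midpiece_vector(
                trace, settings.reference_vector_arc_length_um
            )
        except ValueError as err:
            log.append(f"frame {f}: head-midpiece vector failed ({err})")
            continue
        theta[f] = th
        try:
            rolling[f] = kin.head_rolling_signal(
                stack.frames[f],
                trace.points[0],
                v,
                settings.head_rotation_matrix_radius_px,
            )
        except ValueError as err:
            log.append(f"frame {f}: rolling signal failed ({err})")
        hx, hy = kin.transform_to_head_frame(trace, v)
        arc = trace.arc_length_um
        per_frame["head_frame_x_um"][f] = (arc, hx)
        per_frame["head_frame_y_um"][f] = (arc, hy)
        per_frame["tangential_angle_deg"][f] = (arc, kin.tangential_angle(trace))
        per_frame["curvature_rad_per_um"][f] = (
            arc,
            kin.curvature(trace, settings.curvature_reference_distance_um),
        )
        per_frame["curvature_angle_deg"][f] = (
            arc,
            kin.curvature_angle(trace, settings.curvature_reference_distance_um),
        )
        per_frame["z_width_px"][f] = (arc, trace.z_width)
        per_frame["intensity"][f] = (arc, trace.intensity)

    theta = kin.unwrap_degrees(theta)

    # parameter values between trace points are defined by linear
    # interpolation along the polyline; evaluating each frame on the common
    # bin-centre grid keeps kymograph rows gap-free wherever the trace reaches
    bin_width = kymograph_bin_width_um or stack.pixel_size
    kymographs: dict[str, Kymograph] = {}
    for name in FLAGELLAR_PARAMETERS:
        try:
            kymographs[name] = build_kymograph(
                [_resample_on_grid(pf, bin_width) for pf in per_frame[name]],
                name,
                bin_width,
                stack.fps,
            )
        except ValueError as err:
            log.append(f"kymograph {name}: {err}")

    window = min(settings.fft_window_frames, n)
    head_frequencies: dict[str, fa.SpectrumSummary] = {}
    for name, signal in (("theta_deg", theta), ("rolling_max", rolling)):
        try:
            head_frequencies[name] = fa.analyze_signal(signal, stack.fps, window)[0][1]
        except ValueError as err:
            log.append(f"head frequency {name}: {err}")

    flagellar_frequencies: dict[str, list] = {}
    for name in FREQUENCY_PARAMETERS:
        if name not in kymographs:
            continue
        try:
            flagellar_frequencies[name] = fa.flagellar_frequency_map(
                kymographs[name],
                stack.fps,
                settings.fft_skip_initial_um,
                window,
            )
        except ValueError as err:
            log.append(f"flagellar frequency {name}: {err}")

    return AnalysisRun(
        settings=settings,
        fps=stack.fps,
        pixel_size=stack.pixel_size,
        background_mode=background,
        traces=traces,
        head_x_px=head_x,
        head_y_px=head_y,
        theta_deg=theta,
        rolling_max=rolling,
        per_frame_parameters=per_frame,
        kymographs=kymographs,
        head_frequencies=head_frequencies,
        flagellar_frequencies=flagellar_frequencies,
        log=log,
    )
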