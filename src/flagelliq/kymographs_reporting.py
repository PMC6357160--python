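"""Kymograph assembly and result export.

A kymograph collects one flagellar parameter over the whole movie as a
matrix of arc-length bins (rows) × frames (columns); cells average all
trace points of a frame falling into the bin, and bins a frame's trace does
not reach are masked (NaN). Kymographs, per-frame traces, head parameters
and frequency summaries are exported as CSV into one folder per analysed
cell, together with a settings snapshot and a log, so a run can be
reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from flagelliq.pipeline import AnalysisRun

#: fixed rendering ranges per parameter so heatmaps are comparable across runs;
#: parameters not listed autoscale symmetrically (diverging) or to data (sequential)
HEATMAP_SCALES: dict[str, tuple[float, float, str]] = {
    "curvature_angle_deg": (-90.0, 90.0, "RdBu_r"),
    "curvature_rad_per_um": (-0.5, 0.5, "RdBu_r"),
    "head_frame_y_um": (-20.0, 20.0, "RdBu_r"),
    "head_frame_x_um": (-60.0, 60.0, "RdBu_r"),
    "tangential_angle_deg": (-180.0, 180.0, "twilight"),
}


@dataclass
class Kymograph:
    """Arc-length × time matrix of one flagellar parameter."""

    parameter: str
    bin_edges_um: np.ndarray
    times_s: np.ndarray
    values: np.ndarray  # (n_bins, n_frames), NaN where masked

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.bin_edges_um.size - 1, self.times_s.size):
            raise ValueError(
                f"value matrix {self.values.shape} does not match "
                f"{self.bin_edges_um.size - 1} bins × {self.times_s.size} frames"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where a cell holds no data."""
        return ~np.isfinite(self.values)

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with arc-length bin centres as index, times as columns."""
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.bin_centers_um, name="arc_length_um"),
            columns=[repr(float(t)) for t in self.times_s],
        )
        # shortest round-tripping float repr keeps the CSV bit-exact
        df.to_csv(path, float_format=lambda v: repr(float(v)))

    @classmethod
    def from_csv(cls, path: str | Path, parameter: str = "") -> "Kymograph":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        centers = df.index.to_numpy(dtype=float)
        width = centers[1] - centers[0] if centers.size > 1 else 1.0
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        times = np.array([float(c) for c in df.columns])
        return cls(parameter, edges, times, df.to_numpy(dtype=float))

    def save_heatmap(self, path: str | Path) -> None:
        """Render a PNG heatmap with the documented fixed colour scale."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vmin, vmax, cmap = HEATMAP_SCALES.get(
            self.parameter, (None, None, "viridis")
        )
        fig, ax = plt.subplots(figsize=(6, 4))
        extent = (
            float(self.times_s[0]),
            float(self.times_s[-1]) if self.times_s.size > 1 else 1.0,
            float(self.bin_edges_um[-1]),
            float(self.bin_edges_um[0]),
        )
        im = ax.imshow(
            self.values, aspect="auto", extent=extent, vmin=vmin, vmax=vmax, cmap=cmap
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("arc length (µm)")
        ax.set_title(self.parameter)
        fig.colorbar(im, ax=ax)
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_kymograph(
    per_frame: Sequence[tuple[np.ndarray, np.ndarray] | None],
    parameter: str,
    bin_width_um: float,
    fps: float,
) -> Kymograph:
    """Bin per-frame (arc length, value) series into a kymograph.

    ``per_frame`` holds one ``(arc_lengths_um, values)`` pair per frame
    (None for failed frames). Each value is assigned to the bin containing
    its arc length; multiple points in one bin are averaged; bins a frame
    does not reach stay masked for that frame only.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    valid = [pf for pf in per_frame if pf is not None and pf[0].size > 0]
    if not valid:
        raise ValueError("no valid frames to build a kymograph from")
    max_arc = max(float(arc.max()) for arc, _ in valid)
    n_bins = max(1, int(np.ceil(max_arc / bin_width_um + 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width_um
    n_frames = len(per_frame)
    values = np.full((n_bins, n_frames), np.nan)
    for f, pf in enumerate(per_frame):
        if pf is None or pf[0].size == 0:
            continue
        arc, val = pf
        finite = np.isfinite(val) & np.isfinite(arc)
        if not finite.any():
            continue
        idx = np.clip((arc[finite] / bin_width_um).astype(int), 0, n_bins - 1)
        sums = np.bincount(idx, weights=val[finite], minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            values[:, f] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    times = np.arange(n_frames) / fps
    return Kymograph(parameter, edges, times, values)


def export_results(run: "AnalysisRun", out_dir: str | Path) -> list[Path]:
    """Write the complete result set of one analysed cell to a folder.

    Files: ``trace.csv`` (per-frame per-point trace with fit descriptors),
    ``head.csv`` (per-frame head parameters), one ``kymograph_<param>.csv``
    plus ``kymograph_<param>.png`` per flagellar parameter,
    ``frequency_head.csv`` and ``frequency_flagellar.csv`` (peak/COM
    summaries), ``settings.json`` (snapshot sufficient to reproduce the
    run bit-identically) and ``log.txt``. Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    _write("trace.csv", lambda p: run.trace_table().to_csv(p, index=False))
    _write("head.csv", lambda p: run.head_table().to_csv(p, index=False))
    for name, kymo in run.kymographs.items():
        _write(f"kymograph_{name}.csv", kymo.to_csv)
        _write(f"kymograph_{name}.png", kymo.save_heatmap)
    _write(
        "frequency_head.csv", lambda p: run.head_frequency_table().to_csv(p, index=False)
    )
    _write(
        "frequency_flagellar.csv",
        lambda p: run.flagellar_frequency_table().to_csv(p, index=False),
    )
    snapshot = {
        "settings": run.settings.to_dict(),
        "fps": run.fps,
        "pixel_size_um": run.pixel_size,
        "background_mode": run.background_mode,
    }
    _write("settings.json", lambda p: p.write_text(json.dumps(snapshot, indent=2)))
    _write("log.txt", lambda p: p.write_text("\n".join(run.log) + "\n"))
    return written
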