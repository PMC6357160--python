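"""Analysis settings governing every pipeline stage.

The parameter block mirrors the settings dialogue of skeleton-based flagellar
tracking tools: a thresholding method, the Gaussian blur sigma, point-list
upscaling, the normal-line radius for the cross-profile Gaussian fits, the
smoothing neighbourhoods, the reference arc lengths for the head-midpiece
vector and for curvature, and the FFT window length.

Two presets are shipped: ``Settings.mouse()`` (tethered mouse sperm recorded
at 200 fps, 16× magnification) and ``Settings.human()`` (freely swimming
human sperm at 500 fps, 20×).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

_THRESHOLD_METHODS = ("li", "triangle", "otsu")


@dataclass
class Settings:
    """Parameter block for one analysis run.

    All distances are physical (µm) unless the name says ``_px`` or
    ``_points``; they are converted to pixels internally using the stack's
    pixel size.
    """

    #: histogram thresholding algorithm: "li", "triangle" or "otsu"
    threshold_method: str = "li"
    #: sigma of the Gaussian blur applied before (and optionally after) binarization, px
    gauss_sigma: float = 3.0
    #: blur the binary mask again with the same sigma and re-binarize before skeletonizing
    repeat_gauss_after_binarization: bool = False
    #: restrict the Gaussian blur to the user ROI
    blur_only_inside_roi: bool = True
    #: linear point-list upscaling factor (fold 3 inserts two points per pair)
    upscaling_fold: int = 3
    #: prepend the intensity-weighted centre of mass of the head disk as first point
    add_head_com_first_point: bool = False
    #: replace every frame's first point by the across-frames mean start position
    unify_start_points: bool = False
    #: drop points whose Gaussian fit fails the acceptance criteria (second pass)
    filter_points_by_fits: bool = False
    #: tangent support: vector from i-k to i+k with k = max_vector_length_points // 2
    max_vector_length_points: int = 14
    #: half-length of each normal line for the cross-profile Gaussian fit, µm
    normal_radius_um: float = 5.0
    #: do not shift (or delete) points inside the head region
    exclude_head_from_correction: bool = True
    #: 3-tap moving-average smoothing of the normal profile before fitting
    smooth_normal_profile: bool = True
    #: write per-frame skeletons and rough traces next to the results
    save_intermediates: bool = False
    #: neighbours beyond this arc-length distance are ignored when smoothing z-widths, µm
    z_smoothing_arc_distance_um: float = 9.6
    #: number of upstream/downstream neighbours for xy- and width-smoothing
    smoothing_neighbor_count: int = 15
    #: arc length of the point forming the head-midpiece reference vector, µm
    reference_vector_arc_length_um: float = 10.0
    #: arc-length distance between the two tangents compared for curvature, µm
    curvature_reference_distance_um: float = 10.0
    #: FFT window length in frames (windows are slid if shorter than the movie)
    fft_window_frames: int = 200
    #: skip frequency analysis of flagellar positions at arc length <= this, µm
    fft_skip_initial_um: float = 0.0
    #: half-length of the head cross-sectioning line for the rolling signal, px
    head_rotation_matrix_radius_px: float = 10.0

    def __post_init__(self) -> None:
        if self.threshold_method not in _THRESHOLD_METHODS:
            raise ValueError(
                f"threshold_method must be one of {_THRESHOLD_METHODS}, "
                f"got {self.threshold_method!r}"
            )
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be > 0")
        if self.upscaling_fold < 1:
            raise ValueError("upscaling_fold must be >= 1")
        if self.max_vector_length_points < 2:
            raise ValueError("max_vector_length_points must be >= 2")
        if self.normal_radius_um <= 0:
            raise ValueError("normal_radius_um must be > 0")
        if self.fft_window_frames < 2:
            raise ValueError("fft_window_frames must be >= 2")
        for name in (
            "z_smoothing_arc_distance_um",
            "reference_vector_arc_length_um",
            "curvature_reference_distance_um",
            "fft_skip_initial_um",
            "head_rotation_matrix_radius_px",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.smoothing_neighbor_count < 1:
            raise ValueError("smoothing_neighbor_count must be >= 1")

    # -- presets ---------------------------------------------------------

    @classmethod
    def mouse(cls) -> "Settings":
        """Preset for head-tethered mouse sperm (200 fps, 16×, ~0.69 µm/px)."""
        return cls()

    @classmethod
    def human(cls) -> "Settings":
        """Preset for freely swimming human sperm (500 fps, 20×, 0.55 µm/px)."""
        return cls(
            threshold_method="triangle",
            gauss_sigma=2.0,
            repeat_gauss_after_binarization=True,
            blur_only_inside_roi=False,
            max_vector_length_points=20,
            normal_radius_um=6.0,
            exclude_head_from_correction=False,
            reference_vector_arc_length_um=6.4,
            fft_window_frames=500,
        )

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Settings":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown settings keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "Settings":
        """Load settings from a YAML or JSON file keyed by field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"settings file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **kwargs: Any) -> "Settings":
        return dataclasses.replace(self, **kwargs)
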