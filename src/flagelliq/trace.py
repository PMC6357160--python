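"""Container for a refined per-frame flagellar trace."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FlagellarTrace:
    """Ordered, head-first, sub-pixel flagellar point list with descriptors.

    Per point: position (px), unit tangent/normal, arc length (µm),
    cross-profile Gaussian-fit parameters (height ``fit_a`` above baseline,
    centre offset ``fit_c`` along the normal in px, width ``fit_d`` in px,
    goodness ``fit_r2``), the acceptance flag of the fit, the smoothed width
    ``z_width`` (relative, uncalibrated z proxy) and the fit height as
    ``intensity``. Rejected fits carry NaN parameters.
    """

    x: np.ndarray
    y: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray
    arc_length_um: np.ndarray
    fit_a: np.ndarray
    fit_c: np.ndarray
    fit_d: np.ndarray
    fit_r2: np.ndarray
    fit_baseline: np.ndarray
    accepted: np.ndarray
    z_width: np.ndarray
    intensity: np.ndarray
    pixel_size: float

    def __len__(self) -> int:
        return self.x.size

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (x, y) pixel coordinates."""
        return np.column_stack([self.x, self.y])

    @property
    def length_um(self) -> float:
        """Total arc length of the trace in µm."""
        return float(self.arc_length_um[-1]) if len(self) else 0.0

    def point_at_arc_length(self, s_um: float) -> np.ndarray:
        """(x, y) at arc length ``s_um``, linearly interpolated on the polyline."""
        s = np.clip(s_um, self.arc_length_um[0], self.arc_length_um[-1])
        x = np.interp(s, self.arc_length_um, self.x)
        y = np.interp(s, self.arc_length_um, self.y)
        return np.array([x, y])

    def tangent_at_arc_length(self, s_um: float) -> np.ndarray:
        """Unit tangent at arc length ``s_um`` (nearest-point interpolation of
        the per-point tangents, renormalised)."""
        s = np.clip(s_um, self.arc_length_um[0], self.arc_length_um[-1])
        tx = np.interp(s, self.arc_length_um, self.tangent[:, 0])
        ty = np.interp(s, self.arc_length_um, self.tangent[:, 1])
        t = np.array([tx, ty])
        n = np.linalg.norm(t)
        return t / n if n > 0 else t

    def mask(self, keep: np.ndarray) -> "FlagellarTrace":
        """New trace retaining only the rows where ``keep`` is True."""
        return FlagellarTrace(
            self.x[keep],
            self.y[keep],
            self.tangent[keep],
            self.normal[keep],
            self.arc_length_um[keep],
            self.fit_a[keep],
            self.fit_c[keep],
            self.fit_d[keep],
            self.fit_r2[keep],
            self.fit_baseline[keep],
            self.accepted[keep],
            self.z_width[keep],
            self.intensity[keep],
            self.pixel_size,
        )
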