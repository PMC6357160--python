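"""FFT-based frequency analysis of time-resolved beat parameters.

Every time series (head parameters, and each flagellar parameter at each
arc-length position) is mean-subtracted and transformed with a discrete
Fourier transform (rectangular window, one-sided amplitude spectrum scaled
by 2/W, DC bin excluded). Each spectrum is summarised by the primary peak
(highest local maximum), the secondary peak (second-highest local maximum
at a non-adjacent bin, so spectral-leakage shoulders of the primary do not
masquerade as a second peak) and the amplitude-weighted centre of mass
(COM) of the spectrum.

When the configured window is shorter than the series, the window is slid
along the series at a stride of one frame and a spectrum is produced per
window position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from flagelliq.kymographs_reporting import Kymograph

MAX_MISSING_FRACTION = 0.10


@dataclass
class Spectrum:
    """One-sided amplitude spectrum of a time window.

    ``frequencies[k] = (k+1) * fps / window`` (DC excluded), amplitudes are
    non-negative; the spectrum covers frequencies up to the Nyquist limit
    fps/2.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    window: int
    start_frame: int = 0


@dataclass
class SpectrumSummary:
    """Primary and secondary peak frequencies and spectrum centre of mass (Hz).

    Missing values (no secondary local maximum; zero spectrum) are NaN."""

    primary_hz: float
    secondary_hz: float
    com_hz: float


def _fill_missing(signal: np.ndarray) -> np.ndarray:
    signal = np.asarray(signal, dtype=float)
    bad = ~np.isfinite(signal)
    if not bad.any():
        return signal
    frac = bad.mean()
    if frac > MAX_MISSING_FRACTION:
        raise ValueError(
            f"{bad.sum()} of {signal.size} frames missing "
            f"(frames {np.nonzero(bad)[0].tolist()}); at most "
            f"{MAX_MISSING_FRACTION:.0%} may be interpolated"
        )
    good = np.nonzero(~bad)[0]
    filled = signal.copy()
    filled[bad] = np.interp(np.nonzero(bad)[0], good, signal[good])
    return filled


def amplitude_spectrum(signal: np.ndarray, fps: float, start_frame: int = 0) -> Spectrum:
    """One-sided amplitude spectrum of the mean-subtracted signal, DC dropped.

    Up to 10% missing frames (NaN) are filled by linear interpolation before
    the transform; more than that raises, listing the failed frames.
    """
    signal = _fill_missing(signal)
    w = signal.size
    if w < 2:
        raise ValueError("signal must have at least 2 samples")
    spectrum = np.fft.rfft(signal - signal.mean())
    amps = np.abs(spectrum) * 2.0 / w
    freqs = np.fft.rfftfreq(w, d=1.0 / fps)
    return Spectrum(freqs[1:], amps[1:], w, start_frame)


def sliding_window_spectra(
    signal: np.ndarray, window_frames: int, fps: float
) -> list[Spectrum]:
    """Spectra of every length-``window_frames`` window at stride 1.

    A window equal to the series length yields a single spectrum."""
    signal = np.asarray(signal, dtype=float)
    if window_frames > signal.size:
        raise ValueError(
            f"window of {window_frames} frames exceeds signal length {signal.size}"
        )
    return [
        amplitude_spectrum(signal[s : s + window_frames], fps, start_frame=s)
        for s in range(signal.size - window_frames + 1)
    ]


def _local_maxima(amps: np.ndarray) -> np.ndarray:
    """Indices of local maxima: positive amplitude, >= both neighbours
    (one-sided at the edges). A flat spectrum has no peaks."""
    left = np.concatenate([[-np.inf], amps[:-1]])
    right = np.concatenate([amps[1:], [-np.inf]])
    is_max = (amps >= left) & (amps >= right) & (amps > 0)
    if np.all(amps == amps[0]):
        return np.array([], dtype=int)
    return np.nonzero(is_max)[0]


def find_primary_secondary(spectrum: Spectrum) -> SpectrumSummary:
    """Primary and secondary peak of a spectrum.

    The primary frequency is the highest local maximum of the amplitude
    sequence; the secondary is the second-highest local maximum at a bin not
    adjacent to the primary. Amplitude ties go to the lower frequency. A
    spectrum without local maxima reports the global maximum as primary and
    a missing (NaN) secondary.
    """
    amps = spectrum.amplitudes
    if amps.size < 3:
        raise ValueError("need at least 3 bins")
    maxima = _local_maxima(amps)
    com = spectrum_com(spectrum)
    if maxima.size == 0:
        return SpectrumSummary(
            float(spectrum.frequencies[int(np.argmax(amps))]), np.nan, com
        )
    order = maxima[np.lexsort((maxima, -amps[maxima]))]  # amp desc, freq asc
    primary = int(order[0])
    secondary = np.nan
    for idx in order[1:]:
        if abs(int(idx) - primary) > 1:
            secondary = float(spectrum.frequencies[int(idx)])
            break
    return SpectrumSummary(float(spectrum.frequencies[primary]), secondary, com)


def spectrum_com(spectrum: Spectrum) -> float:
    """Amplitude-weighted mean frequency over all non-DC bins (NaN if empty)."""
    total = spectrum.amplitudes.sum()
    if total <= 0:
        return np.nan
    return float((spectrum.frequencies * spectrum.amplitudes).sum() / total)


def analyze_signal(
    signal: np.ndarray, fps: float, window_frames: int | None = None
) -> list[tuple[Spectrum, SpectrumSummary]]:
    """Spectra plus summaries for a series, sliding the window if shorter."""
    signal = np.asarray(signal, dtype=float)
    if window_frames is None or window_frames >= signal.size:
        spectra = [amplitude_spectrum(signal, fps)]
    else:
        spectra = sliding_window_spectra(signal, window_frames, fps)
    return [(s, find_primary_secondary(s)) for s in spectra]


def flagellar_frequency_map(
    kymograph: Kymograph,
    fps: float,
    skip_initial_um: float = 0.0,
    window_frames: int | None = None,
) -> list[SpectrumSummary | None]:
    """Per-arc-length-bin spectrum summary of a kymograph.

    Every row whose bin centre lies beyond ``skip_initial_um`` is analysed
    independently (full-series spectrum, or the first window when a shorter
    window is configured); rows at or below the cutoff are skipped and
    reported as None, keeping the output aligned with the kymograph rows.
    """
    centers = kymograph.bin_centers_um
    results: list[SpectrumSummary | None] = []
    n_analyzed = 0
    for row, center in zip(kymograph.values, centers):
        if center <= skip_initial_um:
            results.append(None)
            continue
        try:
            spectra = analyze_signal(row, fps, window_frames)
        except ValueError:
            results.append(None)
            continue
        results.append(spectra[0][1])
        n_analyzed += 1
    if n_analyzed == 0:
        raise ValueError(
            "no arc-length rows left to analyse (cutoff beyond flagellum length "
            "or all rows invalid)"
        )
    return results
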