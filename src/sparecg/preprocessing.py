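"""R-peak detection, average cycle length and amplitude normalisation.

The attractor construction downstream needs exactly one number from this
module: the average cycle length L, the mean spacing of successive R peaks.
The detector is a Pan–Tompkins-style pipeline (band-pass emphasis of the QRS
band, differentiation, squaring, moving-window integration, threshold with a
refractory period); since only the mean RR interval is consumed, the precise
detector choice has second-order effect on the features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


class InsufficientBeatsError(ValueError):
    """Fewer than two R peaks were found; the record cannot be embedded."""


@dataclass(frozen=True)
class CycleEstimate:
    """Average cardiac cycle length derived from R-peak positions."""

    r_peak_indices: np.ndarray
    L_samples: float
    L_seconds: float


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Locate R peaks in a single-channel ECG.

    Pipeline: 5–15 Hz band-pass (QRS emphasis), derivative, squaring,
    150 ms moving-window integration, adaptive threshold, 200 ms refractory
    period, then refinement of each detection to the local maximum of the
    band-passed signal within ±50 ms.

    Parameters
    ----------
    signal : array of millivolt samples, at least 2 s long.
    fs : sampling frequency in Hz.

    Returns
    -------
    Strictly increasing sample indices of detected R peaks.

    Raises
    ------
    InsufficientBeatsError
        If fewer than two peaks are found (e.g. a flat signal).
    """
    x = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.size < 2 * fs:
        raise ValueError("signal must be at least 2 s long for peak detection")
    if np.ptp(x) == 0:
        raise InsufficientBeatsError("flat signal: no beats detectable")

    nyq = fs / 2
    low, high = 5 / nyq, min(15 / nyq, 0.99)
    b, a = sps.butter(2, [low, high], btype="band")
    band = sps.filtfilt(b, a, x)

    deriv = np.gradient(band)
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = max(1, int(round(0.200 * fs)))
    threshold = 0.3 * np.percentile(integrated, 99)
    peaks, _ = sps.find_peaks(integrated, height=threshold, distance=refractory)
    if peaks.size < 2:
        raise InsufficientBeatsError(
            f"only {peaks.size} beat(s) detected; need at least 2"
        )

    # refine each detection to the local max of the QRS-emphasised signal
    half = max(1, int(round(0.050 * fs)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(band[lo:hi])))
    refined = np.unique(refined)

    # re-enforce the refractory period after refinement
    kept = [int(refined[0])]
    for idx in refined[1:]:
        if idx - kept[-1] >= refractory:
            kept.append(int(idx))
        elif band[idx] > band[kept[-1]]:
            kept[-1] = int(idx)
    if len(kept) < 2:
        raise InsufficientBeatsError("fewer than 2 beats after refinement")
    return np.asarray(kept, dtype=int)


def average_cycle_length(r_peaks: np.ndarray, fs: float) -> CycleEstimate:
    """Average cycle length L: the mean spacing of successive R peaks."""
    peaks = np.asarray(r_peaks, dtype=int)
    if peaks.size < 2:
        raise ValueError("need at least 2 R peaks to estimate a cycle length")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("R-peak indices must be strictly increasing")
    if fs <= 0:
        raise ValueError("fs must be positive")
    L_samples = float(np.mean(np.diff(peaks)))
    return CycleEstimate(r_peak_indices=peaks, L_samples=L_samples,
                         L_seconds=L_samples / fs)


def normalize_amplitude(signal: np.ndarray) -> np.ndarray:
    """Min–max normalise a signal to exactly [0, 1].

    Removes per-record gain so that attractor densities are comparable
    across records.  Idempotent, and invariant to positive affine
    transforms of the input.
    """
    x = np.asarray(signal, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        raise ValueError("zero amplitude range: constant signal cannot be normalised")
    return (x - lo) / (hi - lo)
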