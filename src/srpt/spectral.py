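"""Oscillatory power: high-pass filtering, per-trial FFT power, band power.

Power convention
----------------
Per-trial spectra use a rectangular window (no taper) on the 1 s stationary
segment 0.5-1.5 s after stimulus onset, so at 1 kHz the bin spacing is
exactly 1 Hz.  The reported power in each bin is the squared magnitude of
the amplitude-normalized complex Fourier coefficient, ``|X_k / N|**2``,
cropped one-sided to 1-100 Hz *without* doubling.  Under this convention a
sinusoid of amplitude *a* at an integer frequency puts ``a**2 / 4`` into its
bin, and the two-sided sum of ``|X_k / N|**2`` equals the mean-square of the
segment (Parseval).  Band power is the sum of bin powers, both band edges
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .vep import TrialMatrix

__all__ = [
    "PowerSpectrum",
    "highpass",
    "trial_spectrum",
    "average_spectra",
    "band_power",
    "spectra_from_matrix",
]

CROP_LO_HZ = 1.0
CROP_HI_HZ = 100.0
STATIONARY_WINDOW_MS = (500.0, 1500.0)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray            # Hz, uniform spacing
    power: np.ndarray            # microvolts^2 per bin
    n_trials: int
    window: tuple[float, float]  # ms relative to stimulus onset

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def highpass(
    series: np.ndarray,
    sample_rate: float = 1000.0,
    order: int = 9,
    cutoff_hz: float = 0.5,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass to remove slow drifts.

    Applied forward-backward (``sosfiltfilt``) so evoked-component latencies
    measured downstream are not skewed by filter delay.
    """
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    x = np.asarray(series, dtype=float)
    try:
        return signal.sosfiltfilt(sos, x)
    except ValueError as err:
        raise ValueError("series shorter than the filter padding requirement") from err


def trial_spectrum(
    epoch: np.ndarray,
    sample_rate: float = 1000.0,
    epoch_window: tuple[float, float] | None = None,
    window: tuple[float, float] = STATIONARY_WINDOW_MS,
    crop: bool = True,
) -> PowerSpectrum:
    """Fourier power of one trial's stationary window.

    ``epoch`` is a single trial's voltage; ``epoch_window`` gives its time
    extent in ms relative to stimulus onset (defaults to starting at 0).
    With ``crop=False`` the full one-sided grid from DC to Nyquist is
    returned (useful for Parseval checks); otherwise bins are cropped to
    1-100 Hz.
    """
    x = np.asarray(epoch, dtype=float)
    if epoch_window is None:
        epoch_window = (0.0, len(x) * 1000.0 / sample_rate)
    lo, hi = window
    if lo < epoch_window[0] - 1e-9 or hi > epoch_window[1] + 1e-9:
        raise ValueError("analysis window not fully covered by the epoch")
    i0 = int(round((lo - epoch_window[0]) * sample_rate / 1000.0))
    i1 = int(round((hi - epoch_window[0]) * sample_rate / 1000.0))
    seg = x[i0:i1]
    n = len(seg)
    coeffs = np.fft.rfft(seg) / n
    power = np.abs(coeffs) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    if crop:
        mask = (freqs >= CROP_LO_HZ) & (freqs <= CROP_HI_HZ)
        freqs, power = freqs[mask], power[mask]
    return PowerSpectrum(freqs=freqs, power=power, n_trials=1, window=window)


def spectra_from_matrix(
    matrix: TrialMatrix,
    window: tuple[float, float] = STATIONARY_WINDOW_MS,
    prefilter: bool = False,
) -> PowerSpectrum:
    """Per-trial spectra of an epoched matrix, trial-averaged.

    ``prefilter`` optionally applies the drift high-pass per epoch; the
    default pipeline filters the continuous record before epoching instead.
    """
    spectra = []
    for row in matrix.values:
        x = highpass(row, matrix.sample_rate) if prefilter else row
        spectra.append(
            trial_spectrum(
                x,
                sample_rate=matrix.sample_rate,
                epoch_window=matrix.window,
                window=window,
            )
        )
    return average_spectra(spectra)


def average_spectra(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Pointwise mean across trials; trial counts accumulate."""
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if len(s.freqs) != len(f0) or not np.allclose(s.freqs, f0):
            raise ValueError("frequency grids do not match")
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(
        freqs=f0.copy(),
        power=power,
        n_trials=sum(s.n_trials for s in spectra),
        window=spectra[0].window,
    )


def band_power(spectrum: PowerSpectrum, lo_hz: float = 1.0, hi_hz: float = 30.0) -> float:
    """Sum of bin powers with lo <= f <= hi (both edges inclusive)."""
    mask = (spectrum.freqs >= lo_hz - 1e-9) & (spectrum.freqs <= hi_hz + 1e-9)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(spectrum.power[mask].sum())
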