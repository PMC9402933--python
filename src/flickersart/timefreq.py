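"""Morlet time-frequency decomposition, inter-trial coherence, ERSP.

The SSVEP is quantified at Oz on an 8–30 Hz grid with 0.5 Hz spacing, with
wavelet length growing linearly from 5 cycles at 8 Hz to 9.375 cycles at
30 Hz. Inter-trial coherence (phase-locking value) is the magnitude of the
mean unit-normalized complex coefficient across trials — 0 for random
phases, 1 for perfect locking. ERSP is absolute trial-averaged power in dB
(no baseline division): the study's reported ERSP magnitudes (~48–52 dB)
are only compatible with an absolute measure.

Summary statistics are means over a frequency × time window, canonically
12–13 Hz (fundamental) or 24.5–25.5 Hz (harmonic) × 500–900 ms — the span
where the SSVEP is fully developed but not yet decaying.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .containers import EpochSet

__all__ = [
    "DEFAULT_FREQS",
    "FUNDAMENTAL_RANGE",
    "HARMONIC_RANGE",
    "SSVEP_WINDOW",
    "TFResult",
    "cycles_at",
    "morlet_decompose",
    "itc",
    "ersp",
    "band_window_mean",
]

#: analysis grid: 8–30 Hz at 0.5 Hz spacing
DEFAULT_FREQS = np.arange(8.0, 30.0 + 1e-9, 0.5)
FUNDAMENTAL_RANGE = (12.0, 13.0)
HARMONIC_RANGE = (24.5, 25.5)
SSVEP_WINDOW = (500.0, 900.0)

ERSP_FLOOR_DB = -300.0


def cycles_at(
    freq,
    c_low: float = 5.0,
    f_low: float = 8.0,
    c_high: float = 9.375,
    f_high: float = 30.0,
):
    """Wavelet length in cycles at ``freq``: linear between the two anchors.

    c(f) = c_low + (f − f_low)·(c_high − c_low)/(f_high − f_low), with the
    default anchors 5 cycles at 8 Hz and 9.375 cycles at 30 Hz.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f < f_low - 1e-9) or np.any(f > f_high + 1e-9):
        raise ValueError(f"freq must lie in [{f_low}, {f_high}] Hz")
    out = c_low + (f - f_low) * (c_high - c_low) / (f_high - f_low)
    return float(out) if np.isscalar(freq) else out


@dataclass
class TFResult:
    """Complex Morlet coefficients at one electrode plus derived maps.

    ``coeffs``: (n_trials, n_freqs, n_times) complex; ``itc`` in [0, 1] and
    ``ersp`` in dB are (n_freqs, n_times).
    """

    freqs: np.ndarray
    times: np.ndarray  # ms
    electrode: str
    coeffs: np.ndarray
    itc: Optional[np.ndarray] = None
    ersp: Optional[np.ndarray] = None


def morlet_decompose(
    epochs: EpochSet,
    electrode: str = "Oz",
    freqs: Sequence[float] = DEFAULT_FREQS,
    compute_maps: bool = True,
) -> TFResult:
    """Complex Morlet coefficients per trial/frequency/time at one electrode.

    Wavelet convolution runs on the full epoch span (canonically −500..1300
    ms) so that the 500–900 ms summary window sits clear of edge effects.
    Raises when the epoch is shorter than the longest wavelet.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, dtype=float)
    n_cycles = cycles_at(freqs)
    longest = n_cycles[0] / freqs[0]  # s, lowest frequency = longest wavelet
    span = (epochs.times[-1] - epochs.times[0]) / 1000.0
    if span < longest:
        need = (longest - span) * 1000.0
        raise ValueError(
            f"epoch span {span * 1000:.0f} ms shorter than the longest wavelet; "
            f"pad by at least {need:.0f} ms"
        )
    data = epochs.get_channel(electrode)[:, None, :]  # trials x 1 x samples
    coeffs = tfr_array_morlet(
        data,
        sfreq=epochs.fs,
        freqs=freqs,
        n_cycles=n_cycles,
        output="complex",
        zero_mean=True,
    )[:, 0]  # -> trials x freqs x times
    result = TFResult(
        freqs=freqs, times=epochs.times.copy(), electrode=electrode, coeffs=coeffs
    )
    if compute_maps:
        result.itc = itc(coeffs)
        result.ersp = ersp(coeffs)
    return result


def itc(coeffs: np.ndarray) -> np.ndarray:
    """Inter-trial coherence: |mean of unit-normalized coefficients|.

    Trials whose coefficient is exactly zero at a cell carry no phase and are
    excluded from that cell's mean; a cell with no valid trial gets ITC 0.
    """
    coeffs = np.asarray(coeffs)
    if coeffs.ndim != 3 or coeffs.shape[0] < 2:
        raise ValueError("need (trials, freqs, times) with >= 2 trials")
    mag = np.abs(coeffs)
    valid = mag > 0
    unit = np.zeros_like(coeffs)
    np.divide(coeffs, mag, out=unit, where=valid)
    count = valid.sum(axis=0)
    resultant = np.abs(unit.sum(axis=0))
    out = np.zeros(coeffs.shape[1:], dtype=float)
    np.divide(resultant, count, out=out, where=count > 0)
    return np.clip(out, 0.0, 1.0)


def ersp(coeffs: np.ndarray) -> np.ndarray:
    """Absolute event-related spectral power: 10·log10(mean |coeff|²) dB.

    All-zero cells are floored at −300 dB instead of −inf.
    """
    coeffs = np.asarray(coeffs)
    if coeffs.ndim != 3 or coeffs.shape[0] < 1:
        raise ValueError("need (trials, freqs, times) with >= 1 trial")
    power = np.mean(np.abs(coeffs) ** 2, axis=0)
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(power)
    return np.maximum(out, ERSP_FLOOR_DB)


def band_window_mean(
    tf_map: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    f_range: Tuple[float, float],
    t_range: Tuple[float, float] = SSVEP_WINDOW,
) -> float:
    """Mean of map cells with freq ∈ f_range and time ∈ t_range (inclusive)."""
    fmask = (freqs >= f_range[0] - 1e-9) & (freqs <= f_range[1] + 1e-9)
    tmask = (times >= t_range[0] - 1e-9) & (times <= t_range[1] + 1e-9)
    if not fmask.any() or not tmask.any():
        raise ValueError("empty frequency/time selection")
    return float(np.mean(np.asarray(tf_map)[np.ix_(fmask, tmask)]))


def single_trial_band_window_mean(
    coeffs: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    f_range: Tuple[float, float],
    t_range: Tuple[float, float] = SSVEP_WINDOW,
) -> np.ndarray:
    """Per-trial ERSP band-window mean (dB), for classifier features."""
    coeffs = np.asarray(coeffs)
    fmask = (freqs >= f_range[0] - 1e-9) & (freqs <= f_range[1] + 1e-9)
    tmask = (times >= t_range[0] - 1e-9) & (times <= t_range[1] + 1e-9)
    if not fmask.any() or not tmask.any():
        raise ValueError("empty frequency/time selection")
    power = np.abs(coeffs[:, fmask][:, :, tmask]) ** 2
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(np.maximum(power.mean(axis=(1, 2)), 1e-30))
    return db
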