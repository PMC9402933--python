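"""Filter–Hilbert band power for alpha (8–12 Hz) and theta (4–8 Hz).

Each band is isolated with a least-squares FIR kernel designed on a
plateau-shaped desired response [0 0 1 1 0 0] with a fractional transition
width of 0.2 and order = sampling rate / lower band edge (64 taps for alpha,
128 for theta at 512 Hz). The kernel is applied zero-phase to the full
−500..1300 ms epoch (so edges stay outside the analysis windows); the
Hilbert transform yields the analytic signal, whose Welch power spectral
density over the pre-stimulus (−200..0 ms) or post-stimulus (0..900 ms)
interval is reduced to a single scalar per trial: the square of the mean
in-band PSD magnitude. ``mode="conventional"`` replaces that reduction with
the mean squared analytic amplitude.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet

__all__ = [
    "BANDS",
    "POWER_ELECTRODES",
    "INTERVALS",
    "design_band_kernel",
    "band_power",
    "band_power_table",
]

BANDS: Dict[str, Tuple[float, float]] = {"alpha": (8.0, 12.0), "theta": (4.0, 8.0)}
POWER_ELECTRODES = ("P7", "P8", "Fz", "Pz")
INTERVALS: Dict[str, Tuple[float, float]] = {
    "pre_stimulus": (-200.0, 0.0),
    "post_stimulus": (0.0, 900.0),
}


def design_band_kernel(
    band: Tuple[float, float], fs: float, transition: float = 0.2
) -> np.ndarray:
    """Least-squares plateau FIR kernel for one band.

    Frequency grid {0, low·(1−transition), low, high, high·(1+transition),
    fs/2} with desired response {0, 0, 1, 1, 0, 0}; filter order
    round(fs / low), bumped by one when needed so the kernel has an odd
    number of taps (type-I, exactly symmetric / linear phase).
    """
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError("need 0 < low < high < fs/2")
    order = int(round(fs / low))
    if order < 8:
        raise ValueError("filter order below 8; band edge too high for fs")
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # type-I symmetric kernel
    upper = min(high * (1 + transition), fs / 2 * 0.999)
    bands = [0.0, low * (1 - transition), low, high, upper, fs / 2]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    return signal.firls(numtaps, bands, desired, fs=fs)


def _trial_power(
    analytic: np.ndarray,
    fs: float,
    band: Tuple[float, float],
    mode: str,
) -> float:
    if mode == "conventional":
        return float(np.mean(np.abs(analytic) ** 2))
    n = analytic.size
    nperseg = max(8, n // 2)
    freqs, psd = signal.welch(
        analytic,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        return_onesided=False,
        detrend=False,
    )
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():  # coarse grid: fall back to the nearest bin
        in_band = np.abs(freqs - np.mean(band)) == np.min(
            np.abs(freqs - np.mean(band))
        )
    return float(np.mean(np.abs(psd[in_band])) ** 2)


def band_power(
    epochs: EpochSet,
    band: str,
    electrode: str,
    interval: Tuple[float, float],
    mode: str = "psd_squared",
) -> np.ndarray:
    """Per-trial band power at one electrode over one interval (ms).

    ``mode="psd_squared"`` (default) reduces the analytic signal's Welch PSD
    to (mean in-band magnitude)²; ``mode="conventional"`` returns the mean
    squared analytic amplitude. Both are nonnegative and scale with the
    fourth / second power of signal amplitude respectively.
    """
    if band not in BANDS:
        raise ValueError(f"band must be one of {sorted(BANDS)}")
    if mode not in ("psd_squared", "conventional"):
        raise ValueError("mode must be 'psd_squared' or 'conventional'")
    lo, hi = interval
    if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
        raise ValueError("interval outside the epoch span")
    mask = epochs.time_mask(lo, hi)
    n_int = int(mask.sum())
    if n_int < 8:
        raise ValueError("interval shorter than one Welch segment")
    kernel = design_band_kernel(BANDS[band], epochs.fs)
    x = epochs.get_channel(electrode)  # trials x samples, full epoch
    filtered = signal.filtfilt(kernel, [1.0], x, axis=-1, padtype="odd")
    analytic = signal.hilbert(filtered, axis=-1)[:, mask]
    return np.array(
        [_trial_power(a, epochs.fs, BANDS[band], mode) for a in analytic]
    )


def band_power_table(
    epochs: EpochSet,
    electrodes: Sequence[str] = POWER_ELECTRODES,
    intervals: Dict[str, Tuple[float, float]] = INTERVALS,
    mode: str = "psd_squared",
) -> pd.DataFrame:
    """Tidy per-trial table: (trial, electrode, band, interval, power)."""
    rows = []
    for electrode in electrodes:
        for band in BANDS:
            for name, window in intervals.items():
                p = band_power(epochs, band, electrode, window, mode=mode)
                for trial, val in enumerate(p):
                    rows.append(
                        {
                            "trial": trial,
                            "electrode": electrode,
                            "band": band,
                            "interval": name,
                            "power": val,
                        }
                    )
    return pd.DataFrame(rows)
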