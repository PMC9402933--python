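"""Event-related potentials: condition averages and single-trial features.

Two layers of analysis. The classical one averages trials per condition and
reads the window-restricted peak amplitude of P1 (50–200 ms, positive, P7/P8),
N1 (100–250 ms, negative, P7/P8) and P3 (250–600 ms, positive, Fz/Pz).

The single-trial layer is template matching: a Mexican-hat (Ricker) wavelet
ψ_s(τ) = (1 − (τ/s)²)·exp(−τ²/(2s²)), unit-energy normalized, is
cross-covaried with the mean-removed trial over a grid of scales; within the
component's window the local extremum of the component's polarity with the
largest absolute surface value yields the feature triple (W, t, s) —
matched amplitude, peak time and template scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import signal

from .containers import EmptyClassError, EpochSet, TrialLabels

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentSpec",
    "STERPFeature",
    "COMPONENT_SPECS",
    "DEFAULT_SCALE_GRID",
    "average_erp",
    "peak_amplitude",
    "ricker_template",
    "single_trial_erp",
]

#: scale grid (ms) spanning brief P1 deflections to the broad P3
DEFAULT_SCALE_GRID = (20.0, 40.0, 60.0, 80.0, 120.0, 160.0)


@dataclass(frozen=True)
class ComponentSpec:
    """Detection window, polarity and electrodes of one ERP component."""

    name: str
    window: Tuple[float, float]
    polarity: str  # "positive" | "negative"
    electrodes: Tuple[str, ...]

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be an increasing interval")


COMPONENT_SPECS = {
    "P1": ComponentSpec("P1", (50.0, 200.0), "positive", ("P7", "P8")),
    "N1": ComponentSpec("N1", (100.0, 250.0), "negative", ("P7", "P8")),
    "P3": ComponentSpec("P3", (250.0, 600.0), "positive", ("Fz", "Pz")),
}


@dataclass
class STERPFeature:
    """Single-trial matched-template feature: amplitude W, time t, scale s."""

    component: str
    W: float  # signed matched amplitude (µV-scaled)
    t: float  # ms
    s: float  # ms
    degenerate: bool = False


def average_erp(
    epochs: EpochSet,
    labels: TrialLabels,
    which: str,
    class_label: str,
    electrode: str,
) -> np.ndarray:
    """Pointwise mean over the trials of one label class at one electrode.

    ``which`` selects the labeling: ``"attention"`` or ``"stickiness"``.
    Raises :class:`EmptyClassError` when the class has no trials (the
    study-level participant-exclusion rule).
    """
    lab = (
        labels.attention_state if which == "attention" else labels.stickiness_class
    )
    idx = np.flatnonzero(lab == class_label)
    if idx.size == 0:
        raise EmptyClassError(f"no trials labeled {class_label!r}")
    return epochs.get_channel(electrode)[idx].mean(axis=0)


def peak_amplitude(
    waveform: np.ndarray, times: np.ndarray, spec: ComponentSpec
) -> Tuple[float, float]:
    """Window-restricted peak: max for positive polarity, min for negative.

    Ties are broken by the earliest latency. Returns (amplitude µV, latency ms).
    """
    mask = (times >= spec.window[0] - 1e-9) & (times <= spec.window[1] + 1e-9)
    if not mask.any():
        raise ValueError("component window outside the waveform span")
    w = waveform[mask]
    t = times[mask]
    i = int(np.argmax(w)) if spec.polarity == "positive" else int(np.argmin(w))
    return float(w[i]), float(t[i])


def ricker_template(scale: float, fs: float) -> np.ndarray:
    """Unit-energy Mexican-hat wavelet sampled at ``fs``, support ±4·scale.

    ``scale`` in ms. ψ_s(τ) = (1 − (τ/s)²)·exp(−τ²/(2s²)); zero-mean by
    construction, normalized so Σψ² = 1.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    half = int(round(4.0 * scale * fs / 1000.0))
    if half < 1 or 2 * half + 1 < 5:
        raise ValueError(f"scale {scale} ms too small for fs {fs} Hz")
    tau = np.arange(-half, half + 1) * 1000.0 / fs  # ms
    x = tau / scale
    psi = (1.0 - x**2) * np.exp(-0.5 * x**2)
    psi -= psi.mean()  # discrete sampling leaves a tiny DC residue
    return psi / np.sqrt(np.sum(psi**2))


def _local_extrema(row: np.ndarray, positive: bool) -> np.ndarray:
    """Indices of strict-or-plateau local maxima (or minima) of a 1D array."""
    y = row if positive else -row
    peaks, _ = signal.find_peaks(y)
    return peaks


def single_trial_erp(
    trial_waveform: np.ndarray,
    times: np.ndarray,
    spec: ComponentSpec,
    fs: float,
    scale_grid: Sequence[float] = DEFAULT_SCALE_GRID,
) -> STERPFeature:
    """Match Ricker templates to one trial; return the (W, t, s) feature.

    The cross-covariance of the mean-removed trial with each unit-energy
    template forms a time × scale surface (a Ricker CWT). Within the
    component window, local extrema of the right polarity are collected per
    scale; the one with the largest |value| wins, ties broken by earliest
    time then smallest scale. When no extremum of the right polarity exists
    the windowed global extremum is returned with ``degenerate=True``.
    """
    if len(scale_grid) == 0:
        raise ValueError("scale_grid must be non-empty")
    x = np.asarray(trial_waveform, dtype=float)
    x = x - x.mean()
    positive = spec.polarity == "positive"
    mask = (times >= spec.window[0] - 1e-9) & (times <= spec.window[1] + 1e-9)
    if not mask.any():
        raise ValueError("component window outside the trial span")
    win_idx = np.flatnonzero(mask)

    if not np.any(x):
        return STERPFeature(
            spec.name,
            0.0,
            float(times[win_idx[0]]),
            float(min(scale_grid)),
            degenerate=True,
        )

    best = None  # (|W|, t, s, W)
    fallback = None
    for s in sorted(scale_grid):
        psi = ricker_template(s, fs)
        # symmetric template: correlation == convolution, 'same' keeps alignment
        surface = signal.fftconvolve(x, psi, mode="same")
        row = surface[win_idx]
        t_row = times[win_idx]
        gi = int(np.argmax(row)) if positive else int(np.argmin(row))
        cand_fb = (abs(row[gi]), t_row[gi], s, row[gi])
        if fallback is None or cand_fb[0] > fallback[0] + 1e-12:
            fallback = cand_fb
        for p in _local_extrema(row, positive):
            val = row[p]
            if (positive and val <= 0) or (not positive and val >= 0):
                continue
            cand = (abs(val), t_row[p], s, val)
            if (
                best is None
                or cand[0] > best[0] + 1e-12
                or (
                    abs(cand[0] - best[0]) <= 1e-12
                    and (cand[1], cand[2]) < (best[1], best[2])
                )
            ):
                best = cand
    if best is None:
        logger.debug(
            "no %s-polarity local extremum for %s; using windowed global extremum",
            spec.polarity,
            spec.name,
        )
        _, t, s, val = fallback
        return STERPFeature(spec.name, float(val), float(t), float(s), degenerate=True)
    _, t, s, val = best
    return STERPFeature(spec.name, float(val), float(t), float(s))
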