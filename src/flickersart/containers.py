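"""In-memory containers shared across the pipeline.

The package's working unit is the :class:`EpochSet`: a dense
``trials x channels x samples`` tensor in microvolts with a millisecond time
axis relative to stimulus onset, plus per-trial metadata (Go/Nogo type, block,
behavioural response). Thought-probe reports are carried as
:class:`ProbeResponse` records and converted into per-trial
:class:`TrialLabels` by :func:`flickersart.preprocess.assign_labels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: BioSemi 32-channel cap layout (10-20 names), the montage the task was
#: recorded with.  Order matches ``mne.channels.make_standard_montage("biosemi32")``.
BIOSEMI32 = [
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3", "CP1", "CP5",
    "P7", "P3", "Pz", "PO3", "O1", "Oz", "O2", "PO4", "P4", "P8",
    "CP6", "CP2", "C4", "T8", "FC6", "FC2", "F4", "F8", "AF4", "Fp2",
    "Fz", "Cz",
]


class EmptyClassError(ValueError):
    """Raised when a requested label class contains no trials.

    Mirrors the study-level rule that a participant without trials in a class
    is excluded from that analysis.
    """


@dataclass
class ProbeResponse:
    """One thought-probe report.

    Parameters
    ----------
    probe_index : int
        Running index of the probe within the session.
    after_trial : int
        Index (0-based, session-wide) of the trial the probe followed.
    content_option : int
        Thought-content option 1-6 ("What were you thinking about just now?").
    stickiness : int or None
        1-9 rating of how difficult it was to disengage from the thought.
    self_focus, valence : int or None
        1-9 ratings; carried but not used by the core analyses.
    """

    probe_index: int
    after_trial: int
    content_option: int
    stickiness: Optional[int] = None
    self_focus: Optional[int] = None
    valence: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.content_option) <= 6:
            raise ValueError(
                f"content_option must be in 1..6, got {self.content_option}"
            )
        for name in ("stickiness", "self_focus", "valence"):
            v = getattr(self, name)
            if v is not None and not 1 <= int(v) <= 9:
                raise ValueError(f"{name} must be in 1..9 or None, got {v}")


@dataclass
class TrialLabels:
    """Per-trial derived labels.

    ``attention_state`` is one of ``on_task`` / ``mind_wandering`` /
    ``excluded``; ``stickiness_class`` one of ``less_sticky`` / ``more_sticky``
    / ``excluded``. Trials farther than ``n_back`` before a probe are excluded
    from both labelings.
    """

    attention_state: np.ndarray  # (n_trials,) of str
    stickiness_class: np.ndarray  # (n_trials,) of str

    def __len__(self) -> int:
        return len(self.attention_state)

    def subset(self, idx) -> "TrialLabels":
        return TrialLabels(self.attention_state[idx], self.stickiness_class[idx])


@dataclass
class EpochSet:
    """Epoched EEG: ``data`` is (n_trials, n_channels, n_samples) in microvolts.

    ``times`` are milliseconds relative to stimulus onset with uniform spacing
    ``1000 / fs``; the onset sample (t == 0) belongs to the epoch.
    ``trial_meta`` holds one row per trial with at least ``trial_index``,
    ``trial_type`` (go / nogo) and ``block``; behavioural columns
    ``responded`` / ``rt`` are present when the source recording carried them.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channel_names: list
    trial_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must match data's sample axis")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match data's channel axis")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.fs, rtol=1e-6, atol=1e-6):
                raise ValueError("times must be uniformly spaced at 1000/fs ms")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.trial_meta is None or len(self.trial_meta) == 0:
            self.trial_meta = pd.DataFrame(
                {"trial_index": np.arange(self.data.shape[0])}
            )
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta must have one row per trial")

    # ------------------------------------------------------------------ views
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError as err:
            raise KeyError(f"channel {name!r} not in EpochSet") from err

    def get_channel(self, name: str) -> np.ndarray:
        """Return (n_trials, n_samples) for one channel."""
        return self.data[:, self.channel_index(name), :]

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        """Boolean sample mask for ``tmin <= t <= tmax`` (inclusive, ms)."""
        return (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)

    def subset_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            times=self.times.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            trial_meta=self.trial_meta.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            trial_meta=self.trial_meta.copy(),
        )


def probes_to_frame(probes: Sequence[ProbeResponse]) -> pd.DataFrame:
    """Tidy DataFrame view of probe responses (one row per probe)."""
    return pd.DataFrame(
        [
            {
                "probe_index": p.probe_index,
                "after_trial": p.after_trial,
                "content_option": p.content_option,
                "stickiness": p.stickiness,
                "self_focus": p.self_focus,
                "valence": p.valence,
            }
            for p in probes
        ]
    )
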