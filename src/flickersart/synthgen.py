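"""Synthetic flicker-SART sessions.

Generates continuous multichannel EEG with the statistical structure the
downstream analyses assume: 1/f background noise, a 12.5 Hz steady-state
visual evoked potential (SSVEP) with a 25 Hz harmonic whose trial-to-trial
phase consistency is governed by a von-Mises concentration parameter,
P1/N1/P3 evoked deflections, state-modulated posterior alpha and frontal
theta, Go/Nogo behaviour, and thought probes that label the five preceding
trials with a latent attentional state.

The latent state is the cross of attention (``on_task`` / ``mind_wandering``)
and thought stickiness (``less_sticky`` / ``more_sticky``); each combination
owns a :class:`StateParams` row. The von-Mises concentration ``kappa`` maps
monotonically onto inter-trial coherence (ITC): ``kappa = 0`` gives uniform
phases (ITC -> 0 in expectation), ``kappa = inf`` perfect phase locking
(ITC -> 1 at high SNR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import BIOSEMI32, ProbeResponse

__all__ = [
    "StateParams",
    "SimConfig",
    "SimulatedSession",
    "make_pink_noise",
    "make_flicker_response",
    "make_erp_waveform",
    "simulate_session",
    "default_state_model",
    "null_state_model",
]

ATTENTION_STATES = ("on_task", "mind_wandering")
STICKINESS_STATES = ("less_sticky", "more_sticky")

#: ERP component shape defaults: (peak latency ms, half-width-at-half-max ms,
#: base peak amplitude µV). Latencies sit inside the detection windows used by
#: the ERP analysis (P1 50-200, N1 100-250, P3 250-600 ms).
ERP_SHAPE = {
    "P1": (120.0, 25.0, 5.0),
    "N1": (170.0, 30.0, 5.0),
    "P3": (400.0, 80.0, 6.0),
}


@dataclass
class StateParams:
    """Generative parameters of one latent state.

    ``ssvep_phase_kappa`` is the von-Mises concentration of the trial-to-trial
    SSVEP phase (controls ITC); ``harmonic_ratio`` the 25 Hz amplitude as a
    fraction of the 12.5 Hz fundamental; amplitudes are in µV.
    """

    state: Tuple[str, str]
    ssvep_amplitude: float = 4.0
    ssvep_phase_kappa: float = 0.9
    harmonic_ratio: float = 0.5
    alpha_amplitude: float = 3.0
    theta_amplitude: float = 1.5
    erp_scale: Dict[str, float] = field(
        default_factory=lambda: {"P1": 1.0, "N1": 1.0, "P3": 1.0}
    )
    nogo_accuracy: float = 0.65
    rt_mean: float = 0.47
    rt_sd: float = 0.10
    pink_noise_sigma: float = 10.0
    pink_exponent: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "ssvep_amplitude",
            "harmonic_ratio",
            "alpha_amplitude",
            "theta_amplitude",
            "pink_noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.nogo_accuracy <= 1.0:
            raise ValueError("nogo_accuracy must be a probability")
        if self.ssvep_phase_kappa < 0:
            raise ValueError("ssvep_phase_kappa must be >= 0")


def default_state_model() -> Dict[Tuple[str, str], StateParams]:
    """Per-state parameter table mirroring the study's measured contrasts.

    Stickiness modulates SSVEP phase consistency (less sticky more coherent)
    and Nogo accuracy; mind-wandering raises posterior alpha slightly and
    lowers Nogo accuracy. Contrasts are deliberately subtle — on the order the
    real study reported — so that single-state summaries look realistic while
    group-level contrasts need many trials.
    """
    table = {}
    kappa = {"less_sticky": 0.95, "more_sticky": 0.80}
    nogo = {
        ("on_task", "less_sticky"): 0.71,
        ("on_task", "more_sticky"): 0.62,
        ("mind_wandering", "less_sticky"): 0.65,
        ("mind_wandering", "more_sticky"): 0.55,
    }
    for att in ATTENTION_STATES:
        for stick in STICKINESS_STATES:
            mw = att == "mind_wandering"
            table[(att, stick)] = StateParams(
                state=(att, stick),
                ssvep_phase_kappa=kappa[stick],
                alpha_amplitude=3.3 if mw else 3.0,
                theta_amplitude=1.6 if mw else 1.5,
                nogo_accuracy=nogo[(att, stick)],
                rt_mean=0.47 if stick == "more_sticky" else 0.48,
            )
    return table


def null_state_model() -> Dict[Tuple[str, str], StateParams]:
    """All states share identical parameters (no decodable signal)."""
    base = StateParams(state=("on_task", "less_sticky"))
    return {
        (att, stick): replace(
            base, state=(att, stick), erp_scale=dict(base.erp_scale)
        )
        for att in ATTENTION_STATES
        for stick in STICKINESS_STATES
    }


@dataclass
class SimConfig:
    """Session layout and generative parameters.

    Defaults reproduce the task structure: 8 blocks of 90 trials with six
    thought probes per block, every ninth trial a Nogo (11.11%), words
    flickering at 12.5 Hz for 320 ms followed by an 880 ms flickering mask,
    fixation jittered over {1480..2120} ms and a 3020 ms inter-stimulus
    interval, recorded at 512 Hz on a BioSemi-32 montage.
    """

    n_blocks: int = 8
    trials_per_block: int = 90
    probes_per_block: int = 6
    nogo_every: int = 9  # every nogo_every-th trial is a Nogo -> 1/9 = 11.11%
    fs: float = 512.0
    channels: Sequence[str] = field(default_factory=lambda: list(BIOSEMI32))
    flicker_freq: float = 12.5
    flicker_duration: float = 1200.0  # ms: 320 ms word + 880 ms mask
    fixation_jitter: Sequence[float] = (1480.0, 1640.0, 1800.0, 1960.0, 2120.0)
    isi: float = 3020.0  # ms without flicker
    state_model: Dict[Tuple[str, str], StateParams] = field(
        default_factory=default_state_model
    )
    p_on_task: float = 0.52
    p_more_sticky: float = 0.5
    #: probe answers drawn from options {4, 6} (not assignable to either
    #: attentional state) with this probability — exercises exclusion paths
    excluded_option_fraction: float = 0.2
    #: probability of the intermediate stickiness rating 5 (excluded)
    rating5_fraction: float = 0.19
    go_response_prob: float = 0.99
    square_wave: bool = False  # square on/off drive instead of two sinusoids
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.nogo_every < 2:
            raise ValueError("nogo_every must be >= 2")
        if not 0 < 1.0 / self.nogo_every < 1:
            raise ValueError("nogo fraction must be in (0, 1)")
        if self.probes_per_block * 5 > self.trials_per_block:
            raise ValueError("probes_per_block x 5 must fit in a block")
        if self.probes_per_block > self.trials_per_block // self.nogo_every:
            raise ValueError("not enough Nogo trials to host the probes")
        if self.flicker_freq >= self.fs / 2:
            raise ValueError("flicker_freq must be below Nyquist")
        names = list(self.channels)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def nogo_fraction(self) -> float:
        return 1.0 / self.nogo_every


@dataclass
class SimulatedSession:
    """A generated session: continuous EEG plus ground truth.

    ``recording`` is (n_channels, n_samples) µV; ``events`` one row per trial
    (sample of word onset, go/nogo, block); ``true_states`` the latent
    (attention, stickiness) pair of every trial; ``behavior`` per-trial
    response flag and RT in seconds (NaN when withheld).
    """

    recording: np.ndarray
    fs: float
    channel_names: list
    events: pd.DataFrame
    probes: list
    true_states: pd.DataFrame
    behavior: pd.DataFrame
    config: SimConfig

    def __post_init__(self) -> None:
        s = self.events["sample"].to_numpy()
        if np.any(np.diff(s) <= 0):
            raise ValueError("event samples must be strictly increasing")


# --------------------------------------------------------------------------
# signal primitives
# --------------------------------------------------------------------------

def make_pink_noise(
    n_samples: int,
    fs: float,
    exponent: float = 1.0,
    sigma: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Zero-mean noise with power spectral density ∝ 1/f**exponent.

    White Gaussian noise is shaped in the frequency domain by
    ``f**(-exponent/2)`` (the DC bin is zeroed) and rescaled to standard
    deviation ``sigma``. ``exponent = 0`` returns white noise; ``sigma = 0``
    an all-zero signal.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if sigma == 0:
        rng.standard_normal(n_samples)  # keep the stream position deterministic
        return np.zeros(n_samples)
    if exponent == 0:
        out = rng.standard_normal(n_samples)
        out = out - out.mean()
    else:
        from scipy import fft as sfft

        # pad to an FFT-friendly length, then truncate: spectral shaping is
        # stationary, so the cut is statistically harmless and much faster
        # on awkward sample counts
        n_fast = sfft.next_fast_len(n_samples, real=True)
        white = rng.standard_normal(n_fast)
        spec = sfft.rfft(white)
        freqs = np.fft.rfftfreq(n_fast, d=1.0 / fs)
        gain = np.zeros_like(freqs)
        gain[1:] = freqs[1:] ** (-exponent / 2.0)
        out = sfft.irfft(spec * gain, n=n_fast)[:n_samples]
        out = out - out.mean()
    sd = out.std()
    if sd > 0:
        out *= sigma / sd
    return out


def make_flicker_response(
    duration: float,
    fs: float,
    freq: float,
    amplitude: float,
    phase: float = 0.0,
    harmonic_ratio: float = 0.5,
    ramp_ms: float = 50.0,
    square: bool = False,
) -> np.ndarray:
    """SSVEP drive: fundamental + first harmonic, raised-cosine ramped.

    ``duration`` in ms. Sum of ``amplitude * sin(2π f t + phase)`` and
    ``amplitude * harmonic_ratio * sin(2π (2f) t + phase)``, multiplied by a
    ``ramp_ms`` raised-cosine onset/offset window; zero outside [0, duration].
    With ``square=True`` a ±amplitude square-wave on/off train replaces the
    two-sinusoid model.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 < freq < fs / 2:
        raise ValueError(f"freq {freq} Hz would alias at fs {fs} Hz")
    n = int(round(duration * fs / 1000.0))
    t = np.arange(n) / fs
    if square:
        from scipy.signal import square as _square

        sig = amplitude * _square(2 * np.pi * freq * t + phase)
    else:
        sig = amplitude * np.sin(2 * np.pi * freq * t + phase)
        sig = sig + amplitude * harmonic_ratio * np.sin(
            2 * np.pi * 2 * freq * t + phase
        )
    n_ramp = int(round(ramp_ms * fs / 1000.0))
    if n_ramp > 0 and 2 * n_ramp <= n:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        sig[:n_ramp] *= ramp
        sig[-n_ramp:] *= ramp[::-1]
    return sig


def make_erp_waveform(
    component: str,
    latency: float,
    width_ms: float,
    amplitude: float,
    fs: float,
    epoch_span: Tuple[float, float],
) -> np.ndarray:
    """Gaussian evoked deflection peaking at ``latency`` ms.

    Polarity is fixed per component (P1 and P3 positive, N1 negative);
    ``width_ms`` is the half-width at half maximum; the signed peak value
    equals ``amplitude`` with the component's polarity. The returned vector
    spans ``epoch_span`` (ms, inclusive endpoints) sampled at ``fs``.
    """
    if component not in ("P1", "N1", "P3"):
        raise ValueError(f"unknown component {component!r}")
    if width_ms <= 0:
        raise ValueError("width_ms must be positive")
    tmin, tmax = epoch_span
    if not tmin <= latency <= tmax:
        raise ValueError("latency must lie inside epoch_span")
    n = int(round((tmax - tmin) * fs / 1000.0)) + 1
    t = tmin + np.arange(n) * 1000.0 / fs
    sigma = width_ms / math.sqrt(2.0 * math.log(2.0))
    polarity = -1.0 if component == "N1" else 1.0
    return polarity * abs(amplitude) * np.exp(-0.5 * ((t - latency) / sigma) ** 2)


# --------------------------------------------------------------------------
# spatial topography
# --------------------------------------------------------------------------

_MONTAGE_POS: Optional[Dict[str, np.ndarray]] = None


def _montage_positions() -> Dict[str, np.ndarray]:
    """3D scalp positions (m) of the BioSemi-32 montage, via MNE."""
    global _MONTAGE_POS
    if _MONTAGE_POS is None:
        import mne

        montage = mne.channels.make_standard_montage("biosemi32")
        _MONTAGE_POS = {
            ch: pos for ch, pos in montage.get_positions()["ch_pos"].items()
        }
    return _MONTAGE_POS


def topography_gain(
    channels: Sequence[str], centers: Sequence[str], sigma_m: float = 0.05
) -> np.ndarray:
    """Gaussian scalp gain profile, 1.0 at the (nearest) center electrode.

    Gains fall off with 3D distance from the closest center with spatial
    scale ``sigma_m`` (m). Channels missing from the montage get gain 0.
    """
    pos = _montage_positions()
    gains = np.zeros(len(channels))
    centers_pos = [pos[c] for c in centers if c in pos]
    if not centers_pos:
        raise ValueError("no montage position for any center electrode")
    for i, ch in enumerate(channels):
        if ch not in pos:
            continue
        d = min(np.linalg.norm(pos[ch] - c) for c in centers_pos)
        gains[i] = math.exp(-0.5 * (d / sigma_m) ** 2)
    return gains


# --------------------------------------------------------------------------
# session simulation
# --------------------------------------------------------------------------

def _draw_phase(rng: np.random.Generator, kappa: float) -> float:
    if math.isinf(kappa):
        return 0.0
    if kappa == 0:
        return float(rng.uniform(-np.pi, np.pi))
    return float(rng.vonmises(0.0, kappa))


def _draw_rt(rng: np.random.Generator, mean: float, sd: float, floor: float = 0.150) -> float:
    # truncated normal, lower bound 150 ms
    for _ in range(100):
        rt = rng.normal(mean, sd)
        if rt >= floor:
            return float(rt)
    return floor


def simulate_session(config: SimConfig) -> SimulatedSession:
    """Generate one participant's continuous flicker-SART session.

    Reproducible given ``config.seed`` (required). Per-trial EEG is pink
    noise plus a spatially weighted flicker response (maximal at Oz), ERP
    components (P1/N1 maximal at P7/P8, P3 at Pz), and alpha/theta
    oscillations (posterior / frontal) with random phase per trial. The
    latent state is drawn per probe and held constant over the probe's five
    preceding trials; probe answers are drawn consistently with the state.
    """
    if config.seed is None:
        raise ValueError("SimConfig.seed is required for reproducibility")
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    channels = list(config.channels)
    n_ch = len(channels)
    n_trials = config.n_trials

    # ---------------------------------------------------------------- timing
    ms = lambda x: int(round(x * fs / 1000.0))
    pad = ms(1000.0)
    onsets = np.empty(n_trials, dtype=np.int64)
    cursor = pad
    jitter = np.asarray(config.fixation_jitter, dtype=float)
    for i in range(n_trials):
        cursor += ms(float(rng.choice(jitter)))
        onsets[i] = cursor
        cursor += ms(config.flicker_duration) + ms(config.isi)
    n_samples = cursor + ms(5000.0)  # tail pad so the last 4300 ms epoch fits

    trial_idx = np.arange(n_trials)
    blocks = trial_idx // config.trials_per_block
    is_nogo = (trial_idx % config.nogo_every) == (config.nogo_every - 1)

    # ---------------------------------------------------------------- probes
    probe_trials = []
    for b in range(config.n_blocks):
        in_block = trial_idx[(blocks == b) & is_nogo]
        chosen = rng.choice(in_block, size=config.probes_per_block, replace=False)
        probe_trials.extend(sorted(int(c) for c in chosen))

    # ------------------------------------------------------------ true states
    attention = np.empty(n_trials, dtype=object)
    stickiness = np.empty(n_trials, dtype=object)
    for i in range(n_trials):
        attention[i] = ATTENTION_STATES[rng.random() >= config.p_on_task]
        stickiness[i] = STICKINESS_STATES[rng.random() < config.p_more_sticky]
    probes = []
    for k, pt in enumerate(probe_trials):
        att = ATTENTION_STATES[rng.random() >= config.p_on_task]
        stick = STICKINESS_STATES[rng.random() < config.p_more_sticky]
        lo = max(0, pt - 4)
        attention[lo : pt + 1] = att
        stickiness[lo : pt + 1] = stick
        if rng.random() < config.excluded_option_fraction:
            option = int(rng.choice([4, 6]))
        elif att == "on_task":
            option = int(rng.choice([1, 2]))
        else:
            option = int(rng.choice([3, 5]))
        if rng.random() < config.rating5_fraction:
            rating = 5
        elif stick == "less_sticky":
            rating = int(rng.integers(1, 5))
        else:
            rating = int(rng.integers(6, 10))
        probes.append(
            ProbeResponse(
                probe_index=k,
                after_trial=pt,
                content_option=option,
                stickiness=rating,
                self_focus=int(rng.integers(1, 10)),
                valence=int(rng.integers(1, 10)),
            )
        )

    # ------------------------------------------------------------- topography
    g_ssvep = topography_gain(channels, ["Oz"])
    g_p1n1 = topography_gain(channels, ["P7", "P8"])
    g_p3 = topography_gain(channels, ["Pz"])
    g_alpha = topography_gain(channels, ["Oz", "Pz", "P7", "P8"], sigma_m=0.06)
    g_theta = topography_gain(channels, ["Fz"], sigma_m=0.06)

    # -------------------------------------------------------------- recording
    sigmas = [p.pink_noise_sigma for p in config.state_model.values()]
    exps = [p.pink_exponent for p in config.state_model.values()]
    noise_sigma = float(np.mean(sigmas))
    noise_exp = float(np.mean(exps))
    recording = np.empty((n_ch, n_samples), dtype=np.float64)
    for c in range(n_ch):
        recording[c] = make_pink_noise(
            n_samples, fs, exponent=noise_exp, sigma=noise_sigma, rng=rng
        )

    osc_span = (-500.0, 1300.0)  # ms around onset where oscillations are active
    n_osc = ms(osc_span[1] - osc_span[0]) + 1
    t_osc = (osc_span[0] + np.arange(n_osc) * 1000.0 / fs) / 1000.0  # s
    osc_ramp = np.ones(n_osc)
    nr = ms(100.0)
    osc_ramp[:nr] = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    osc_ramp[-nr:] = osc_ramp[:nr][::-1]

    erp_span = (0.0, config.flicker_duration)
    erp_cache: Dict[Tuple[str, float], np.ndarray] = {}

    responded = np.zeros(n_trials, dtype=bool)
    rts = np.full(n_trials, np.nan)

    for i in range(n_trials):
        params = config.state_model[(attention[i], stickiness[i])]
        on = onsets[i]

        # SSVEP drive
        phase = _draw_phase(rng, params.ssvep_phase_kappa)
        flick = make_flicker_response(
            config.flicker_duration,
            fs,
            config.flicker_freq,
            params.ssvep_amplitude,
            phase=phase,
            harmonic_ratio=params.harmonic_ratio,
            square=config.square_wave,
        )
        recording[:, on : on + flick.size] += g_ssvep[:, None] * flick[None, :]

        # ERP components
        for comp, (lat, width, base_amp) in ERP_SHAPE.items():
            amp = base_amp * params.erp_scale.get(comp, 1.0)
            key = (comp, amp)
            if key not in erp_cache:
                erp_cache[key] = make_erp_waveform(
                    comp, lat, width, amp, fs, erp_span
                )
            wave = erp_cache[key]
            gain = g_p3 if comp == "P3" else g_p1n1
            recording[:, on : on + wave.size] += gain[:, None] * wave[None, :]

        # ongoing oscillations with random phase per trial
        start = on + ms(osc_span[0])
        alpha = params.alpha_amplitude * np.sin(
            2 * np.pi * 10.0 * t_osc + rng.uniform(0, 2 * np.pi)
        )
        theta = params.theta_amplitude * np.sin(
            2 * np.pi * 6.0 * t_osc + rng.uniform(0, 2 * np.pi)
        )
        seg = (g_alpha[:, None] * (alpha * osc_ramp)[None, :]) + (
            g_theta[:, None] * (theta * osc_ramp)[None, :]
        )
        recording[:, start : start + n_osc] += seg

        # behaviour
        if is_nogo[i]:
            responded[i] = rng.random() >= params.nogo_accuracy
        else:
            responded[i] = rng.random() < config.go_response_prob
        if responded[i]:
            rts[i] = _draw_rt(rng, params.rt_mean, params.rt_sd)

    events = pd.DataFrame(
        {
            "trial_index": trial_idx,
            "sample": onsets,
            "trial_type": np.where(is_nogo, "nogo", "go"),
            "block": blocks,
        }
    )
    true_states = pd.DataFrame(
        {"trial_index": trial_idx, "attention": attention, "stickiness": stickiness}
    )
    behavior = pd.DataFrame(
        {"trial_index": trial_idx, "responded": responded, "rt": rts}
    )
    return SimulatedSession(
        recording=recording,
        fs=fs,
        channel_names=channels,
        events=events,
        probes=probes,
        true_states=true_states,
        behavior=behavior,
        config=config,
    )
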