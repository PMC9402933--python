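"""Quantify the SSVEP: inter-trial coherence and ERSP at Oz.

The 12.5 Hz flicker entrains an occipital steady-state response; its
trial-to-trial phase consistency is measured as ITC on an 8-30 Hz Morlet
grid and summarised over 12-13 Hz (fundamental) and 24.5-25.5 Hz (harmonic)
in the 500-900 ms window where the SSVEP is fully developed.
"""

import flickersart as fs
from flickersart.pipeline import participant_itc_contrast
from flickersart.timefreq import (
    FUNDAMENTAL_RANGE,
    HARMONIC_RANGE,
    band_window_mean,
)
from flickersart.synthgen import SimConfig

config = SimConfig(
    n_blocks=2, trials_per_block=45, probes_per_block=5,
    channels=["Fz", "Cz", "Pz", "Oz", "P7", "P8", "O1", "O2"], seed=3,
)
pre = fs.preprocess_session(fs.simulate_session(config))
tf = fs.morlet_decompose(pre.epochs_tf, electrode="Oz")

for name, f_range in [("12.5 Hz", FUNDAMENTAL_RANGE), ("25 Hz", HARMONIC_RANGE)]:
    m_itc = band_window_mean(tf.itc, tf.freqs, tf.times, f_range)
    m_ersp = band_window_mean(tf.ersp, tf.freqs, tf.times, f_range)
    print(f"{name}: ITC {m_itc:.3f}  ERSP {m_ersp:.1f} dB")
# ITC near 0 would mean random phases; near 1, perfect locking. The default
# generator injects moderate phase consistency (von-Mises kappa ~ 0.9), so
# fundamental ITC lands around 0.3-0.45.

values, contrast = participant_itc_contrast(pre, target="stickiness")
print("per-class 12.5 Hz ITC:", {k: round(v, 3) for k, v in values.items()})
print(f"contrast (less - more sticky): {contrast:+.3f}")
# The default parameterization makes less-sticky trials slightly more
# phase-locked, so the contrast tends positive — but with few trials per
# class, single-participant estimates are noisy.
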