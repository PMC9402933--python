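"""Shared fixtures: small simulated sessions and cohort-level experiments.

The cohort fixtures (strong-effect study, null study, ITC-direction cohort)
are session-scoped because several tests — per-module property tests and
the acceptance suite — assert different facets of the same experiment.
Problem sizes are scaled down relative to the full task (fewer blocks,
a reduced posterior/frontal channel set) to keep the suite quick while
preserving every structural property under test.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import flickersart as fs
from flickersart.pipeline import participant_itc_contrast, run_study
from flickersart.synthgen import (
    SimConfig,
    default_state_model,
    null_state_model,
)

#: reduced montage: the analysis electrodes plus enough others for averaging
TEST_CHANNELS = ["Fz", "Cz", "Pz", "Oz", "P7", "P8", "O1", "O2"]


def small_config(seed: int, n_blocks: int = 2, state_model=None, **kw) -> SimConfig:
    return SimConfig(
        n_blocks=n_blocks,
        trials_per_block=45,
        probes_per_block=5,
        channels=list(TEST_CHANNELS),
        state_model=state_model or default_state_model(),
        seed=seed,
        **kw,
    )


def strong_state_model():
    """Large injected stickiness effect: ITC contrast >= 0.15 via the phase
    concentration (kappa 4 vs 0.3) and a >30% posterior-alpha contrast."""
    model = default_state_model()
    for (att, stick), p in model.items():
        less = stick == "less_sticky"
        model[(att, stick)] = replace(
            p,
            ssvep_phase_kappa=4.0 if less else 0.3,
            alpha_amplitude=2.0 if less else 8.0,
            erp_scale=dict(p.erp_scale),
        )
    return model


def kappa_contrast_model(kappa_less: float = 4.0, kappa_more: float = 0.5):
    """Stickiness modulates only the SSVEP phase concentration."""
    model = default_state_model()
    for (att, stick), p in model.items():
        model[(att, stick)] = replace(
            p,
            ssvep_phase_kappa=kappa_less if stick == "less_sticky" else kappa_more,
            alpha_amplitude=3.0,
            theta_amplitude=1.5,
            erp_scale=dict(p.erp_scale),
        )
    return model


@pytest.fixture(scope="session")
def small_session():
    return fs.simulate_session(small_config(seed=7))


@pytest.fixture(scope="session")
def small_pre(small_session):
    return fs.preprocess_session(small_session)


@pytest.fixture(scope="session")
def strong_study():
    """10 simulated participants with a strong injected stickiness effect."""
    cfg = small_config(seed=0, n_blocks=4, state_model=strong_state_model())
    return run_study(cfg, n_participants=10, seed=2024, target="stickiness")


@pytest.fixture(scope="session")
def null_study():
    """10 simulated participants with all states identical (no signal)."""
    cfg = small_config(seed=0, n_blocks=4, state_model=null_state_model())
    return run_study(cfg, n_participants=10, seed=2024, target="stickiness")


@pytest.fixture(scope="session")
def itc_direction_cohort():
    """20 participants with kappa(less) > kappa(more); per-participant
    12.5 Hz ITC contrasts (less − more)."""
    contrasts = []
    for i in range(20):
        cfg = small_config(seed=1000 + i, n_blocks=2,
                           state_model=kappa_contrast_model())
        pre = fs.preprocess_session(fs.simulate_session(cfg))
        _, contrast = participant_itc_contrast(pre, target="stickiness")
        contrasts.append(contrast)
    return np.asarray(contrasts)
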