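"""End-to-end study orchestration on simulated cohorts.

``run_study`` simulates N participants, preprocesses each session, extracts
features, trains the with- and without-SSVEP classifier variants per
participant, and aggregates group-level results, including the paired
t / Bayes-factor comparison of the two variants. Participants whose label
class is empty (e.g. no more-sticky probes survived) are excluded before
classification, as the study protocol prescribes.

Everything is deterministic given the study seed: per-participant seeds are
spawned from it, recorded in each report, and re-running with the same
configuration reproduces the result exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import classify, stats, timefreq
from .classify import ClassifierReport
from .containers import EmptyClassError
from .preprocess import Preprocessed, preprocess_session
from .stats import PairedTestResult
from .synthgen import SimConfig, simulate_session

__all__ = ["ParticipantResult", "StudyResult", "run_study", "compare_variants",
           "participant_itc_contrast"]


def _participant_seed(study_seed: int, participant: int) -> int:
    """Stable per-participant seed below 2**31."""
    return int(
        np.random.SeedSequence([study_seed, participant]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class ParticipantResult:
    participant: int
    seed: int
    with_ssvep: ClassifierReport
    without_ssvep: ClassifierReport
    itc_fundamental: Dict[str, float]  # mean 12-13 Hz x 500-900 ms ITC per class
    nogo_accuracy: Dict[str, float]


@dataclass
class StudyResult:
    """Cohort-level outcome with full provenance."""

    target: str
    seed: int
    n_requested: int
    participants: List[ParticipantResult]
    excluded: List[int]
    mean_accuracy_with: float
    mean_accuracy_without: float
    variant_comparison: Optional[PairedTestResult]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def participant_itc_contrast(
    pre: Preprocessed,
    target: str = "stickiness",
    tf_by_class: Optional[Dict[str, np.ndarray]] = None,
) -> Tuple[Dict[str, float], float]:
    """Per-class 12.5 Hz ITC (12–13 Hz × 500–900 ms mean) and the contrast.

    Returns ({class: mean ITC}, contrast) where the contrast is
    less_sticky − more_sticky (or on_task − mind_wandering). Classes with
    fewer than 2 trials are skipped and yield a NaN contrast.
    """
    lab = (
        pre.labels.stickiness_class
        if target == "stickiness"
        else pre.labels.attention_state
    )
    order = (
        ("less_sticky", "more_sticky")
        if target == "stickiness"
        else ("on_task", "mind_wandering")
    )
    values: Dict[str, float] = {}
    for cls in order:
        idx = np.flatnonzero(lab == cls)
        if idx.size < 2:
            continue
        tf = timefreq.morlet_decompose(
            pre.epochs_tf.subset_trials(idx), electrode="Oz", compute_maps=False
        )
        itc_map = timefreq.itc(tf.coeffs)
        values[cls] = timefreq.band_window_mean(
            itc_map, tf.freqs, tf.times, timefreq.FUNDAMENTAL_RANGE
        )
    if all(c in values for c in order):
        contrast = values[order[0]] - values[order[1]]
    else:
        contrast = float("nan")
    return values, contrast


def _participant(
    config: SimConfig,
    target: str,
    alpha: float,
    seed: int,
) -> Tuple[ClassifierReport, ClassifierReport, Dict[str, float], Dict[str, float]]:
    session = simulate_session(replace(config, seed=seed))
    pre = preprocess_session(session)
    tf = timefreq.morlet_decompose(pre.epochs_tf, electrode="Oz", compute_maps=False)

    table_with = classify.build_feature_table(
        pre.epochs_erp, pre.epochs_tf, pre.labels, target=target,
        with_ssvep=True, tf_result=tf,
    )
    ssvep_cols = [c for c in table_with.columns if c.startswith("ersp_")]
    table_without = table_with.drop(columns=ssvep_cols)

    rep_with = classify.run_classification(
        table_with, target=target, with_ssvep=True, alpha=alpha, seed=seed
    )
    rep_without = classify.run_classification(
        table_without, target=target, with_ssvep=False, alpha=alpha, seed=seed
    )

    itc_vals, _ = participant_itc_contrast(pre, target=target)

    lab = (
        pre.labels.stickiness_class
        if target == "stickiness"
        else pre.labels.attention_state
    )
    behav = stats.behavior_summary(
        pre.epochs_tf.trial_meta,
        pre.labels,
        which=target,
    )
    nogo = {
        k: v.nogo_accuracy
        for k, v in behav.items()
        if v.nogo_accuracy is not None
    }
    return rep_with, rep_without, itc_vals, nogo


def run_study(
    config: SimConfig,
    n_participants: int,
    seed: int,
    target: str = "stickiness",
    alpha: float = 0.01,
) -> StudyResult:
    """Simulate and analyse a cohort; deterministic given ``seed``.

    Participants raising :class:`EmptyClassError` anywhere along the chain
    (an empty label class, too few trials to split) are excluded and listed
    in the result.
    """
    participants: List[ParticipantResult] = []
    excluded: List[int] = []
    for i in range(n_participants):
        pseed = _participant_seed(seed, i)
        try:
            rep_w, rep_wo, itc_vals, nogo = _participant(
                config, target, alpha, pseed
            )
        except EmptyClassError:
            excluded.append(i)
            continue
        participants.append(
            ParticipantResult(
                participant=i,
                seed=pseed,
                with_ssvep=rep_w,
                without_ssvep=rep_wo,
                itc_fundamental=itc_vals,
                nogo_accuracy=nogo,
            )
        )
    if not participants:
        raise EmptyClassError("all simulated participants were excluded")

    acc_w = [p.with_ssvep.accuracy for p in participants]
    acc_wo = [p.without_ssvep.accuracy for p in participants]
    comparison = (
        stats.paired_test(acc_w, acc_wo) if len(participants) >= 2 else None
    )
    return StudyResult(
        target=target,
        seed=seed,
        n_requested=n_participants,
        participants=participants,
        excluded=excluded,
        mean_accuracy_with=float(np.mean(acc_w)),
        mean_accuracy_without=float(np.mean(acc_wo)),
        variant_comparison=comparison,
    )


def compare_variants(study: StudyResult) -> PairedTestResult:
    """Paired t / BF on per-participant accuracies (with − without SSVEP)."""
    if len(study.participants) < 2:
        raise ValueError("need >= 2 participants with both variants")
    return stats.paired_test(
        [p.with_ssvep.accuracy for p in study.participants],
        [p.without_ssvep.accuracy for p in study.participants],
    )
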