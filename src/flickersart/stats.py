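"""Behavioural summaries and inferential statistics.

Condition contrasts use the paired t-test together with the default
Jeffreys–Zellner–Siow (JZS) Bayes factor for a paired/one-sample design: a
Cauchy(0, r) prior on the standardized effect size (r = √2/2 by default),
expressed as the usual normal scale mixture with g ~ InverseGamma(1/2, r²/2)
and integrated by adaptive quadrature. BF₁₀ > 3 is read as evidence for the
alternative, < 0.3 as evidence for the null, anything between as
inconclusive.

Behavioural measures follow the task's conventions: Go accuracy is the
response rate on Go trials, Nogo accuracy the withhold rate on Nogo trials,
RT statistics are computed over responded Go trials only, and cvRT is the
sample standard deviation of RT divided by its mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

from .containers import TrialLabels

__all__ = [
    "BehaviorSummary",
    "PairedTestResult",
    "behavior_summary",
    "paired_t",
    "jzs_bf10",
    "interpret_bf",
    "paired_test",
    "DEFAULT_PRIOR_SCALE",
]

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


@dataclass
class BehaviorSummary:
    """Go/Nogo accuracy and RT statistics within one condition."""

    grouping: str
    n_go: int
    n_nogo: int
    go_accuracy: Optional[float]
    nogo_accuracy: Optional[float]
    rt_mean: Optional[float]
    rt_sd: Optional[float]
    rt_cv: Optional[float]


@dataclass
class PairedTestResult:
    """Paired t-test with its JZS Bayes factor."""

    t: float
    df: int
    p: float
    bf10: float
    n: int
    interpretation: str


def behavior_summary(
    trial_meta: pd.DataFrame,
    labels: Optional[TrialLabels] = None,
    which: str = "stickiness",
) -> Dict[str, BehaviorSummary]:
    """Per-condition behavioural summary.

    ``trial_meta`` needs columns ``trial_type`` (go/nogo), ``responded`` and
    ``rt`` (s, NaN when withheld). With ``labels`` given, summaries are
    computed within each label class of the chosen labeling (``"stickiness"``
    or ``"attention"``), skipping ``excluded``; otherwise a single
    ``"overall"`` summary is returned.
    """
    if labels is None:
        groups = {"overall": np.ones(len(trial_meta), dtype=bool)}
    else:
        lab = (
            labels.stickiness_class if which == "stickiness" else labels.attention_state
        )
        classes = [c for c in pd.unique(lab) if c != "excluded"]
        groups = {c: lab == c for c in classes}

    out: Dict[str, BehaviorSummary] = {}
    for name, mask in groups.items():
        sub = trial_meta.loc[np.asarray(mask)]
        go = sub[sub["trial_type"] == "go"]
        nogo = sub[sub["trial_type"] == "nogo"]
        go_acc = float(go["responded"].mean()) if len(go) else None
        nogo_acc = float((~nogo["responded"].astype(bool)).mean()) if len(nogo) else None
        rts = go.loc[go["responded"].astype(bool), "rt"].dropna().to_numpy()
        if rts.size:
            rt_mean = float(rts.mean())
            rt_sd = float(rts.std(ddof=1)) if rts.size > 1 else 0.0
            rt_cv = rt_sd / rt_mean if rt_mean > 0 else None
        else:
            rt_mean = rt_sd = rt_cv = None
        out[name] = BehaviorSummary(
            grouping=name,
            n_go=len(go),
            n_nogo=len(nogo),
            go_accuracy=go_acc,
            nogo_accuracy=nogo_acc,
            rt_mean=rt_mean,
            rt_sd=rt_sd,
            rt_cv=rt_cv,
        )
    return out


def paired_t(x: Sequence[float], y: Sequence[float]):
    """Paired t-test on differences x − y: returns (t, df, two-sided p).

    Zero-variance differences with a nonzero mean give t = ±inf with p = 0
    (flagged by the infinite statistic); identical samples give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, d.mean()), df, 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def _jzs_integrand(g: float, t: float, n: int, r: float) -> float:
    """Integrand of the JZS marginal-likelihood ratio at mixing variance g.

    (1+ng)^(-1/2) · [(1 + t²/((1+ng)ν)) / (1 + t²/ν)]^(-(ν+1)/2) · π(g),
    π(g) the InverseGamma(1/2, r²/2) density; the ratio form keeps the
    numerator/denominator likelihoods from underflowing at large |t|.
    """
    nu = n - 1
    t2 = t * t
    log_like = -0.5 * math.log1p(n * g) - 0.5 * (nu + 1) * (
        math.log1p(t2 / ((1.0 + n * g) * nu)) - math.log1p(t2 / nu)
    )
    log_prior = (
        math.log(r)
        - 0.5 * math.log(2.0 * math.pi)
        - 1.5 * math.log(g)
        - r * r / (2.0 * g)
    )
    return math.exp(log_like + log_prior)


def jzs_bf10(
    t: float, n: int, r: float = DEFAULT_PRIOR_SCALE, epsrel: float = 1e-10
) -> float:
    """Two-sided JZS Bayes factor BF₁₀ for a paired design from (t, n).

    ``n`` is the number of pairs (df = n − 1); ``r`` the Cauchy prior scale
    on the standardized effect size. Depends on the data only through t and
    n. The scale-mixture integral is evaluated by adaptive quadrature to a
    relative tolerance well below 1e-8.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    if r <= 0:
        raise ValueError("prior scale r must be positive")

    def compactified(u: float) -> float:
        # g = u / (1 - u) maps (0, 1) onto (0, inf); jacobian 1 / (1 - u)^2
        g = u / (1.0 - u)
        return _jzs_integrand(g, t, n, r) / (1.0 - u) ** 2

    # split at the prior's bulk (g = r^2) to help the adaptive rule
    u_split = r * r / (1.0 + r * r)
    val1, _ = integrate.quad(
        compactified, 0.0, u_split, epsabs=0.0, epsrel=epsrel, limit=200
    )
    val2, _ = integrate.quad(
        compactified, u_split, 1.0, epsabs=0.0, epsrel=epsrel, limit=200
    )
    return val1 + val2


def interpret_bf(bf10: float) -> str:
    """Evidence category: <0.3 null, >3 alternative, otherwise inconclusive."""
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    if bf10 < 0.3:
        return "supports_null"
    if bf10 > 3.0:
        return "supports_alternative"
    return "inconclusive"


def paired_test(
    x: Sequence[float], y: Sequence[float], r: float = DEFAULT_PRIOR_SCALE
) -> PairedTestResult:
    """Paired t-test plus JZS BF₁₀ in one result record."""
    t, df, p = paired_t(x, y)
    n = df + 1
    # zero-variance differences: the point null is excluded outright
    bf = jzs_bf10(t, n, r=r) if math.isfinite(t) else math.inf
    return PairedTestResult(
        t=t, df=df, p=p, bf10=bf, n=n, interpretation=interpret_bf(bf)
    )
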