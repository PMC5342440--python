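"""Publication-bias diagnostics: Egger's regression, the Begg-Mazumdar rank
correlation, and funnel-plot data export.

Egger's test regresses the standardized effect θ/SE on precision 1/SE by
ordinary least squares; a non-zero intercept indicates small-study
asymmetry. Begg's test rank-correlates variance-stabilized deviations from
the fixed-effect pool with the study variances, with the usual continuity
correction on the normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import EffectEstimate

__all__ = ["BiasTestResult", "egger_test", "begg_test", "funnel_data"]


@dataclass(frozen=True)
class BiasTestResult:
    """Result of one publication-bias test.

    ``statistic`` is the Egger intercept or the Kendall tau; ``detail``
    carries per-test extras (intercept SE and t for Egger; concordant and
    discordant pair counts and the continuity-corrected z for Begg).
    """

    test: str
    statistic: float
    p: float
    k: int
    detail: dict


def egger_test(estimates: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's linear regression test for funnel-plot asymmetry.

    OLS of θ_i/SE_i on 1/SE_i over k >= 3 studies; the intercept is tested
    two-sided against t with k-2 degrees of freedom. A perfectly collinear
    design (all precisions equal) is singular and raises.
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Egger's test needs at least 3 studies")
    se = np.array([e.se for e in estimates], dtype=float)
    theta = np.array([e.log_or for e in estimates], dtype=float)
    precision = 1.0 / se
    snd = theta / se
    if np.ptp(precision) == 0:
        raise ValueError("all precisions identical: Egger design is singular")
    fit = stats.linregress(precision, snd)
    intercept = float(fit.intercept)
    intercept_se = float(fit.intercept_stderr)
    if intercept_se == 0:
        # Exact linear data: zero residual variance. Report a finite answer.
        t_stat = np.inf if intercept != 0 else 0.0
        p = 0.0 if intercept != 0 else 1.0
    else:
        t_stat = intercept / intercept_se
        p = float(2 * stats.t.sf(abs(t_stat), df=k - 2))
    return BiasTestResult(
        test="egger",
        statistic=intercept,
        p=p,
        k=k,
        detail={
            "intercept_se": intercept_se,
            "t": float(t_stat),
            "slope": float(fit.slope),
            "df": k - 2,
        },
    )


def begg_test(estimates: Sequence[EffectEstimate]) -> BiasTestResult:
    """Begg-Mazumdar rank correlation test.

    With fixed-effect pooled θ̂ and W = Σ 1/SE², the variance-stabilized
    deviates u_i = (θ_i - θ̂)/sqrt(SE_i² - 1/W) are rank-correlated with the
    variances SE_i² (Kendall's tau from concordant/discordant pair counts).
    z = (P - Q)/sqrt(k(k-1)(2k+5)/18) with |P - Q| reduced by 1 as a
    continuity correction; p is the two-sided normal tail.
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("Begg's test needs at least 2 studies")
    se = np.array([e.se for e in estimates], dtype=float)
    theta = np.array([e.log_or for e in estimates], dtype=float)
    v = se**2
    w = 1.0 / v
    theta_fixed = (w * theta).sum() / w.sum()
    stabilized_var = v - 1.0 / w.sum()
    if np.any(stabilized_var <= 0):
        raise ValueError("degenerate variances: a stabilized variance is non-positive")
    u = (theta - theta_fixed) / np.sqrt(stabilized_var)
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise ValueError("tau undefined: zero variance of ranks")

    concordant = discordant = 0
    for i in range(k - 1):
        du = u[i + 1:] - u[i]
        dv = v[i + 1:] - v[i]
        prod = np.sign(du) * np.sign(dv)
        concordant += int((prod > 0).sum())
        discordant += int((prod < 0).sum())
    n_pairs = k * (k - 1) // 2
    tau = (concordant - discordant) / n_pairs
    diff = concordant - discordant
    corrected = np.sign(diff) * max(0, abs(diff) - 1)
    z = corrected / np.sqrt(k * (k - 1) * (2 * k + 5) / 18)
    p = float(2 * stats.norm.sf(abs(z)))
    return BiasTestResult(
        test="begg",
        statistic=float(tau),
        p=p,
        k=k,
        detail={"concordant": concordant, "discordant": discordant, "z": float(z)},
    )


def funnel_data(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Per-study rows sufficient to draw a funnel plot externally.

    Columns: ``or`` (odds ratio), ``se`` (SE of the log OR), ``precision``
    (1/SE) and ``snd`` (standardized effect θ/SE). Export with
    ``df.to_csv(path, sep='\\t', index=False)``.
    """
    if len(estimates) == 0:
        raise ValueError("funnel_data needs at least one estimate")
    return pd.DataFrame(
        {
            "or": [e.or_ for e in estimates],
            "se": [e.se for e in estimates],
            "precision": [1.0 / e.se for e in estimates],
            "snd": [e.log_or / e.se for e in estimates],
        }
    )
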