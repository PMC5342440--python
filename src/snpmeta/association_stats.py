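"""Per-study association statistics.

Crude (unadjusted) odds ratios with Woolf standard errors, and the Pearson
chi-square test of Hardy-Weinberg equilibrium in control genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .genetic_models import TwoByTwo
from .study_io import GenotypeCounts

__all__ = ["EffectEstimate", "HWEResult", "woolf_estimate", "hwe_chi_square"]


@dataclass(frozen=True)
class EffectEstimate:
    """A per-study log odds ratio with its Woolf standard error.

    The 95% CI (or another level, recorded implicitly by the caller), the
    Wald z statistic and its two-sided normal p-value are precomputed.
    """

    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    study_id: Optional[str] = None

    def scaled(self, factor: float) -> "EffectEstimate":
        """The same estimate with effect and SE multiplied by ``factor > 0``
        (a pure change of units; used in invariance checks)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return EffectEstimate(
            log_or=self.log_or * factor,
            se=self.se * factor,
            or_=float(np.exp(self.log_or * factor)),
            ci_low=float(np.exp((self.log_or - self._zcrit() * self.se) * factor)),
            ci_high=float(np.exp((self.log_or + self._zcrit() * self.se) * factor)),
            z=self.z,
            p=self.p,
            study_id=self.study_id,
        )

    def _zcrit(self) -> float:
        # Recover the critical value from the stored CI; falls back to 95%.
        if self.se > 0:
            return (np.log(self.ci_high) - self.log_or) / self.se
        return 1.959963984540054


def woolf_estimate(
    table: TwoByTwo, ci_level: float = 0.95, study_id: Optional[str] = None
) -> EffectEstimate:
    """Crude odds ratio of a 2x2 table with the Woolf variance.

    log OR = ln(ad/bc), SE = sqrt(1/a + 1/b + 1/c + 1/d). All four cells
    must be positive; resolve zeros with a zero-cell policy first.
    """
    a, b, c, d = table.cells()
    if min(a, b, c, d) <= 0:
        raise ValueError(
            "woolf_estimate requires all cells > 0; "
            "apply a zero-cell policy (drop or haldane) first"
        )
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    zcrit = float(stats.norm.ppf(0.5 + ci_level / 2))
    z = log_or / se
    return EffectEstimate(
        log_or=log_or,
        se=se,
        or_=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - zcrit * se)),
        ci_high=float(np.exp(log_or + zcrit * se)),
        z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        study_id=study_id,
    )


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square goodness-of-fit to Hardy-Weinberg proportions."""

    chi2: float
    df: int
    p: float
    expected: tuple[float, float, float]


def hwe_chi_square(controls: GenotypeCounts) -> HWEResult:
    """Hardy-Weinberg equilibrium test on one control arm.

    The rare-allele frequency q is estimated from the counts; expected
    genotype counts are n*((1-q)^2, 2q(1-q), q^2) and the three-cell Pearson
    chi-square is referred to a chi-square distribution with 1 degree of
    freedom (3 cells - 1 - 1 estimated allele frequency). Monomorphic arms
    (q = 0 or 1) fit exactly by convention: chi2 = 0, p = 1.
    """
    n = controls.total
    if n == 0:
        raise ValueError("cannot test HWE on an empty arm")
    q = controls.n_rare_allele / (2 * n)
    expected = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2)
    if q == 0.0 or q == 1.0:
        return HWEResult(chi2=0.0, df=1, p=1.0, expected=expected)
    observed = np.asarray(controls.as_tuple(), dtype=float)
    chi2 = float((((observed - np.asarray(expected)) ** 2) / np.asarray(expected)).sum())
    return HWEResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, df=1)), expected=expected)
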