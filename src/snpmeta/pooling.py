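"""Pooling of per-study odds ratios: fixed effect (inverse-variance and
Mantel-Haenszel), DerSimonian-Laird random effects, Cochran Q / I-squared
heterogeneity, data-driven model selection, subgroup pooling and
leave-one-out sensitivity analysis.

Conventions
-----------
* Heterogeneity (Q, its p-value, I², τ²) is always computed from fixed
  inverse-variance weights, whatever method reports the pooled effect.
* ``select_model`` applies the conventional rule: random effects when the
  heterogeneity p-value is below 0.1 or I² exceeds 50%, fixed otherwise.
* With a single study Q = 0, the heterogeneity p-value is defined as 1 and
  I² as 0; τ² is 0 under any fixed-effect method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .association_stats import EffectEstimate, woolf_estimate
from .genetic_models import (
    MODELS,
    TwoByTwo,
    apply_zero_cell_policy,
    build_contrast,
    table_from_precollapsed,
)
from .study_io import StudyRecord, StudyTable, filter_table

__all__ = [
    "PooledResult",
    "pool_fixed_iv",
    "pool_fixed_mh",
    "dersimonian_laird",
    "select_model",
    "pool",
    "subgroup_pool",
    "leave_one_out",
]

METHODS = ("fixed_iv", "fixed_mh", "random_dl")


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with heterogeneity statistics.

    ``q`` is Cochran's Q from fixed inverse-variance weights; ``p_het`` its
    chi-square (k-1 df) p-value; ``i2`` = max(0, (Q-(k-1))/Q)*100; ``tau2``
    the DerSimonian-Laird between-study variance (0 for fixed methods).
    """

    k: int
    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    p_het: float
    i2: float
    tau2: float
    method: str
    log_or: float = 0.0
    se: float = 0.0
    contributing_ids: tuple[str, ...] = ()
    excluded_ids: tuple[str, ...] = ()


def _arrays(estimates: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty list of estimates")
    theta = np.array([e.log_or for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    return theta, se


def _heterogeneity(theta: np.ndarray, se: np.ndarray) -> tuple[float, float, float]:
    """(Q, p_het, I²) from fixed inverse-variance weights."""
    w = 1.0 / se**2
    theta_fixed = float((w * theta).sum() / w.sum())
    q = float((w * (theta - theta_fixed) ** 2).sum())
    k = len(theta)
    if k == 1:
        return 0.0, 1.0, 0.0
    p_het = float(stats.chi2.sf(q, df=k - 1))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return q, p_het, i2


def _finish(
    log_or: float,
    se: float,
    k: int,
    q: float,
    p_het: float,
    i2: float,
    tau2: float,
    method: str,
    ci_level: float,
    contributing_ids: tuple[str, ...],
    excluded_ids: tuple[str, ...] = (),
) -> PooledResult:
    zcrit = float(stats.norm.ppf(0.5 + ci_level / 2))
    z = log_or / se
    return PooledResult(
        k=k,
        pooled_or=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - zcrit * se)),
        ci_high=float(np.exp(log_or + zcrit * se)),
        z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        q=q,
        p_het=p_het,
        i2=i2,
        tau2=tau2,
        method=method,
        log_or=float(log_or),
        se=float(se),
        contributing_ids=contributing_ids,
        excluded_ids=excluded_ids,
    )


def _ids(estimates: Sequence[EffectEstimate]) -> tuple[str, ...]:
    return tuple(e.study_id or f"study{i + 1}" for i, e in enumerate(estimates))


def pool_fixed_iv(
    estimates: Sequence[EffectEstimate], ci_level: float = 0.95
) -> PooledResult:
    """Fixed-effect inverse-variance pooling of log odds ratios.

    Weights are 1/SE²; the pooled SE is 1/sqrt(sum of weights).
    """
    theta, se = _arrays(estimates)
    w = 1.0 / se**2
    log_or = float((w * theta).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    q, p_het, i2 = _heterogeneity(theta, se)
    return _finish(
        log_or, pooled_se, len(estimates), q, p_het, i2, 0.0,
        "fixed_iv", ci_level, _ids(estimates),
    )


def pool_fixed_mh(
    tables: Sequence[TwoByTwo], ci_level: float = 0.95,
    study_ids: Optional[Sequence[str]] = None,
) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled odds ratio.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the variance of its log
    is the Robins-Breslow-Greenland estimator. Single zero cells are
    tolerated (they simply contribute nothing to one of the sums).
    Heterogeneity is reported from Woolf estimates of the same tables, with
    the Haldane correction applied to zero-cell tables for that purpose.
    """
    if len(tables) == 0:
        raise ValueError("cannot pool an empty list of tables")
    a = np.array([t.a for t in tables], dtype=float)
    b = np.array([t.b for t in tables], dtype=float)
    c = np.array([t.c for t in tables], dtype=float)
    d = np.array([t.d for t in tables], dtype=float)
    n = a + b + c + d
    r = a * d / n
    s = b * c / n
    if s.sum() == 0 or r.sum() == 0:
        raise ValueError("Mantel-Haenszel odds ratio is inestimable (a zero marginal sum)")
    log_or = float(np.log(r.sum() / s.sum()))
    # Robins-Breslow-Greenland variance of log(OR_MH)
    p_t = (a + d) / n
    q_t = (b + c) / n
    var = (
        (p_t * r).sum() / (2 * r.sum() ** 2)
        + ((p_t * s + q_t * r).sum()) / (2 * r.sum() * s.sum())
        + (q_t * s).sum() / (2 * s.sum() ** 2)
    )
    pooled_se = float(np.sqrt(var))

    woolf = [
        woolf_estimate(apply_zero_cell_policy(t, "haldane"))
        for t in tables
    ]
    theta_w, se_w = _arrays(woolf)
    q, p_het, i2 = _heterogeneity(theta_w, se_w)
    ids = tuple(study_ids) if study_ids is not None else tuple(
        f"study{i + 1}" for i in range(len(tables))
    )
    return _finish(log_or, pooled_se, len(tables), q, p_het, i2, 0.0,
                   "fixed_mh", ci_level, ids)


def dersimonian_laird(
    estimates: Sequence[EffectEstimate], ci_level: float = 0.95
) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    τ² = max(0, (Q - (k-1)) / (Σw - Σw²/Σw)) with fixed weights w = 1/SE²;
    studies are then re-weighted by 1/(SE² + τ²). With a single study the
    result falls back to the fixed-effect answer.
    """
    theta, se = _arrays(estimates)
    k = len(estimates)
    if k == 1:
        res = pool_fixed_iv(estimates, ci_level=ci_level)
        return PooledResult(**{**res.__dict__, "method": "random_dl"})
    w = 1.0 / se**2
    q, p_het, i2 = _heterogeneity(theta, se)
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    log_or = float((w_star * theta).sum() / w_star.sum())
    pooled_se = float(1.0 / np.sqrt(w_star.sum()))
    return _finish(log_or, pooled_se, k, q, p_het, i2, tau2,
                   "random_dl", ci_level, _ids(estimates))


def select_model(
    q: float,
    k: int,
    p_het: float,
    i2: float,
    p_threshold: float = 0.1,
    i2_threshold: float = 50.0,
) -> str:
    """Conventional heterogeneity-driven model choice.

    Random effects when the Q test is significant (p_het < p_threshold) or
    I² exceeds i2_threshold; fixed inverse-variance otherwise.
    """
    if p_het < p_threshold or i2 > i2_threshold:
        return "random_dl"
    return "fixed_iv"


@dataclass(frozen=True)
class _Prepared:
    estimates: tuple[EffectEstimate, ...]
    tables: tuple[TwoByTwo, ...]
    excluded: tuple[str, ...]
    skipped: tuple[str, ...]


def _prepare(
    records: Sequence[StudyRecord], model: str, zero_policy: str, ci_level: float
) -> _Prepared:
    """Contrast tables + Woolf estimates for every usable record; bookkeeping
    of zero-cell exclusions and unusable (incomplete / wrong-collapse) rows."""
    estimates, tables, excluded, skipped = [], [], [], []
    for rec in records:
        if rec.kind == "genotype":
            t = build_contrast(rec.cases, rec.controls, model)
        elif rec.kind == "collapsed" and rec.cases.model_label == model:
            t = table_from_precollapsed(rec.cases, rec.controls, model)
        else:
            skipped.append(rec.study_id)
            continue
        resolved = apply_zero_cell_policy(t, zero_policy)
        if resolved is None:
            excluded.append(rec.study_id)
            continue
        tables.append(resolved)
        estimates.append(woolf_estimate(resolved, ci_level=ci_level, study_id=rec.study_id))
    return _Prepared(tuple(estimates), tuple(tables), tuple(excluded), tuple(skipped))


def pool(
    table: StudyTable,
    snp: str,
    model: str,
    method: str = "auto",
    zero_policy: str = "drop",
    ci_level: float = 0.95,
    het_p_threshold: float = 0.1,
    i2_threshold: float = 50.0,
) -> PooledResult:
    """End-to-end pooling driver for one SNP and one genetic contrast.

    Selects the records for ``snp``, builds the contrast tables, applies the
    zero-cell policy, estimates per-study Woolf log odds ratios, picks the
    pooling method (when ``method='auto'``, via :func:`select_model`) and
    pools. Studies excluded by the zero-cell policy are recorded in
    ``excluded_ids``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    if method not in ("auto",) + METHODS:
        raise ValueError(f"unknown pooling method {method!r}")
    records = [r for r in table if r.snp_id == snp]
    if not records:
        raise ValueError(f"no studies for SNP {snp!r} in table {table.source!r}")
    prep = _prepare(records, model, zero_policy, ci_level)
    if not prep.estimates:
        raise ValueError(
            f"no estimable studies for {snp}/{model}: "
            f"zero-cell exclusions {list(prep.excluded)}, unusable {list(prep.skipped)}"
        )
    if method == "fixed_mh":
        res = pool_fixed_mh(
            prep.tables, ci_level=ci_level,
            study_ids=[e.study_id for e in prep.estimates],
        )
    else:
        if method == "auto":
            theta, se = _arrays(prep.estimates)
            _, p_het, i2 = _heterogeneity(theta, se)
            method = select_model(0.0, len(prep.estimates), p_het, i2,
                                  het_p_threshold, i2_threshold)
        if method == "fixed_iv":
            res = pool_fixed_iv(prep.estimates, ci_level=ci_level)
        else:
            res = dersimonian_laird(prep.estimates, ci_level=ci_level)
    return PooledResult(**{**res.__dict__, "excluded_ids": prep.excluded})


def subgroup_pool(
    table: StudyTable,
    snp: str,
    model: str,
    by: str,
    method: str = "auto",
    zero_policy: str = "drop",
    ci_level: float = 0.95,
) -> dict[str, Optional[PooledResult]]:
    """Pool independently within each level of a metadata field.

    Returns a mapping group value -> PooledResult; groups with no estimable
    study map to None (reported as absent rather than raising).
    """
    records = [r for r in table if r.snp_id == snp]
    if not records:
        raise ValueError(f"no studies for SNP {snp!r}")
    groups: dict[str, None] = {}
    for r in records:
        md = r.metadata()
        if by not in md:
            raise KeyError(f"unknown metadata field: {by!r}")
        groups.setdefault(str(md[by]), None)
    out: dict[str, Optional[PooledResult]] = {}
    for g in groups:
        sub = filter_table(StudyTable(tuple(records), table.source), {by: g})
        try:
            out[g] = pool(sub, snp, model, method=method,
                          zero_policy=zero_policy, ci_level=ci_level)
        except ValueError:
            out[g] = None
    return out


def leave_one_out(
    table: StudyTable,
    snp: str,
    model: str,
    method: str = "auto",
    zero_policy: str = "drop",
    ci_level: float = 0.95,
) -> list[tuple[str, PooledResult]]:
    """Sensitivity analysis: re-pool with each contributing study omitted.

    Requires at least two contributing studies; the k = 2 case degenerates
    to each remaining single-study estimate.
    """
    full = pool(table, snp, model, method=method, zero_policy=zero_policy,
                ci_level=ci_level)
    if full.k < 2:
        raise ValueError("leave-one-out needs at least two contributing studies")
    out = []
    for omit in full.contributing_ids:
        remaining = StudyTable(
            tuple(r for r in table if not (r.snp_id == snp and r.study_id == omit)),
            table.source,
        )
        out.append((omit, pool(remaining, snp, model, method=method,
                               zero_policy=zero_policy, ci_level=ci_level)))
    return out
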