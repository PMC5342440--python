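"""Synthetic case-control genotype data with known truth.

Each simulated study draws a control minor-allele frequency, puts the
controls in exact Hardy-Weinberg proportions, and tilts those proportions
exponentially by a per-study log odds ratio to obtain the case genotype
distribution (a logistic disease model under the rare-disease
approximation: the target OR holds exactly in expectation for the allele
dose used). Between-study heterogeneity enters as a normal random effect on
the log OR with variance tau2. An optional selection rule suppresses
"unpublished" studies — those whose crude allele-model p-value exceeds a
threshold and whose estimated effect points in a given direction — and the
generator keeps drawing candidate studies until the requested number
survive, mimicking a published literature of fixed size.

Randomness is reproducible: study ``i`` uses the dedicated substream
``default_rng([seed, i])``, so changing k extends a table without
reshuffling earlier studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .association_stats import hwe_chi_square, HWEResult, woolf_estimate
from .genetic_models import apply_zero_cell_policy, build_contrast
from .study_io import GenotypeCounts, StudyRecord, StudyTable

__all__ = [
    "SelectionRule",
    "SimulationConfig",
    "simulate_study_set",
    "hwe_conformity_check",
]

#: Genotype dose per copy-number of the effect allele, by generating model.
_DOSES = {
    "allele": (0.0, 1.0, 2.0),
    "dominant": (0.0, 1.0, 1.0),
    "recessive": (0.0, 0.0, 1.0),
}


@dataclass(frozen=True)
class SelectionRule:
    """Small-study suppression: a candidate study is dropped with
    probability ``prob`` when its crude allele-model p-value exceeds
    ``p_threshold`` and its estimated log OR has sign ``direction``."""

    p_threshold: float = 0.2
    direction: int = 1
    prob: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if not 0 <= self.prob <= 1:
            raise ValueError("prob must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-set generator settings.

    Defaults emulate the shape of the bundled real table: a literature of
    k = 15 studies, control minor-allele frequencies between 5% and 35%,
    arm sizes of a few hundred to a few thousand, allele-dose genetics, no
    heterogeneity and no selection.
    """

    k: int = 15
    true_log_or: float = 0.0
    tau2: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.35)
    n_cases_range: tuple[int, int] = (200, 2000)
    n_controls_range: tuple[int, int] = (200, 2000)
    genetic_model: str = "allele"
    selection: Optional[SelectionRule] = None
    seed: int = 0
    snp_id: str = "rs_sim"
    max_attempts_per_study: int = 50

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for name in ("n_cases_range", "n_controls_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a non-empty positive interval")
        if self.genetic_model not in _DOSES:
            raise ValueError(
                f"genetic_model must be one of {tuple(_DOSES)} for generation"
            )


def _case_probs(control_probs: np.ndarray, log_or: float, doses) -> np.ndarray:
    tilt = control_probs * np.exp(log_or * np.asarray(doses))
    return tilt / tilt.sum()


def _draw_study(cfg: SimulationConfig, stream_index: int) -> StudyRecord:
    rng = np.random.default_rng([cfg.seed, stream_index])
    q = rng.uniform(*cfg.maf_range)
    theta = cfg.true_log_or + (
        rng.normal(0.0, np.sqrt(cfg.tau2)) if cfg.tau2 > 0 else 0.0
    )
    n_cases = int(rng.integers(cfg.n_cases_range[0], cfg.n_cases_range[1] + 1))
    n_controls = int(rng.integers(cfg.n_controls_range[0], cfg.n_controls_range[1] + 1))
    control_probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    case_probs = _case_probs(control_probs, theta, _DOSES[cfg.genetic_model])
    case_counts = rng.multinomial(n_cases, case_probs)
    ctrl_counts = rng.multinomial(n_controls, control_probs)
    return StudyRecord(
        study_id=f"sim{stream_index:04d}",
        snp_id=cfg.snp_id,
        cases=GenotypeCounts(*map(int, case_counts)),
        controls=GenotypeCounts(*map(int, ctrl_counts)),
        effect_allele="C",
        ethnicity="Simulated",
        cancer_type="Simulated",
        country="Simulated",
        year=2016,
        extra={"true_log_or": repr(float(theta)), "maf": repr(float(q))},
    )


def _suppressed(rec: StudyRecord, rule: SelectionRule, rng: np.random.Generator) -> bool:
    table = apply_zero_cell_policy(
        build_contrast(rec.cases, rec.controls, "allele"), "haldane"
    )
    est = woolf_estimate(table)
    if est.p > rule.p_threshold and np.sign(est.log_or) == rule.direction:
        return rng.uniform() < rule.prob
    return False


def simulate_study_set(config: SimulationConfig) -> StudyTable:
    """Generate a study table of ``config.k`` studies with known truth.

    Identical configs (including seed) give identical tables. With a
    selection rule, candidate studies are drawn on successive substreams
    until k survive suppression (bounded by ``max_attempts_per_study * k``).
    """
    records = []
    attempt = 0
    limit = config.max_attempts_per_study * config.k
    while len(records) < config.k:
        if attempt >= limit:
            raise RuntimeError(
                f"selection rule suppressed too many studies "
                f"({attempt} candidates for k={config.k})"
            )
        rec = _draw_study(config, attempt)
        if config.selection is not None:
            sel_rng = np.random.default_rng([config.seed, attempt, 1])
            if _suppressed(rec, config.selection, sel_rng):
                attempt += 1
                continue
        records.append(rec)
        attempt += 1
    return StudyTable(tuple(records), source=f"simulated:seed={config.seed}")


def hwe_conformity_check(
    table: StudyTable, alpha: float = 0.05
) -> list[tuple[str, Optional[HWEResult], bool]]:
    """Run the control-arm HWE test over a whole table.

    Returns one (study_id, HWEResult, conforms) triple per full-genotype
    record; records without full genotype data are reported with a None
    result and conforms = False, rather than silently dropped.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out: list[tuple[str, Optional[HWEResult], bool]] = []
    for rec in table:
        if rec.kind != "genotype":
            out.append((rec.study_id, None, False))
            continue
        res = hwe_chi_square(rec.controls)
        out.append((rec.study_id, res, res.p >= alpha))
    return out
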