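"""Genetic contrast construction: genotype counts to 2x2 tables.

Five standard contrasts of a biallelic SNP with effect (minor) allele ``e``
and reference allele ``r``:

==============  =========================  ==========================
model           exposed                    unexposed
==============  =========================  ==========================
allele          e allele count             r allele count
dominant        er + ee carriers           rr
recessive       ee                         rr + er
homozygote      ee                         rr  (heterozygotes dropped)
heterozygote    er                         rr  (rare homozygotes dropped)
==============  =========================  ==========================

The allele model counts alleles (two per individual); the others count
individuals. Zero cells are handled by an explicit policy: ``drop``
excludes the study from that contrast, ``haldane`` adds 0.5 to every cell
(Haldane-Anscombe continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .study_io import GenotypeCounts, PreCollapsed

__all__ = [
    "MODELS",
    "ZERO_CELL_POLICIES",
    "TwoByTwo",
    "InestimableTableError",
    "build_contrast",
    "table_from_precollapsed",
    "apply_zero_cell_policy",
    "contrast_label",
]

MODELS = ("allele", "dominant", "recessive", "homozygote", "heterozygote")
ZERO_CELL_POLICIES = ("drop", "haldane")


class InestimableTableError(ValueError):
    """The contingency table carries no information (an arm is all zero)."""


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table for one genetic contrast.

    a = case-exposed, b = case-unexposed, c = control-exposed,
    d = control-unexposed. Cells are floats so a continuity correction can
    be represented; ``corrected`` records whether one was applied.
    """

    a: float
    b: float
    c: float
    d: float
    contrast: str = ""
    corrected: bool = False

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValueError(f"cell {cell} is negative")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def _collapse(g: GenotypeCounts, model: str) -> tuple[int, int]:
    if model == "allele":
        return g.n_rare_allele, g.n_common_allele
    if model == "dominant":
        return g.n_het + g.n_rare_hom, g.n_common_hom
    if model == "recessive":
        return g.n_rare_hom, g.n_common_hom + g.n_het
    if model == "homozygote":
        return g.n_rare_hom, g.n_common_hom
    if model == "heterozygote":
        return g.n_het, g.n_common_hom
    raise ValueError(f"unknown genetic model {model!r}; expected one of {MODELS}")


def build_contrast(
    counts_case: GenotypeCounts, counts_ctrl: GenotypeCounts, model: str
) -> TwoByTwo:
    """Build the 2x2 table for one genetic contrast.

    Raises
    ------
    ValueError
        for an unknown model name.
    InestimableTableError
        when both arms are all zero for the requested contrast.
    """
    a, b = _collapse(counts_case, model)
    c, d = _collapse(counts_ctrl, model)
    if a + b == 0 and c + d == 0:
        raise InestimableTableError(f"no observations in either arm for {model}")
    return TwoByTwo(a=a, b=b, c=c, d=d, contrast=model)


def table_from_precollapsed(cases: PreCollapsed, controls: PreCollapsed, model: str) -> TwoByTwo:
    """2x2 table from pre-collapsed arms; only valid for their labelled model."""
    if cases.model_label != model:
        raise ValueError(
            f"pre-collapsed counts are for {cases.model_label!r}, not {model!r}"
        )
    return TwoByTwo(
        a=cases.n_exposed, b=cases.n_unexposed,
        c=controls.n_exposed, d=controls.n_unexposed,
        contrast=model,
    )


def apply_zero_cell_policy(table: TwoByTwo, policy: str = "drop") -> Optional[TwoByTwo]:
    """Resolve zero cells: ``drop`` returns None (exclude the study from the
    contrast), ``haldane`` adds 0.5 to all four cells. Tables without zero
    cells pass through unchanged."""
    if policy not in ZERO_CELL_POLICIES:
        raise ValueError(f"unknown zero-cell policy {policy!r}; expected one of {ZERO_CELL_POLICIES}")
    if not table.has_zero_cell:
        return table
    if policy == "drop":
        return None
    return replace(
        table,
        a=table.a + 0.5, b=table.b + 0.5, c=table.c + 0.5, d=table.d + 0.5,
        corrected=True,
    )


def contrast_label(model: str, effect_allele: str, reference_allele: str) -> str:
    """Human-readable contrast heading, e.g. ``C vs. A`` or ``CC+AC vs. AA``."""
    e, r = effect_allele, reference_allele
    if model == "allele":
        return f"{e} vs. {r}"
    if model == "dominant":
        return f"{e}{e}+{r}{e} vs. {r}{r}"
    if model == "recessive":
        return f"{e}{e} vs. {r}{r}+{r}{e}"
    if model == "homozygote":
        return f"{e}{e} vs. {r}{r}"
    if model == "heterozygote":
        return f"{r}{e} vs. {r}{r}"
    raise ValueError(f"unknown genetic model {model!r}")
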