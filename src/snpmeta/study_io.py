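"""Reading, validating and filtering case-control genotype study tables.

A *study* is one case-control comparison for one SNP: three genotype counts
per arm (common homozygote, heterozygote, rare homozygote) plus metadata.
Tables are plain CSV with one row per study; the bundled example table
(``load_example_table``) carries the genotype counts of a published
multi-SNP cancer meta-analysis and is the fixture used throughout the test
suite.

Rows that print partial genotype data (some cells "NA") but no collapsed
two-by-two counts are kept as *incomplete* records: they survive reading so
the table row count matches the source, but they are unusable for any
contrast and downstream drivers skip them with a note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Optional, Union

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "PreCollapsed",
    "StudyRecord",
    "StudyTable",
    "SchemaError",
    "ValidationError",
    "read_study_table",
    "write_study_table",
    "filter_table",
    "load_example_table",
]

#: Required CSV columns, in canonical order.
REQUIRED_COLUMNS = (
    "study_id", "year", "country", "ethnicity", "cancer_type",
    "snp_id", "effect_allele",
    "case_g0", "case_g1", "case_g2", "ctrl_g0", "ctrl_g1", "ctrl_g2",
)

#: Optional columns carrying pre-collapsed 2x2 counts for one named contrast.
COLLAPSED_COLUMNS = (
    "case_exposed", "case_unexposed", "ctrl_exposed", "ctrl_unexposed",
    "collapsed_model",
)

METADATA_FIELDS = ("study_id", "snp_id", "ethnicity", "cancer_type", "country", "year")


class SchemaError(ValueError):
    """The input file is missing a required column."""


class ValidationError(ValueError):
    """A row holds an invalid value (negative, non-integer, inconsistent)."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm, ordered common-hom, het, rare-hom."""

    n_common_hom: int
    n_het: int
    n_rare_hom: int

    def __post_init__(self) -> None:
        for name in ("n_common_hom", "n_het", "n_rare_hom"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.n_common_hom + self.n_het + self.n_rare_hom

    @property
    def n_common_allele(self) -> int:
        return 2 * self.n_common_hom + self.n_het

    @property
    def n_rare_allele(self) -> int:
        return 2 * self.n_rare_hom + self.n_het

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_common_hom, self.n_het, self.n_rare_hom)


@dataclass(frozen=True)
class PreCollapsed:
    """A 2x2 arm already collapsed for one named contrast (e.g. dominant)."""

    n_exposed: int
    n_unexposed: int
    model_label: str

    def __post_init__(self) -> None:
        for name in ("n_exposed", "n_unexposed"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")


Arm = Union[GenotypeCounts, PreCollapsed, None]


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study of one SNP.

    ``cases``/``controls`` are either both :class:`GenotypeCounts` (full
    genotype data), both :class:`PreCollapsed` (only one collapsed contrast
    available), or both ``None`` (incomplete source row, kept for
    bookkeeping but unusable).
    """

    study_id: str
    snp_id: str
    cases: Arm
    controls: Arm
    effect_allele: str = ""
    ethnicity: str = ""
    cancer_type: str = ""
    country: str = ""
    year: int = 0
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if type(self.cases) is not type(self.controls):
            raise ValidationError(
                f"{self.study_id}/{self.snp_id}: cases and controls must have "
                "the same shape (both genotype, both collapsed, or both absent)"
            )
        if isinstance(self.cases, PreCollapsed) and isinstance(self.controls, PreCollapsed):
            if self.cases.model_label != self.controls.model_label:
                raise ValidationError(
                    f"{self.study_id}/{self.snp_id}: collapsed model labels differ"
                )

    @property
    def kind(self) -> str:
        if isinstance(self.cases, GenotypeCounts):
            return "genotype"
        if isinstance(self.cases, PreCollapsed):
            return "collapsed"
        return "incomplete"

    @property
    def usable(self) -> bool:
        return self.kind != "incomplete"

    def metadata(self) -> dict:
        md = {f: getattr(self, f) for f in METADATA_FIELDS}
        md.update(self.extra)
        return md


@dataclass(frozen=True)
class StudyTable:
    """An ordered, validated collection of study records."""

    records: tuple[StudyRecord, ...]
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> StudyRecord:
        return self.records[i]

    @property
    def snp_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.snp_id, None)
        return tuple(seen)

    def for_snp(self, snp_id: str) -> "StudyTable":
        return filter_table(self, {"snp_id": snp_id})


def _parse_count(value, row_label: str, column: str) -> Optional[int]:
    """Parse one count cell; None for NA/empty, ValidationError otherwise."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "" or s.lower() in ("na", "nan"):
            return None
        value = s
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_label}: {column} is not a number: {value!r}")
    if f != int(f):
        raise ValidationError(f"row {row_label}: {column} must be an integer, got {value!r}")
    n = int(f)
    if n < 0:
        raise ValidationError(f"row {row_label}: {column} must be non-negative, got {n}")
    return n


def _row_to_record(row: Mapping, row_label: str, extra_columns) -> StudyRecord:
    geno = {c: _parse_count(row[c], row_label, c)
            for c in ("case_g0", "case_g1", "case_g2", "ctrl_g0", "ctrl_g1", "ctrl_g2")}
    collapsed = {c: _parse_count(row.get(c), row_label, c)
                 for c in ("case_exposed", "case_unexposed", "ctrl_exposed", "ctrl_unexposed")}

    cases: Arm
    controls: Arm
    if all(v is not None for v in geno.values()):
        cases = GenotypeCounts(geno["case_g0"], geno["case_g1"], geno["case_g2"])
        controls = GenotypeCounts(geno["ctrl_g0"], geno["ctrl_g1"], geno["ctrl_g2"])
    elif all(v is not None for v in collapsed.values()):
        label = str(row.get("collapsed_model") or "").strip()
        if not label or label.lower() in ("na", "nan"):
            raise ValidationError(
                f"row {row_label}: collapsed counts given without collapsed_model"
            )
        cases = PreCollapsed(collapsed["case_exposed"], collapsed["case_unexposed"], label)
        controls = PreCollapsed(collapsed["ctrl_exposed"], collapsed["ctrl_unexposed"], label)
    else:
        # Partial genotype data and no collapsed complement: keep the row as
        # an incomplete record so the table mirrors its source line-for-line.
        cases = controls = None

    year = _parse_count(row.get("year"), row_label, "year")
    extra = {c: "" if pd.isna(row[c]) else str(row[c]) for c in extra_columns}
    return StudyRecord(
        study_id=str(row["study_id"]).strip(),
        snp_id=str(row["snp_id"]).strip(),
        cases=cases,
        controls=controls,
        effect_allele=str(row["effect_allele"]).strip(),
        ethnicity=str(row["ethnicity"]).strip(),
        cancer_type=str(row["cancer_type"]).strip(),
        country=str(row["country"]).strip(),
        year=year or 0,
        extra=extra,
    )


def read_study_table(path: Union[str, Path], **csv_options) -> StudyTable:
    """Read and validate a study table from CSV.

    Rows with every genotype cell present become full-genotype records; rows
    with "NA" genotype cells but complete collapsed-count columns become
    pre-collapsed records; rows with partial genotype data and no collapsed
    complement are kept as incomplete (unusable) records. Row order is
    preserved.

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValidationError
        for negative/non-integer counts or duplicate (study_id, snp_id).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **csv_options)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra_columns = [c for c in df.columns
                     if c not in REQUIRED_COLUMNS and c not in COLLAPSED_COLUMNS]

    records = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.to_dict(orient="records")):
        rec = _row_to_record(row, row_label=str(i + 2), extra_columns=extra_columns)
        key = (rec.study_id, rec.snp_id)
        if key in seen:
            raise ValidationError(
                f"duplicate (study_id, snp_id) pair: {key}; merge or relabel the rows"
            )
        seen.add(key)
        records.append(rec)
    if not records:
        raise ValidationError(f"{path}: table is empty")
    return StudyTable(records=tuple(records), source=str(path))


def write_study_table(table: StudyTable, path: Union[str, Path]) -> None:
    """Write a study table back to the canonical CSV schema."""
    rows = []
    for r in table:
        row = {c: "" for c in REQUIRED_COLUMNS + COLLAPSED_COLUMNS}
        row.update(
            study_id=r.study_id, year=r.year, country=r.country,
            ethnicity=r.ethnicity, cancer_type=r.cancer_type,
            snp_id=r.snp_id, effect_allele=r.effect_allele,
        )
        if r.kind == "genotype":
            row.update(zip(("case_g0", "case_g1", "case_g2"), r.cases.as_tuple()))
            row.update(zip(("ctrl_g0", "ctrl_g1", "ctrl_g2"), r.controls.as_tuple()))
        elif r.kind == "collapsed":
            row.update(
                case_g0="NA", case_g1="NA", case_g2="NA",
                ctrl_g0="NA", ctrl_g1="NA", ctrl_g2="NA",
                case_exposed=r.cases.n_exposed, case_unexposed=r.cases.n_unexposed,
                ctrl_exposed=r.controls.n_exposed, ctrl_unexposed=r.controls.n_unexposed,
                collapsed_model=r.cases.model_label,
            )
        else:
            row.update(
                case_g0="NA", case_g1="NA", case_g2="NA",
                ctrl_g0="NA", ctrl_g1="NA", ctrl_g2="NA",
            )
        row.update(r.extra)
        rows.append(row)
    columns = list(REQUIRED_COLUMNS + COLLAPSED_COLUMNS)
    for r in table:
        for k in r.extra:
            if k not in columns:
                columns.append(k)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def filter_table(table: StudyTable, constraints: Mapping[str, object]) -> StudyTable:
    """Sub-table of records matching *all* field=value constraints.

    Constraint fields are the metadata fields (study_id, snp_id, ethnicity,
    cancer_type, country, year) or any extra column carried through from the
    input. An empty constraint set is the identity. The result may be empty.
    """
    for field_name in constraints:
        if field_name not in METADATA_FIELDS and not any(
            field_name in r.extra for r in table
        ):
            raise KeyError(f"unknown metadata field: {field_name!r}")
    matched = tuple(
        r for r in table
        if all(str(r.metadata().get(f, "")) == str(v) for f, v in constraints.items())
    )
    return StudyTable(records=matched, source=table.source)


def load_example_table() -> StudyTable:
    """The bundled example table: 21 case-control studies over five SNPs.

    Genotype counts transcribed from the summary table of a published
    meta-analysis of MDM4 polymorphisms and cancer risk (rs4245739,
    rs1563828, rs11801299, rs10900598, rs1380576). The three Wang2012 rows
    print partial genotype data only and load as incomplete records.
    """
    with resources.as_file(resources.files("snpmeta").joinpath("data/table1.csv")) as p:
        table = read_study_table(p)
    return replace(table, source="bundled:table1.csv")
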