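"""Reading, validating and writing per-study count tables.

A study contributes either genotype counts (GG/GT/TT per arm) or allele
counts (G/T per arm) for cases and controls, plus metadata (label, year,
country, ethnicity subgroup).  Genotype resolution supports all five
genetic contrasts; allele resolution supports only the per-allele one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "AlleleCounts",
    "StudyRecord",
    "StudyTable",
    "SchemaError",
    "ValidationError",
    "read_study_table",
    "write_study_table",
    "genotype_to_allele",
    "write_results_table",
    "write_results_json",
    "results_to_dataframe",
]

GENOTYPE_COLUMNS = ["case_GG", "case_GT", "case_TT", "ctrl_GG", "ctrl_GT", "ctrl_TT"]
ALLELE_COLUMNS = ["case_G", "case_T", "ctrl_G", "ctrl_T"]
META_COLUMNS = ["study_id", "year", "country", "subgroup"]


class SchemaError(ValueError):
    """The input table's header does not match a supported schema."""


class ValidationError(ValueError):
    """A value in the input table violates a count invariant."""


def _check_count(value, *, where: str) -> int:
    """Counts are strict non-negative integers; fractional input is rejected."""
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{where}: non-numeric count {value!r}") from None
    if f != int(f):
        raise ValidationError(f"{where}: non-integer count {value!r}")
    n = int(f)
    if n < 0:
        raise ValidationError(f"{where}: negative count {n}")
    return n


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm of a biallelic SNP (G/T coded)."""

    n_gg: int
    n_gt: int
    n_tt: int

    def __post_init__(self) -> None:
        for name in ("n_gg", "n_gt", "n_tt"):
            object.__setattr__(self, name, _check_count(getattr(self, name), where=name))

    @property
    def total(self) -> int:
        return self.n_gg + self.n_gt + self.n_tt


@dataclass(frozen=True)
class AlleleCounts:
    """Allele counts for one arm: each subject contributes two alleles."""

    n_g: int
    n_t: int

    def __post_init__(self) -> None:
        for name in ("n_g", "n_t"):
            object.__setattr__(self, name, _check_count(getattr(self, name), where=name))

    @property
    def total(self) -> int:
        return self.n_g + self.n_t


def genotype_to_allele(counts: GenotypeCounts) -> AlleleCounts:
    """Collapse genotype counts to allele counts.

    Each GG subject carries two G alleles, each heterozygote one of each,
    so ``n_G = 2*n_GG + n_GT`` and ``n_T = 2*n_TT + n_GT``; the allele
    total is exactly twice the number of subjects.
    """
    return AlleleCounts(
        n_g=2 * counts.n_gg + counts.n_gt,
        n_t=2 * counts.n_tt + counts.n_gt,
    )


Counts = Union[GenotypeCounts, AlleleCounts]


@dataclass
class StudyRecord:
    """One study's case and control counts plus metadata."""

    study_id: str
    year: int
    country: str
    subgroup: str
    case_counts: Counts
    control_counts: Counts
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if type(self.case_counts) is not type(self.control_counts):
            raise ValidationError(
                f"{self.study_id}: case and control counts must share one "
                "resolution (both genotype or both allele)"
            )

    @property
    def resolution(self) -> Literal["genotype", "allele"]:
        return "genotype" if isinstance(self.case_counts, GenotypeCounts) else "allele"

    def case_alleles(self) -> AlleleCounts:
        c = self.case_counts
        return genotype_to_allele(c) if isinstance(c, GenotypeCounts) else c

    def control_alleles(self) -> AlleleCounts:
        c = self.control_counts
        return genotype_to_allele(c) if isinstance(c, GenotypeCounts) else c


@dataclass
class StudyTable:
    """Ordered collection of study records for one SNP."""

    records: list[StudyRecord]
    snp_label: str = ""

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate study_id values: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def study_ids(self) -> list[str]:
        return [r.study_id for r in self.records]

    def subgroups(self) -> list[str]:
        """Distinct subgroup labels in order of first appearance."""
        seen: list[str] = []
        for r in self.records:
            if r.subgroup not in seen:
                seen.append(r.subgroup)
        return seen

    def subset(self, study_ids: Sequence[str]) -> "StudyTable":
        keep = set(study_ids)
        return StudyTable(
            [r for r in self.records if r.study_id in keep], self.snp_label
        )

    def by_subgroup(self, label: str) -> "StudyTable":
        return StudyTable(
            [r for r in self.records if r.subgroup == label], self.snp_label
        )


def _infer_schema(columns: Iterable[str]) -> str:
    cols = set(columns)
    if cols.issuperset(GENOTYPE_COLUMNS):
        return "genotype"
    if cols.issuperset(ALLELE_COLUMNS):
        return "allele"
    missing_g = [c for c in GENOTYPE_COLUMNS if c not in cols]
    missing_a = [c for c in ALLELE_COLUMNS if c not in cols]
    missing = missing_a if len(missing_a) < len(missing_g) else missing_g
    raise SchemaError(
        f"header matches neither genotype nor allele schema; missing column(s) "
        f"{missing} (got {sorted(cols)})"
    )


def read_study_table(
    path: Union[str, Path],
    format_hint: Literal["genotype", "allele", None] = None,
    snp_label: str = "",
) -> StudyTable:
    """Read a delimited (tab or comma) per-study count table.

    The resolution is inferred from which count columns are present
    (``case_GG``.. for genotype, ``case_G``.. for allele) unless
    ``format_hint`` forces it.  Metadata columns are preserved verbatim;
    optional ``n_case``/``n_control`` columns are cross-checked against the
    counts and mismatches raise a warning, not an error, since published
    tables occasionally disagree with their own totals.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise SchemaError(f"missing required metadata column(s): {missing_meta}")
    schema = format_hint or _infer_schema(df.columns)
    if format_hint is not None:
        needed = GENOTYPE_COLUMNS if format_hint == "genotype" else ALLELE_COLUMNS
        absent = [c for c in needed if c not in df.columns]
        if absent:
            raise SchemaError(f"format_hint={format_hint!r} but missing column(s): {absent}")

    records: list[StudyRecord] = []
    for idx, row in df.iterrows():
        sid = str(row["study_id"]).strip()
        where = f"row {idx} ({sid})"
        if schema == "genotype":
            case = GenotypeCounts(
                *(_check_count(row[c], where=f"{where} {c}") for c in GENOTYPE_COLUMNS[:3])
            )
            ctrl = GenotypeCounts(
                *(_check_count(row[c], where=f"{where} {c}") for c in GENOTYPE_COLUMNS[3:])
            )
        else:
            case = AlleleCounts(
                *(_check_count(row[c], where=f"{where} {c}") for c in ALLELE_COLUMNS[:2])
            )
            ctrl = AlleleCounts(
                *(_check_count(row[c], where=f"{where} {c}") for c in ALLELE_COLUMNS[2:])
            )
        try:
            year = int(float(row["year"]))
        except (TypeError, ValueError):
            raise ValidationError(f"{where}: non-integer year {row['year']!r}") from None
        rec = StudyRecord(
            study_id=sid,
            year=year,
            country=str(row["country"]).strip(),
            subgroup=str(row["subgroup"]).strip(),
            case_counts=case,
            control_counts=ctrl,
        )
        for arm, counts, ncol in (("case", case, "n_case"), ("control", ctrl, "n_control")):
            if ncol in df.columns and str(row[ncol]).strip() not in ("", "nan"):
                stated = _check_count(row[ncol], where=f"{where} {ncol}")
                subjects = counts.total if schema == "genotype" else counts.total // 2
                if subjects != stated:
                    warnings.warn(
                        f"{where}: {arm} counts imply {subjects} subjects but "
                        f"{ncol}={stated}",
                        stacklevel=2,
                    )
        records.append(rec)
    return StudyTable(records, snp_label=snp_label)


def write_study_table(table: StudyTable, path: Union[str, Path], sep: str = "\t") -> None:
    """Write a study table back out in the matching schema (tab by default)."""
    rows = []
    for r in table:
        row: dict = {
            "study_id": r.study_id,
            "year": r.year,
            "country": r.country,
            "subgroup": r.subgroup,
        }
        if r.resolution == "genotype":
            cc, tc = r.case_counts, r.control_counts
            row.update(
                case_GG=cc.n_gg, case_GT=cc.n_gt, case_TT=cc.n_tt,
                ctrl_GG=tc.n_gg, ctrl_GT=tc.n_gt, ctrl_TT=tc.n_tt,
            )
        else:
            cc, tc = r.case_counts, r.control_counts
            row.update(case_G=cc.n_g, case_T=cc.n_t, ctrl_G=tc.n_g, ctrl_T=tc.n_t)
        rows.append(row)
    cols = META_COLUMNS + (
        GENOTYPE_COLUMNS if table.records and table.records[0].resolution == "genotype"
        else ALLELE_COLUMNS
    )
    pd.DataFrame(rows, columns=cols if rows else None).to_csv(path, sep=sep, index=False)


def _pooled_row(res) -> dict:
    est = res.estimate
    het = res.heterogeneity
    return {
        "subgroup": res.subgroup,
        "contrast": res.contrast,
        "OR": round(est.or_value, 3),
        "ci_low": round(est.ci_low, 3),
        "ci_high": round(est.ci_high, 3),
        "i_squared_pct": round(het.i_squared, 2),
        "het_p": round(het.p_value, 3),
        "model": res.model_used,
        "n_studies": res.k,
    }


def results_to_dataframe(results: Iterable) -> pd.DataFrame:
    """Tabulate pooled results, one row per (subgroup, contrast)."""
    rows = sorted((_pooled_row(r) for r in results), key=lambda d: (d["subgroup"], d["contrast"]))
    cols = ["subgroup", "contrast", "OR", "ci_low", "ci_high",
            "i_squared_pct", "het_p", "model", "n_studies"]
    return pd.DataFrame(rows, columns=cols)


def write_results_table(results: Iterable, path: Union[str, Path], sep: str = "\t") -> None:
    """Write pooled results as delimited text, numbers to 3 decimals,
    ordered by (subgroup, contrast)."""
    df = results_to_dataframe(results)
    df.to_csv(path, sep=sep, index=False, float_format="%.3f")


def write_results_json(results: Iterable, path: Union[str, Path]) -> None:
    df = results_to_dataframe(results)
    Path(path).write_text(json.dumps(df.to_dict(orient="records"), indent=1))
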