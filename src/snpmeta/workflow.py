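"""Full analysis orchestration: subgroup grids, HWE-filtered re-analysis,
sensitivity, publication bias, and invasiveness-stratified runs.

``run_full_analysis`` computes, for every subgroup label plus the pooled
"All" stratum and every requested contrast, a pooled odds ratio before and
after Hardy-Weinberg filtering of controls, then leave-one-out sensitivity
rows and Egger's test per contrast.  Cells a table cannot support (a
genotype contrast on allele-resolution records) are reported as
not-computable and the run continues.

``run_stratified_analysis`` reuses the identical machinery on case-case
tables, where the "case" arm holds the aggressive stratum (e.g. Gleason
score >= 7, PSA > 10 ng/mL, or metastatic / clinical stage >= T3 disease)
and the "control" arm the non-aggressive one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .contrasts import (
    CONTRASTS,
    UnsupportedContrastError,
    apply_hwe_filter,
    table_effects,
)
from .inference_extras import EggerResult, SensitivityRow, egger_test, leave_one_out
from .meta_engine import PooledResult, pool
from .study_io import StudyTable, results_to_dataframe

__all__ = [
    "AnalysisConfig",
    "StratifiedSpec",
    "CellResult",
    "ResultSet",
    "run_full_analysis",
    "run_stratified_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full pipeline, all with the conventional defaults."""

    contrasts: tuple[str, ...] = CONTRASTS
    subgroup_column: str = "subgroup"
    hwe_alpha: float = 0.05
    i2_threshold: float = 50.0
    het_p_alpha: float = 0.10
    zero_cell_policy: str = "haldane"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [c for c in self.contrasts if c not in CONTRASTS]
        if unknown:
            raise ValueError(f"unknown contrast(s) {unknown}")
        for name, lo, hi in (
            ("hwe_alpha", 0.0, 1.0),
            ("het_p_alpha", 0.0, 1.0),
            ("i2_threshold", 0.0, 100.0),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")


_STRATA_RULES = {
    "GS": ("GS>=7", "GS<7"),
    "PSA": ("PSA>10 ng/mL", "PSA<=10 ng/mL"),
    "clinical_status": ("metastasis(+) or stage>=T3", "localized, stage<T3"),
}


@dataclass(frozen=True)
class StratifiedSpec:
    """Which invasiveness index stratifies cases, and how it dichotomizes."""

    index: str  # "GS" | "PSA" | "clinical_status"
    case_rule: str = ""
    control_rule: str = ""

    def __post_init__(self) -> None:
        if self.index not in _STRATA_RULES:
            raise ValueError(f"index must be one of {sorted(_STRATA_RULES)}")
        default_case, default_ctrl = _STRATA_RULES[self.index]
        if not self.case_rule:
            object.__setattr__(self, "case_rule", default_case)
        if not self.control_rule:
            object.__setattr__(self, "control_rule", default_ctrl)


@dataclass
class CellResult:
    """One (filter state, subgroup, contrast) cell of the analysis grid."""

    filter_state: str  # "unfiltered" | "hwe_filtered"
    subgroup: str
    contrast: str
    pooled: PooledResult | None
    note: str = ""


@dataclass
class ResultSet:
    """Everything a full run produces, with provenance."""

    cells: list[CellResult]
    hwe_excluded: list[tuple[str, float]]
    sensitivity: dict[str, list[SensitivityRow]]
    egger: dict[str, EggerResult | None]
    config: AnalysisConfig
    label: str = ""
    study_ids: list[str] = field(default_factory=list)

    def pooled_results(self, filter_state: str = "unfiltered") -> list[PooledResult]:
        return [
            c.pooled for c in self.cells if c.filter_state == filter_state and c.pooled
        ]

    def get(self, subgroup: str, contrast: str, filter_state: str = "unfiltered") -> CellResult:
        for c in self.cells:
            if (c.subgroup, c.contrast, c.filter_state) == (subgroup, contrast, filter_state):
                return c
        raise KeyError((subgroup, contrast, filter_state))

    def to_dataframe(self, filter_state: str = "unfiltered") -> pd.DataFrame:
        return results_to_dataframe(self.pooled_results(filter_state))


def _grid(
    table: StudyTable, config: AnalysisConfig, filter_state: str
) -> list[CellResult]:
    cells: list[CellResult] = []
    strata = [("All", table)] + [(g, table.by_subgroup(g)) for g in table.subgroups()]
    for subgroup, sub in strata:
        for contrast in config.contrasts:
            if len(sub) == 0:
                cells.append(CellResult(filter_state, subgroup, contrast, None, "no studies"))
                continue
            try:
                ids, effects = table_effects(sub, contrast, config.zero_cell_policy)
            except UnsupportedContrastError as exc:
                logger.info("cell %s/%s not computable: %s", subgroup, contrast, exc)
                cells.append(CellResult(filter_state, subgroup, contrast, None, str(exc)))
                continue
            res = pool(
                effects, ids,
                i2_threshold=config.i2_threshold,
                contrast=contrast, subgroup=subgroup,
            )
            cells.append(CellResult(filter_state, subgroup, contrast, res))
    return cells


def run_full_analysis(
    table: StudyTable, config: AnalysisConfig | None = None
) -> ResultSet:
    """Subgroup x contrast pooling grid, HWE-filtered re-analysis,
    leave-one-out sensitivity, and Egger's test per contrast."""
    config = config or AnalysisConfig()
    cells = _grid(table, config, "unfiltered")
    filtered, excluded = apply_hwe_filter(table, alpha=config.hwe_alpha)
    cells += _grid(filtered, config, "hwe_filtered")

    sensitivity: dict[str, list[SensitivityRow]] = {}
    egger: dict[str, EggerResult | None] = {}
    for contrast in config.contrasts:
        try:
            if len(table) >= 2:
                sensitivity[contrast] = leave_one_out(
                    table, contrast, config.i2_threshold, config.zero_cell_policy
                )
        except UnsupportedContrastError:
            pass
        try:
            _, effects = table_effects(table, contrast, config.zero_cell_policy)
            egger[contrast] = egger_test(effects) if len(effects) >= 3 else None
        except UnsupportedContrastError:
            egger[contrast] = None
    return ResultSet(
        cells=cells,
        hwe_excluded=excluded,
        sensitivity=sensitivity,
        egger=egger,
        config=config,
        study_ids=table.study_ids,
    )


def run_stratified_analysis(
    table: StudyTable, spec: StratifiedSpec, config: AnalysisConfig | None = None
) -> ResultSet:
    """Invasiveness-stratified (case-case) analysis.

    ``table`` must hold case-case counts: the "case" arm is the aggressive
    stratum per ``spec.case_rule`` and the "control" arm the non-aggressive
    one.  Pooling is identical to the case-control grid; results are
    labeled by the stratifying index.
    """
    config = config or AnalysisConfig()
    logger.info(
        "stratified analysis by %s: %s vs %s", spec.index, spec.case_rule, spec.control_rule
    )
    rs = run_full_analysis(table, config)
    rs.label = spec.index
    return rs
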