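"""Genetic contrasts, per-study odds ratios, and Hardy-Weinberg testing.

Five contrasts of a biallelic SNP (G risk allele vs T) are supported:

====================  ===========================================
dominant              GG + GT vs TT
recessive             GG vs GT + TT
codominant_GG_vs_GT   GG vs GT (TT subjects excluded)
codominant_GG_vs_TT   GG vs TT (GT subjects excluded)
per_allele            G vs T, counting each of the 2N alleles
====================  ===========================================

All but ``per_allele`` need genotype-resolution counts; the per-allele
contrast accepts either resolution (genotypes are collapsed to alleles).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Union

from scipy import stats

from .study_io import (
    AlleleCounts,
    GenotypeCounts,
    StudyRecord,
    StudyTable,
    genotype_to_allele,
)

__all__ = [
    "CONTRASTS",
    "FourfoldTable",
    "EffectEstimate",
    "HWEResult",
    "UnsupportedContrastError",
    "DegenerateTableError",
    "build_contrast_table",
    "estimate_odds_ratio",
    "study_effect",
    "table_effects",
    "hwe_chi_square",
    "hwe_exact_midp",
    "apply_hwe_filter",
]

logger = logging.getLogger(__name__)

CONTRASTS = (
    "dominant",
    "recessive",
    "codominant_GG_vs_GT",
    "codominant_GG_vs_TT",
    "per_allele",
)

Z975 = stats.norm.ppf(0.975)  # exact 97.5% normal point, not a hard-coded 1.96


class UnsupportedContrastError(ValueError):
    """The record's count resolution cannot support the requested contrast."""


class DegenerateTableError(ValueError):
    """Both diagonals of the 2x2 table are zero; no odds ratio exists."""


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 case/control table for one contrast.

    ``a``/``b`` are case exposed/unexposed, ``c``/``d`` control
    exposed/unexposed; ``corrected`` records whether a 0.5 continuity
    correction has been added to every cell.
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("fourfold table entries must be non-negative")

    def with_continuity_correction(self) -> "FourfoldTable":
        return FourfoldTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5, True)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with its large-sample standard error."""

    log_or: float
    se_log_or: float

    @property
    def or_value(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z975 * self.se_log_or)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z975 * self.se_log_or)


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square goodness-of-fit to Hardy-Weinberg proportions."""

    chi_square: float
    p_value: float
    passes: bool
    alpha: float = 0.05
    monomorphic: bool = False
    df: int = 1


def build_contrast_table(study: StudyRecord, contrast: str) -> FourfoldTable:
    """Build the 2x2 table for one study under one genetic contrast."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    if contrast == "per_allele":
        case, ctrl = study.case_alleles(), study.control_alleles()
        return FourfoldTable(case.n_g, case.n_t, ctrl.n_g, ctrl.n_t)
    if study.resolution != "genotype":
        raise UnsupportedContrastError(
            f"{study.study_id}: contrast {contrast!r} needs genotype counts but "
            "the record is allele-resolution"
        )
    cc: GenotypeCounts = study.case_counts
    tc: GenotypeCounts = study.control_counts
    if contrast == "dominant":
        return FourfoldTable(cc.n_gg + cc.n_gt, cc.n_tt, tc.n_gg + tc.n_gt, tc.n_tt)
    if contrast == "recessive":
        return FourfoldTable(cc.n_gg, cc.n_gt + cc.n_tt, tc.n_gg, tc.n_gt + tc.n_tt)
    if contrast == "codominant_GG_vs_GT":
        return FourfoldTable(cc.n_gg, cc.n_gt, tc.n_gg, tc.n_gt)
    return FourfoldTable(cc.n_gg, cc.n_tt, tc.n_gg, tc.n_tt)


def estimate_odds_ratio(
    table: FourfoldTable, zero_cell_policy: str = "haldane"
) -> EffectEstimate:
    """Odds ratio and Woolf standard error from a 2x2 table.

    OR = ad/bc; SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d).  Under the
    default ``haldane`` policy 0.5 is added to every cell if (and only if)
    any cell is zero, so sparse studies are retained rather than dropped;
    ``none`` disables the correction and degenerate tables raise.
    """
    if zero_cell_policy not in ("haldane", "none"):
        raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    cells = (table.a, table.b, table.c, table.d)
    if all(x == 0 for x in cells):
        raise DegenerateTableError("all four cells are zero")
    if zero_cell_policy == "haldane" and any(x == 0 for x in cells) and not table.corrected:
        logger.info("continuity correction (+0.5 per cell) applied to table %s", cells)
        table = table.with_continuity_correction()
    a, b, c, d = table.a, table.b, table.c, table.d
    if a * d == 0 and b * c == 0:
        raise DegenerateTableError(f"no odds ratio defined for cells {cells}")
    if a * d == 0 or b * c == 0 or min(a, b, c, d) == 0:
        raise DegenerateTableError(
            f"zero cell leaves the log odds ratio undefined for cells {cells}"
        )
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(log_or=log_or, se_log_or=se)


def study_effect(
    study: StudyRecord, contrast: str, zero_cell_policy: str = "haldane"
) -> EffectEstimate:
    """Convenience: contrast table then odds ratio for one study."""
    return estimate_odds_ratio(build_contrast_table(study, contrast), zero_cell_policy)


def table_effects(
    table: StudyTable, contrast: str, zero_cell_policy: str = "haldane"
) -> tuple[list[str], list[EffectEstimate]]:
    """Per-study effects for every record, preserving input order.

    Raises :class:`UnsupportedContrastError` if any record lacks the
    resolution the contrast needs; callers that want partial grids catch it.
    """
    ids: list[str] = []
    effects: list[EffectEstimate] = []
    for rec in table:
        effects.append(study_effect(rec, contrast, zero_cell_policy))
        ids.append(rec.study_id)
    return ids, effects


def hwe_chi_square(controls: GenotypeCounts, alpha: float = 0.05) -> HWEResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts come from the estimated G-allele frequency
    p = (2*GG + GT) / 2N: N*(p^2, 2pq, q^2).  No Yates correction.
    Monomorphic samples fit HW exactly and are flagged rather than refused.
    """
    n = controls.total
    if n <= 0:
        raise ValueError("control total must be positive")
    alleles = genotype_to_allele(controls)
    if alleles.n_g == 0 or alleles.n_t == 0:
        return HWEResult(0.0, 1.0, passes=True, alpha=alpha, monomorphic=True)
    p = alleles.n_g / (2 * n)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (controls.n_gg, controls.n_gt, controls.n_tt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(chi2, p_value, passes=p_value >= alpha, alpha=alpha)


def hwe_exact_midp(controls: GenotypeCounts, alpha: float = 0.05) -> HWEResult:
    """Exact conditional HWE test (mid-P variant), as an alternative to the
    chi-square form for small samples.

    Conditions on the observed allele counts; the null distribution over
    the number of heterozygotes is the standard exact HW distribution.
    The mid-P value sums probabilities of outcomes less likely than the
    observed heterozygote count plus half the observed one's probability.
    """
    n = controls.total
    if n <= 0:
        raise ValueError("control total must be positive")
    alleles = genotype_to_allele(controls)
    n_g, n_t = alleles.n_g, alleles.n_t
    if n_g == 0 or n_t == 0:
        return HWEResult(0.0, 1.0, passes=True, alpha=alpha, monomorphic=True, df=0)
    rare = min(n_g, n_t)
    obs_het = controls.n_gt
    # log P(het = h | allele counts) up to a shared constant
    hets = range(rare % 2, rare + 1, 2)
    logp = {}
    for h in hets:
        n_hom_rare = (rare - h) // 2
        n_hom_common = (max(n_g, n_t) - h) // 2
        logp[h] = (
            h * math.log(2)
            - math.lgamma(n_hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_hom_common + 1)
        )
    m = max(logp.values())
    probs = {h: math.exp(v - m) for h, v in logp.items()}
    z = sum(probs.values())
    probs = {h: v / z for h, v in probs.items()}
    p_obs = probs[obs_het]
    p_value = sum(v for v in probs.values() if v < p_obs) + 0.5 * p_obs + 0.5 * sum(
        v for h, v in probs.items() if v == p_obs and h != obs_het
    )
    p_value = min(1.0, p_value)
    return HWEResult(float("nan"), p_value, passes=p_value >= alpha, alpha=alpha, df=0)


def apply_hwe_filter(
    table: StudyTable, alpha: float = 0.05, method: str = "chisq"
) -> tuple[StudyTable, list[tuple[str, float]]]:
    """Drop studies whose control genotypes deviate from HW at ``alpha``.

    Returns the filtered table and the excluded ``(study_id, p_value)``
    pairs.  Allele-resolution records carry no genotype information, are
    not testable, and pass through (logged as such).
    """
    test = hwe_chi_square if method == "chisq" else hwe_exact_midp
    kept: list[StudyRecord] = []
    excluded: list[tuple[str, float]] = []
    for rec in table:
        if rec.resolution != "genotype":
            logger.info("HWE not testable for allele-resolution study %s", rec.study_id)
            kept.append(rec)
            continue
        res = test(rec.control_counts, alpha=alpha)
        if res.passes:
            kept.append(rec)
        else:
            logger.info(
                "HWE filter excluded study %s (P=%.4g < %.3g)",
                rec.study_id, res.p_value, alpha,
            )
            excluded.append((rec.study_id, res.p_value))
    return StudyTable(kept, table.snp_label), excluded
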