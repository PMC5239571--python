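import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snpmeta import (
    AlleleCounts,
    FourfoldTable,
    GenotypeCounts,
    StudyRecord,
    StudyTable,
    apply_hwe_filter,
    build_contrast_table,
    estimate_odds_ratio,
    hwe_chi_square,
    hwe_exact_midp,
    simulate_table,
    SimulationDesign,
)
from snpmeta.contrasts import DegenerateTableError, UnsupportedContrastError

from conftest import make_genotype_record


def cells(t: FourfoldTable):
    return (t.a, t.b, t.c, t.d)


class TestBuildContrastTable:
    def test_per_allele_from_allele_record(self):
        rec = StudyRecord(
            "Pournourali", 2015, "Iran", "Asian",
            AlleleCounts(110, 90), AlleleCounts(90, 110),
        )
        assert cells(build_contrast_table(rec, "per_allele")) == (110, 90, 90, 110)

    @pytest.mark.parametrize(
        "contrast, expected",
        [
            ("dominant", (30, 30, 30, 30)),
            ("recessive", (10, 50, 10, 50)),
            ("codominant_GG_vs_GT", (10, 20, 10, 20)),
            ("codominant_GG_vs_TT", (10, 30, 10, 30)),
            ("per_allele", (40, 80, 40, 80)),
        ],
    )
    def test_genotype_contrasts(self, contrast, expected):
        rec = make_genotype_record("s", case=(10, 20, 30), control=(10, 20, 30))
        assert cells(build_contrast_table(rec, contrast)) == expected

    def test_monomorphic_dominant(self):
        rec = make_genotype_record("s", case=(0, 0, 50), control=(0, 0, 50))
        assert cells(build_contrast_table(rec, "dominant")) == (0, 50, 0, 50)

    def test_allele_record_refuses_genotype_contrast(self):
        rec = StudyRecord("s", 2020, "X", "All", AlleleCounts(5, 5), AlleleCounts(5, 5))
        with pytest.raises(UnsupportedContrastError, match="genotype"):
            build_contrast_table(rec, "dominant")

    def test_subject_conservation_dominant_recessive(self):
        rec = make_genotype_record("s", case=(12, 34, 56), control=(7, 8, 9))
        for contrast in ("dominant", "recessive"):
            t = build_contrast_table(rec, contrast)
            assert t.a + t.b == 102 and t.c + t.d == 24


class TestEstimateOddsRatio:
    def test_published_counts(self):
        est = estimate_odds_ratio(FourfoldTable(110, 90, 90, 110))
        assert est.or_value == pytest.approx(1.4938, abs=1e-3)
        assert est.log_or == pytest.approx(0.4013, abs=1e-3)
        assert est.se_log_or == pytest.approx(0.2010, abs=1e-3)
        assert est.ci_low < est.or_value < est.ci_high

    def test_symmetric_table(self):
        est = estimate_odds_ratio(FourfoldTable(10, 10, 10, 10))
        assert est.log_or == 0.0
        assert est.se_log_or == pytest.approx(math.sqrt(0.4), abs=1e-10)

    def test_zero_cell_haldane(self):
        est = estimate_odds_ratio(FourfoldTable(5, 0, 3, 7))
        assert est.or_value == pytest.approx((5.5 * 7.5) / (0.5 * 3.5), rel=1e-12)

    def test_zero_cell_policy_none_raises(self):
        with pytest.raises(DegenerateTableError):
            estimate_odds_ratio(FourfoldTable(5, 0, 3, 7), zero_cell_policy="none")

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateTableError):
            estimate_odds_ratio(FourfoldTable(0, 0, 0, 0))

    def test_ci_matches_normal_quantile(self):
        est = estimate_odds_ratio(FourfoldTable(20, 30, 25, 25))
        z = stats.norm.ppf(0.975)
        assert est.ci_low == pytest.approx(math.exp(est.log_or - z * est.se_log_or))
        assert est.ci_high == pytest.approx(math.exp(est.log_or + z * est.se_log_or))

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    @settings(derandomize=True, max_examples=100)
    def test_case_control_swap_inverts_or(self, a, b, c, d):
        """Swapping arms (a<->c, b<->d) inverts the OR; SE is unchanged."""
        fwd = estimate_odds_ratio(FourfoldTable(a, b, c, d))
        rev = estimate_odds_ratio(FourfoldTable(c, d, a, b))
        assert rev.log_or == pytest.approx(-fwd.log_or, abs=1e-12)
        assert rev.se_log_or == pytest.approx(fwd.se_log_or, abs=1e-12)


class TestHWE:
    def test_exact_proportions(self):
        res = hwe_chi_square(GenotypeCounts(25, 50, 25))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.passes

    def test_heterozygote_deficit(self):
        # p=0.5: expected 25/50/25 of 100, chi2 = 25/25 + 100/50 + 25/25 = 4
        res = hwe_chi_square(GenotypeCounts(30, 40, 30))
        assert res.chi_square == pytest.approx(4.0, abs=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-12)
        assert res.p_value == pytest.approx(0.0455, abs=2e-4)
        assert not res.passes

    def test_monomorphic_flagged_not_error(self):
        res = hwe_chi_square(GenotypeCounts(0, 0, 100))
        assert res.monomorphic and res.passes and res.p_value == 1.0

    @given(
        gg=st.integers(0, 200), gt=st.integers(0, 200), tt=st.integers(0, 200)
    )
    @settings(derandomize=True, max_examples=100)
    def test_p_is_chi2_survival(self, gg, gt, tt):
        if gg + gt + tt == 0:
            return
        res = hwe_chi_square(GenotypeCounts(gg, gt, tt))
        if not res.monomorphic:
            assert res.p_value == pytest.approx(stats.chi2.sf(res.chi_square, 1), rel=1e-9)

    @pytest.mark.parametrize(
        "counts", [(12, 19, 9), (5, 5, 30), (2, 18, 20), (25, 50, 25)]
    )
    def test_exact_midp_matches_enumeration_oracle(self, counts):
        """The exact mid-P equals a direct rational enumeration of the
        conditional heterozygote-count distribution."""
        from fractions import Fraction
        from math import factorial

        gg, gt, tt = counts
        n = gg + gt + tt
        n_g, n_t = 2 * gg + gt, 2 * tt + gt
        rare = min(n_g, n_t)
        probs = {}
        for h in range(rare % 2, rare + 1, 2):
            hom_rare = (rare - h) // 2
            hom_common = (max(n_g, n_t) - h) // 2
            probs[h] = Fraction(
                factorial(n) * 2**h,
                factorial(hom_rare) * factorial(h) * factorial(hom_common),
            )
        total = sum(probs.values())
        probs = {h: p / total for h, p in probs.items()}
        p_obs = probs[gt]
        expected = float(
            sum(p for p in probs.values() if p < p_obs)
            + Fraction(1, 2) * sum(p for p in probs.values() if p == p_obs)
        )
        res = hwe_exact_midp(GenotypeCounts(gg, gt, tt))
        assert res.p_value == pytest.approx(min(1.0, expected), abs=1e-9)


class TestApplyHweFilter:
    def test_filters_deviating_study(self):
        good = make_genotype_record("good", control=(25, 50, 25))
        bad = make_genotype_record("bad", control=(30, 40, 30))  # P~0.046
        table = StudyTable([good, bad])
        kept, excluded = apply_hwe_filter(table, alpha=0.05)
        assert kept.study_ids == ["good"]
        assert excluded[0][0] == "bad" and excluded[0][1] < 0.05

    def test_all_in_hwe_nothing_excluded(self):
        table = StudyTable([make_genotype_record(f"s{i}") for i in range(3)])
        kept, excluded = apply_hwe_filter(table)
        assert len(kept) == 3 and excluded == []

    def test_allele_records_pass_through(self):
        rec = StudyRecord("a", 2020, "X", "All", AlleleCounts(5, 5), AlleleCounts(5, 5))
        kept, excluded = apply_hwe_filter(StudyTable([rec]))
        assert kept.study_ids == ["a"] and excluded == []

    def test_inbreeding_perturbed_study_is_caught(self):
        """F=0.3 at n=500 controls deviates detectably from HW proportions."""
        design = SimulationDesign(
            n_studies=4, n_controls=500, inbreeding_f=0.3, f_studies=(2,), seed=7
        )
        table = simulate_table(design)
        _, excluded = apply_hwe_filter(table, alpha=0.05)
        assert "sim_002" in [sid for sid, _ in excluded]
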