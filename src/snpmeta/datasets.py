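"""Bundled example data: published APEX1 rs1130409 prostate-cancer studies.

Allele counts (G/T per arm) for the seven case-control studies of the
Asp148Glu (rs1130409) polymorphism and prostate cancer risk, as printed in
the source studies' reports, with ethnicity subgroup labels (Asian, Mix,
African descent).  Allele resolution supports the per-allele (G vs T)
contrast; the genotype-model contrasts need per-genotype counts that the
combined table does not provide.
"""

from __future__ import annotations

from .study_io import AlleleCounts, StudyRecord, StudyTable

# study_id, year, country, subgroup, case (G, T), control (G, T)
_APEX1_PCA_ALLELES = [
    ("Pournourali", 2015, "Iran", "Asian", (110, 90), (90, 110)),
    ("Jing", 2013, "China", "Asian", (166, 230), (119, 193)),
    ("Mandal", 2012, "India", "Asian", (101, 283), (118, 330)),
    ("Mittal", 2012, "India", "Asian", (102, 288), (127, 373)),
    ("Kuasne", 2011, "Brazil", "Mix", (93, 251), (68, 276)),
    ("Lavender", 2010, "America", "African", (120, 252), (445, 817)),
    ("Chen", 2006, "America", "Mix", (302, 400), (261, 397)),
]


def load_apex1_prostate() -> StudyTable:
    """Seven-study allele-count table for APEX1 rs1130409 vs prostate cancer."""
    records = [
        StudyRecord(
            study_id=sid,
            year=year,
            country=country,
            subgroup=subgroup,
            case_counts=AlleleCounts(*case),
            control_counts=AlleleCounts(*ctrl),
        )
        for sid, year, country, subgroup, case, ctrl in _APEX1_PCA_ALLELES
    ]
    return StudyTable(records, snp_label="rs1130409")
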