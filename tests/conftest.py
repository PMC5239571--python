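import pytest

from snpmeta import (
    AnalysisConfig,
    GenotypeCounts,
    StudyRecord,
    StudyTable,
    load_apex1_prostate,
)


@pytest.fixture(scope="session")
def apex_table() -> StudyTable:
    """Seven-study published allele-count table (bundled dataset)."""
    return load_apex1_prostate()


def make_genotype_record(
    study_id: str,
    case=(25, 50, 25),
    control=(25, 50, 25),
    subgroup: str = "All",
    year: int = 2015,
) -> StudyRecord:
    return StudyRecord(
        study_id=study_id,
        year=year,
        country="testland",
        subgroup=subgroup,
        case_counts=GenotypeCounts(*case),
        control_counts=GenotypeCounts(*control),
    )


@pytest.fixture
def genotype_table() -> StudyTable:
    """Three genotype-resolution studies with distinct case splits."""
    return StudyTable(
        [
            make_genotype_record("s1", case=(30, 50, 20), control=(25, 50, 25)),
            make_genotype_record("s2", case=(28, 52, 20), control=(24, 50, 26)),
            make_genotype_record("s3", case=(35, 45, 20), control=(26, 49, 25)),
        ],
        snp_label="synthetic",
    )


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig()
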