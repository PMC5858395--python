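from hypothesis import HealthCheck, settings
import pytest

from hdpmeta.types import GenotypeCounts, StudyRecord, EthnicGroup, HdpSubtype, Locus

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_study(
    study_id="S1",
    cases=(30, 40, 30),
    controls=(40, 40, 20),
    country="Testland",
    ethnic_group=EthnicGroup.CAUCASIAN,
    hdp_subtype=HdpSubtype.PE_E,
    locus=Locus.C677T,
    level=2,
    quality=20,
    year=2015,
) -> StudyRecord:
    return StudyRecord(
        study_id=study_id,
        country=country,
        ethnic_group=ethnic_group,
        hdp_subtype=hdp_subtype,
        locus=locus,
        cases=GenotypeCounts.of(*cases),
        controls=GenotypeCounts.of(*controls),
        air_pollution_level=level,
        quality_score=quality,
        year=year,
    )


@pytest.fixture
def study_factory():
    return make_study
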