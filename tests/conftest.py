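import pytest
from hypothesis import HealthCheck, settings

from twostage.cohort import ParticipantRecord

settings.register_profile(
    "ci", derandomize=True, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def make_record():
    """Factory for fully resolved participant records with overridable fields."""

    def _make(**kwargs) -> ParticipantRecord:
        defaults = dict(
            id="p1", age_years=55.0,
            retinopathy=False, av_nicking=False, focal_narrowing=False,
            generalized_narrowing=False, hypertension=False, diabetes=False,
            chs_grade=1,
        )
        defaults.update(kwargs)
        return ParticipantRecord(**defaults)

    return _make


@pytest.fixture
def cohort_csv(tmp_path):
    """Write a small cohort CSV and return its path."""

    header = ("id,age_years,retinopathy,av_nicking,focal_narrowing,"
              "generalized_narrowing,hypertension,diabetes,chs_grade,"
              "wmh_volume_cm3,followup_wmh_volume_cm3")

    def _write(rows: list[str], name: str = "cohort.csv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write
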