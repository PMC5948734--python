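"""Shared fixtures: the reconstructed full-sample table and small cohorts."""

import datetime as dt

import pytest
from hypothesis import settings

from hfvalid import ConfusionTable, HFRecord, SurveyRecord, Vocabulary

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_table() -> ConfusionTable:
    """The full-population 2x2 table reconstructed from published marginals."""
    return ConfusionTable(99, 83, 88, 1443)


@pytest.fixture()
def vocab() -> Vocabulary:
    return Vocabulary.from_sets(
        smoker=["CURRENT SMOKER", "TOBACCO USER"],
        quitter=["QUIT IN PAST YEAR", "CURRENT NON-TOBACCO USER"],
        smokeless=["SMOKELESS TOBACCO USER"],
    )


@pytest.fixture()
def mailing_date() -> dt.date:
    return dt.date(2011, 1, 4)


def make_hf(patient: str, date: dt.date, label: str, site: str = "A") -> HFRecord:
    return HFRecord(patient, site, date, label)


@pytest.fixture()
def hf_factory():
    return make_hf


@pytest.fixture()
def survey_factory(mailing_date):
    def make(patient: str, responded: bool = True, items=(False, False, False)):
        if not responded:
            return SurveyRecord(patient, mailing_date, False)
        return SurveyRecord(patient, mailing_date, True, *items)

    return make
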