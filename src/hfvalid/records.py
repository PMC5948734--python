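"""Data model and CSV ingest for the health-factor, survey, and covariate tables.

The analysis joins three per-patient tables:

* an EHR *health factor* (HF) table — one row per structured tobacco-status
  entry made during routine clinical care (who, when, where, what label);
* a follow-up *survey* table — one row per patient, holding the mailing
  date, a response flag, and the three abstinence items that define
  6-month prolonged smoking abstinence;
* an optional *covariate* table with baseline demographics and comorbidity
  flags used for subgroup analyses and the nonresponse model.

All dates are calendar dates handled at day resolution; every temporal
quantity downstream is an integer difference of days.  Files are
comma-separated UTF-8 with a header row; dates default to ISO-8601.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

HF_COLUMNS = ["patient_id", "site_id", "record_date", "label"]
SURVEY_COLUMNS = [
    "patient_id",
    "mailing_date",
    "responded",
    "smoked_past30",
    "smoked_7day_run",
    "smoked_two_weekends",
]
COVARIATE_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "race",
    "mental_illness",
    "respiratory_disease",
    "hospitalized_past_year",
    "charlson",
]


class IngestError(ValueError):
    """Fatal problem with an input table (missing column, duplicate key...)."""


@dataclass(frozen=True)
class HFRecord:
    """One EHR health-factor entry.

    ``label`` is uppercase-normalized and whitespace-trimmed on ingest, so
    downstream classification can match on exact strings.
    """

    patient_id: str
    site_id: str
    record_date: dt.date
    label: str


@dataclass(frozen=True)
class SurveyRecord:
    """One mailed 12-month follow-up survey.

    The three items are tri-state (True = yes, False = no, None = missing).
    If ``responded`` is False all items are missing.
    """

    patient_id: str
    mailing_date: dt.date
    responded: bool
    item_past30: Optional[bool] = None
    item_7consec: Optional[bool] = None
    item_2weekends: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.responded and any(
            v is not None
            for v in (self.item_past30, self.item_7consec, self.item_2weekends)
        ):
            raise ValueError(
                f"nonresponder {self.patient_id} has non-missing survey items"
            )

    @property
    def items(self) -> tuple[Optional[bool], Optional[bool], Optional[bool]]:
        return (self.item_past30, self.item_7consec, self.item_2weekends)


@dataclass(frozen=True)
class CovariateRecord:
    """Baseline demographics and clinical flags for one patient."""

    patient_id: str
    age: float
    sex: str
    race: str
    mental_illness: bool
    respiratory_disease: bool
    hospitalized_past_year: bool
    charlson: int

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 80:
            raise ValueError(f"age {self.age} outside trial range [18, 80]")
        if self.charlson < 0:
            raise ValueError("charlson index must be non-negative")


@dataclass
class ParseConfig:
    """Parsing options shared by the table readers.

    study_period, when set, rejects HF rows dated outside it (inclusive).
    """

    date_format: str = "%Y-%m-%d"
    study_period: Optional[tuple[dt.date, dt.date]] = None


@dataclass
class IngestLog:
    """Row accounting for one ingest: accepted + rejected == raw rows."""

    raw_rows: int = 0
    accepted: int = 0
    rejected: int = 0
    warnings: list[str] = field(default_factory=list)

    def reject(self, message: str) -> None:
        self.rejected += 1
        self.warnings.append(message)
        logger.warning(message)


@dataclass
class CohortDataset:
    """The assembled cohort: HF records, surveys, covariates, patient roster.

    ``patients`` is the union of ids seen in any source; surveys and
    covariates are unique per patient.
    """

    patients: set[str]
    hf_records: list[HFRecord]
    surveys: dict[str, SurveyRecord]
    covariates: dict[str, CovariateRecord]

    def hf_frame(self) -> pd.DataFrame:
        """HF records as a DataFrame (vectorized path for linkage)."""
        return pd.DataFrame(
            [(r.patient_id, r.site_id, r.record_date, r.label) for r in self.hf_records],
            columns=HF_COLUMNS,
        )

    def survey_frame(self) -> pd.DataFrame:
        rows = [
            (
                s.patient_id,
                s.mailing_date,
                s.responded,
                s.item_past30,
                s.item_7consec,
                s.item_2weekends,
            )
            for s in self.surveys.values()
        ]
        return pd.DataFrame(rows, columns=SURVEY_COLUMNS)

    def covariate_frame(self) -> pd.DataFrame:
        rows = [
            (
                c.patient_id,
                c.age,
                c.sex,
                c.race,
                c.mental_illness,
                c.respiratory_disease,
                c.hospitalized_past_year,
                c.charlson,
            )
            for c in self.covariates.values()
        ]
        return pd.DataFrame(rows, columns=COVARIATE_COLUMNS)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s) {missing}")


def _parse_date(value: object, config: ParseConfig) -> dt.date:
    return dt.datetime.strptime(str(value).strip(), config.date_format).date()


def _parse_tristate(value: object) -> Optional[bool]:
    """Map the file encoding {1, 0, empty} to {True, False, None}."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan"}:
        return None
    if text in {"1", "1.0"}:
        return True
    if text in {"0", "0.0"}:
        return False
    raise ValueError(f"cannot interpret tri-state value {value!r}")


def _parse_flag(value: object) -> bool:
    text = str(value).strip().lower()
    if text in {"1", "1.0", "true", "yes"}:
        return True
    if text in {"0", "0.0", "false", "no"}:
        return False
    raise ValueError(f"cannot interpret flag value {value!r}")


def read_hf_table(
    path: str | Path, config: ParseConfig | None = None
) -> tuple[list[HFRecord], IngestLog]:
    """Read the health-factor table.

    Labels are uppercased and trimmed.  Rows with unparseable dates, or
    dates outside the configured study period, are rejected with a warning;
    a missing required column is fatal.
    """
    config = config or ParseConfig()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, HF_COLUMNS, path)
    log = IngestLog(raw_rows=len(frame))
    records: list[HFRecord] = []
    for row in frame.itertuples(index=False):
        label = str(row.label).strip().upper()
        if not label:
            log.reject(f"{path}: empty label for patient {row.patient_id}")
            continue
        try:
            date = _parse_date(row.record_date, config)
        except ValueError:
            log.reject(
                f"{path}: unparseable date {row.record_date!r} for patient {row.patient_id}"
            )
            continue
        if config.study_period is not None:
            lo, hi = config.study_period
            if not lo <= date <= hi:
                log.reject(f"{path}: date {date} outside study period for {row.patient_id}")
                continue
        records.append(HFRecord(str(row.patient_id), str(row.site_id), date, label))
        log.accepted += 1
    logger.info("read %d HF records from %s (%d rejected)", log.accepted, path, log.rejected)
    return records, log


def read_survey_table(
    path: str | Path, config: ParseConfig | None = None
) -> tuple[list[SurveyRecord], IngestLog]:
    """Read the 12-month follow-up survey table.

    One survey per patient by design: a duplicate patient_id is fatal.
    Nonresponder rows get all-missing items regardless of file content.
    """
    config = config or ParseConfig()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, SURVEY_COLUMNS, path)
    dupes = frame["patient_id"][frame["patient_id"].duplicated()]
    if not dupes.empty:
        raise IngestError(f"{path}: duplicate survey patient_id(s): {sorted(set(dupes))}")
    log = IngestLog(raw_rows=len(frame))
    records: list[SurveyRecord] = []
    for row in frame.itertuples(index=False):
        try:
            mailing = _parse_date(row.mailing_date, config)
            responded = _parse_flag(row.responded)
            if responded:
                items = (
                    _parse_tristate(row.smoked_past30),
                    _parse_tristate(row.smoked_7day_run),
                    _parse_tristate(row.smoked_two_weekends),
                )
            else:
                items = (None, None, None)
        except ValueError as exc:
            log.reject(f"{path}: patient {row.patient_id}: {exc}")
            continue
        records.append(SurveyRecord(str(row.patient_id), mailing, responded, *items))
        log.accepted += 1
    logger.info("read %d survey records from %s (%d rejected)", log.accepted, path, log.rejected)
    return records, log


def read_covariate_table(
    path: str | Path, config: ParseConfig | None = None
) -> tuple[list[CovariateRecord], IngestLog]:
    """Read the baseline covariate table; invalid rows rejected with warning."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, COVARIATE_COLUMNS, path)
    log = IngestLog(raw_rows=len(frame))
    records: list[CovariateRecord] = []
    for row in frame.itertuples(index=False):
        try:
            records.append(
                CovariateRecord(
                    str(row.patient_id),
                    float(row.age),
                    str(row.sex),
                    str(row.race),
                    _parse_flag(row.mental_illness),
                    _parse_flag(row.respiratory_disease),
                    _parse_flag(row.hospitalized_past_year),
                    int(float(row.charlson)),
                )
            )
            log.accepted += 1
        except ValueError as exc:
            log.reject(f"{path}: patient {row.patient_id}: {exc}")
    return records, log


def assemble_cohort(
    hf_records: Iterable[HFRecord],
    surveys: Iterable[SurveyRecord],
    covariates: Iterable[CovariateRecord] = (),
) -> CohortDataset:
    """Join the three sources into one dataset.

    The patient roster is the union of ids across sources; a patient may be
    present in any subset of them (that incompleteness is itself an
    analysis outcome, the four-way source grouping).
    """
    hf_list = list(hf_records)
    survey_map: dict[str, SurveyRecord] = {}
    for s in surveys:
        if s.patient_id in survey_map:
            raise IngestError(f"duplicate survey for patient {s.patient_id}")
        survey_map[s.patient_id] = s
    cov_map = {c.patient_id: c for c in covariates}
    patients = (
        {r.patient_id for r in hf_list} | set(survey_map) | set(cov_map)
    )
    logger.info(
        "assembled cohort: %d patients, %d HF records, %d surveys, %d covariate rows",
        len(patients), len(hf_list), len(survey_map), len(cov_map),
    )
    return CohortDataset(patients, hf_list, survey_map, cov_map)


def load_cohort(
    hf_path: str | Path,
    survey_path: str | Path,
    covariate_path: str | Path | None = None,
    config: ParseConfig | None = None,
) -> CohortDataset:
    """Convenience: read all tables and assemble the dataset."""
    hf, _ = read_hf_table(hf_path, config)
    surveys, _ = read_survey_table(survey_path, config)
    covs: list[CovariateRecord] = []
    if covariate_path is not None:
        covs, _ = read_covariate_table(covariate_path, config)
    return assemble_cohort(hf, surveys, covs)


def write_cohort(dataset: CohortDataset, outdir: str | Path) -> dict[str, Path]:
    """Write hf.csv / survey.csv / covariates.csv readable by the readers.

    Tri-state survey items are encoded as 1 / 0 / empty.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hf": outdir / "hf.csv",
        "survey": outdir / "survey.csv",
        "covariates": outdir / "covariates.csv",
    }

    hf = dataset.hf_frame()
    hf["record_date"] = hf["record_date"].map(lambda d: d.isoformat())
    hf.to_csv(paths["hf"], index=False)

    def _tri(v: Optional[bool]) -> str:
        return "" if v is None else str(int(v))

    sv = dataset.survey_frame()
    sv["mailing_date"] = sv["mailing_date"].map(lambda d: d.isoformat())
    sv["responded"] = sv["responded"].astype(int)
    for col in ("smoked_past30", "smoked_7day_run", "smoked_two_weekends"):
        sv[col] = sv[col].map(_tri)
    sv.to_csv(paths["survey"], index=False)

    cv = dataset.covariate_frame()
    for col in ("mental_illness", "respiratory_disease", "hospitalized_past_year"):
        if len(cv):
            cv[col] = cv[col].astype(int)
    cv.to_csv(paths["covariates"], index=False)
    return paths
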