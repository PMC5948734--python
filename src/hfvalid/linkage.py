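"""Temporal linkage: pick each patient's analysis HF and assign source groups.

The follow-up HF for a patient is the *temporally closest* classifiable
health factor within a symmetric window around the survey mailing date
(default ±120 days, bounds inclusive).  Deterministic tie rules, applied in
order when several records minimize the absolute offset:

1. prefer the pre-mailing record (the survey's recall period lies before
   mailing);
2. among same-day conflicting statuses, prefer SMOKER over QUITTER over
   smokeless-only (conservative against overstating cessation); a conflict
   is logged.

Patients are then partitioned into the four source groups — both sources,
survey only, HF only, neither — where "has survey" means a determinate
prolonged-abstinence status and "has HF" means a classifiable record in
window.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import HFRecord
from .status import (
    HFStatus,
    QuitIndicator,
    SurveyStatus,
    Vocabulary,
    binary_followup_status,
    classify_hf_label,
    classify_labels,
)

logger = logging.getLogger(__name__)

# Same-day conflict preference: lower sorts first.
_STATUS_PRIORITY = {
    HFStatus.SMOKER: 0,
    HFStatus.QUITTER: 1,
    HFStatus.NONSMOKER_OTHER_TOBACCO: 2,
}


class SourceGroup(Enum):
    BOTH = "both"
    SURVEY_ONLY = "survey_only"
    HF_ONLY = "hf_only"
    NEITHER = "neither"


@dataclass(frozen=True)
class MatchResult:
    """The selected follow-up HF for one patient."""

    patient_id: str
    matched_record: HFRecord
    status: HFStatus
    offset_days: int  # record_date - mailing_date, signed
    window_days: int

    def __post_init__(self) -> None:
        if abs(self.offset_days) > self.window_days:
            raise ValueError("matched record outside the window")


def hfs_in_window(
    records: Iterable[HFRecord],
    index_date: dt.date,
    window_days: int,
    vocab: Vocabulary,
) -> list[tuple[HFRecord, HFStatus, int]]:
    """Classifiable records with |record_date - index_date| <= window_days.

    Returns (record, status, offset) triples; unclassified labels are
    dropped, mirroring the analysis which uses only records that map to a
    known status.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    out = []
    for rec in records:
        offset = (rec.record_date - index_date).days
        if abs(offset) > window_days:
            continue
        status = classify_hf_label(rec.label, vocab)
        if status is HFStatus.UNCLASSIFIED:
            continue
        out.append((rec, status, offset))
    return out


def closest_hf(
    records: Iterable[HFRecord],
    index_date: dt.date,
    window_days: int,
    vocab: Vocabulary,
) -> Optional[MatchResult]:
    """Select the temporally closest classifiable HF, or None.

    Sort key is (|offset|, post-mailing flag, status priority), making the
    choice invariant to input order.
    """
    candidates = hfs_in_window(records, index_date, window_days, vocab)
    if not candidates:
        return None
    ranked = sorted(
        candidates,
        key=lambda t: (abs(t[2]), t[2] > 0, _STATUS_PRIORITY[t[1]], t[0].label),
    )
    best = ranked[0]
    same_offset = {t[1] for t in ranked if t[2] == best[2]}
    if len(same_offset) > 1:
        logger.warning(
            "patient %s: conflicting same-day statuses %s at offset %d; kept %s",
            best[0].patient_id,
            sorted(s.value for s in same_offset),
            best[2],
            best[1].value,
        )
    return MatchResult(best[0].patient_id, best[0], best[1], best[2], window_days)


def link_cohort(
    hf_frame: pd.DataFrame,
    survey_frame: pd.DataFrame,
    window_days: int,
    vocab: Vocabulary,
) -> pd.DataFrame:
    """Vectorized closest-HF selection for a whole cohort.

    ``hf_frame`` needs columns patient_id / record_date / label and
    ``survey_frame`` patient_id / mailing_date.  Patients without a survey
    mailing date have no index date and receive no match.  Returns one row
    per matched patient with columns: patient_id, offset_days, hf_status,
    hf_quit (QuitIndicator), label.
    """
    if hf_frame.empty or survey_frame.empty:
        return pd.DataFrame(
            columns=["patient_id", "offset_days", "hf_status", "hf_quit", "label"]
        )
    merged = hf_frame.merge(
        survey_frame[["patient_id", "mailing_date"]], on="patient_id", how="inner"
    )
    if merged.empty:
        return pd.DataFrame(
            columns=["patient_id", "offset_days", "hf_status", "hf_quit", "label"]
        )
    offsets = (
        pd.to_datetime(merged["record_date"]) - pd.to_datetime(merged["mailing_date"])
    ).dt.days
    merged = merged.assign(offset_days=offsets)
    merged = merged[merged["offset_days"].abs() <= window_days]
    merged = merged.assign(hf_status=classify_labels(merged["label"], vocab))
    merged = merged[merged["hf_status"] != HFStatus.UNCLASSIFIED]
    if merged.empty:
        return pd.DataFrame(
            columns=["patient_id", "offset_days", "hf_status", "hf_quit", "label"]
        )
    merged = merged.assign(
        _abs=merged["offset_days"].abs(),
        _post=(merged["offset_days"] > 0).astype(int),
        _prio=merged["hf_status"].map(_STATUS_PRIORITY),
    )
    merged = merged.sort_values(
        ["patient_id", "_abs", "_post", "_prio", "label"], kind="mergesort"
    )
    # warn on same-closest-offset status conflicts before deduplicating
    top = merged.drop_duplicates(["patient_id", "_abs", "_post"], keep=False)
    conflict_pool = merged[~merged.index.isin(top.index)]
    if not conflict_pool.empty:
        firsts = merged.drop_duplicates("patient_id")
        key = conflict_pool.merge(
            firsts[["patient_id", "_abs", "_post"]],
            on=["patient_id", "_abs", "_post"],
        )
        n_conflict = (key.groupby("patient_id")["hf_status"].nunique() > 1).sum()
        if n_conflict:
            logger.warning(
                "%d patient(s) had conflicting statuses at the closest offset; "
                "resolved smoker > quitter > smokeless",
                n_conflict,
            )
    best = merged.drop_duplicates("patient_id")
    return best.assign(
        hf_quit=best["hf_status"].map(binary_followup_status)
    )[["patient_id", "offset_days", "hf_status", "hf_quit", "label"]].reset_index(
        drop=True
    )


def assign_source_groups(
    patients: Iterable[str],
    survey_status: Mapping[str, SurveyStatus],
    matched: Iterable[str],
) -> pd.Series:
    """Four-way data-source partition over the patient roster.

    ``survey_status`` holds classified statuses for responders; a patient
    "has survey data" only if that status is determinate.  ``matched`` is
    the set of patient ids with a classifiable HF in window.
    """
    matched_set = set(matched)
    out = {}
    for pid in patients:
        status = survey_status.get(pid)
        has_survey = status in (
            SurveyStatus.PROLONGED_ABSTINENT,
            SurveyStatus.NOT_ABSTINENT,
        )
        has_hf = pid in matched_set
        if has_survey and has_hf:
            grp = SourceGroup.BOTH
        elif has_survey:
            grp = SourceGroup.SURVEY_ONLY
        elif has_hf:
            grp = SourceGroup.HF_ONLY
        else:
            grp = SourceGroup.NEITHER
        out[pid] = grp
    return pd.Series(out, name="source_group")


def baseline_eligibility(
    records: Iterable[HFRecord],
    reference_date: dt.date,
    vocab: Vocabulary,
    lookback_days: int = 90,
) -> bool:
    """Trial-entry screen: a smoker-classified HF in the prior 90 days.

    The lookback window is [reference_date - lookback_days, reference_date],
    inclusive on both ends.
    """
    for rec in records:
        offset = (rec.record_date - reference_date).days
        if -lookback_days <= offset <= 0:
            if classify_hf_label(rec.label, vocab) is HFStatus.SMOKER:
                return True
    return False
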