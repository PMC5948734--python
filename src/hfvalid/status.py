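"""Status classification: HF labels -> smoking status, survey items -> abstinence.

Two classifiers live here.

*Health-factor side.*  Free-text-like structured labels ("CURRENT SMOKER",
"NON TOBACCO USER - QUIT IN PAST YEAR", ...) are mapped to one of four
statuses via a curated vocabulary of literal strings.  Matching is exact on
uppercase-trimmed labels by default; a curated-substring mode exists but is
off by default because substring matching invites false hits (e.g.
"NON-SMOKER" contains "SMOKER").  Patients whose label indicates smokeless
tobacco only are treated as cigarette-abstinent, since the outcome under
study is cigarette smoking.

*Survey side.*  Self-reported 6-month prolonged abstinence is the gold
standard.  A responder fails it if any of three items is affirmative:
smoking in the past 30 days, smoking on seven consecutive days during the
past 6 months, or smoking on two consecutive weekends.  All-negative items
mean prolonged abstinence; a mix of negative and missing items with no
affirmative is indeterminate and is excluded downstream (the missing-data
rule is a package decision, recorded in run metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .records import SurveyRecord

logger = logging.getLogger(__name__)


class HFStatus(Enum):
    SMOKER = "smoker"
    QUITTER = "quitter"
    NONSMOKER_OTHER_TOBACCO = "nonsmoker_other_tobacco"
    UNCLASSIFIED = "unclassified"


class SurveyStatus(Enum):
    PROLONGED_ABSTINENT = "prolonged_abstinent"
    NOT_ABSTINENT = "not_abstinent"
    INDETERMINATE = "indeterminate"


class QuitIndicator(Enum):
    """Binary follow-up outcome shared by both sources: quit vs smoker."""

    QUIT = "quit"
    SMOKER = "smoker"


class VocabularyError(ValueError):
    """Invalid vocabulary (overlapping sets, malformed file)."""


@dataclass(frozen=True)
class Vocabulary:
    """Label sets defining the HF status map; the three sets are disjoint."""

    smoker_labels: frozenset[str]
    quitter_labels: frozenset[str]
    smokeless_labels: frozenset[str]
    match_mode: str = "exact"  # "exact" | "substring"

    def __post_init__(self) -> None:
        if self.match_mode not in {"exact", "substring"}:
            raise VocabularyError(f"unknown match_mode {self.match_mode!r}")
        sets = {
            "smoker": self.smoker_labels,
            "quitter": self.quitter_labels,
            "smokeless": self.smokeless_labels,
        }
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise VocabularyError(
                        f"labels in both {a} and {b} sets: {sorted(overlap)}"
                    )
        if not self.quitter_labels:
            logger.warning("vocabulary has an empty quitter set: no quitter detectable")

    @staticmethod
    def from_sets(
        smoker: Iterable[str],
        quitter: Iterable[str],
        smokeless: Iterable[str] = (),
        match_mode: str = "exact",
    ) -> "Vocabulary":
        norm = lambda xs: frozenset(str(x).strip().upper() for x in xs)
        return Vocabulary(norm(smoker), norm(quitter), norm(smokeless), match_mode)

    def extended(self, category: str, labels: Iterable[str]) -> "Vocabulary":
        """A new vocabulary with extra labels added to one category."""
        parts = {
            "smoker": set(self.smoker_labels),
            "quitter": set(self.quitter_labels),
            "smokeless": set(self.smokeless_labels),
        }
        parts[category].update(str(x).strip().upper() for x in labels)
        return Vocabulary.from_sets(
            parts["smoker"], parts["quitter"], parts["smokeless"], self.match_mode
        )


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a vocabulary YAML (keys: smoker, quitter, smokeless, match_mode)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise VocabularyError(f"{path}: vocabulary file must be a mapping")
    vocab = Vocabulary.from_sets(
        raw.get("smoker", []),
        raw.get("quitter", []),
        raw.get("smokeless", []),
        raw.get("match_mode", "exact"),
    )
    logger.info(
        "loaded vocabulary from %s: %d smoker / %d quitter / %d smokeless labels",
        path,
        len(vocab.smoker_labels),
        len(vocab.quitter_labels),
        len(vocab.smokeless_labels),
    )
    return vocab


def default_vocabulary() -> Vocabulary:
    """The vocabulary shipped with the package."""
    ref = resources.files("hfvalid").joinpath("data/vocabulary.yaml")
    with resources.as_file(ref) as path:
        return load_vocabulary(path)


def classify_hf_label(label: str, vocab: Vocabulary) -> HFStatus:
    """Map one HF label to a status; unrecognized labels are UNCLASSIFIED."""
    norm = str(label).strip().upper()
    if vocab.match_mode == "exact":
        if norm in vocab.smoker_labels:
            return HFStatus.SMOKER
        if norm in vocab.quitter_labels:
            return HFStatus.QUITTER
        if norm in vocab.smokeless_labels:
            return HFStatus.NONSMOKER_OTHER_TOBACCO
        return HFStatus.UNCLASSIFIED
    hits = {
        status
        for status, labels in (
            (HFStatus.SMOKER, vocab.smoker_labels),
            (HFStatus.QUITTER, vocab.quitter_labels),
            (HFStatus.NONSMOKER_OTHER_TOBACCO, vocab.smokeless_labels),
        )
        if any(entry in norm for entry in labels)
    }
    if len(hits) == 1:
        return hits.pop()
    if len(hits) > 1:
        logger.warning("label %r matches multiple categories; left unclassified", label)
    return HFStatus.UNCLASSIFIED


def classify_labels(labels: pd.Series, vocab: Vocabulary) -> pd.Series:
    """Vectorized :func:`classify_hf_label` over a Series of labels."""
    if vocab.match_mode == "exact":
        mapping = {lab: HFStatus.SMOKER for lab in vocab.smoker_labels}
        mapping.update({lab: HFStatus.QUITTER for lab in vocab.quitter_labels})
        mapping.update(
            {lab: HFStatus.NONSMOKER_OTHER_TOBACCO for lab in vocab.smokeless_labels}
        )
        return (
            labels.astype(str)
            .str.strip()
            .str.upper()
            .map(mapping)
            .fillna(HFStatus.UNCLASSIFIED)
        )
    return labels.map(lambda lab: classify_hf_label(lab, vocab))


def binary_followup_status(status: HFStatus) -> Optional[QuitIndicator]:
    """Collapse the HF status to the binary quit indicator.

    Smokeless-only users count as quit because the outcome is cigarette
    abstinence; unclassified records are unusable (None) and are treated as
    absent by the linkage step.
    """
    if status is HFStatus.SMOKER:
        return QuitIndicator.SMOKER
    if status in (HFStatus.QUITTER, HFStatus.NONSMOKER_OTHER_TOBACCO):
        return QuitIndicator.QUIT
    return None


def classify_survey(record: SurveyRecord) -> SurveyStatus:
    """Evaluate 6-month prolonged abstinence from the three survey items.

    Any affirmative item means not abstinent regardless of missingness in
    the others; three negatives mean prolonged abstinence; otherwise the
    status is indeterminate.  Raises on nonresponders — callers filter them
    out first.
    """
    if not record.responded:
        raise ValueError(
            f"patient {record.patient_id}: cannot classify a nonresponder survey"
        )
    items = record.items
    if any(v is True for v in items):
        return SurveyStatus.NOT_ABSTINENT
    if all(v is False for v in items):
        return SurveyStatus.PROLONGED_ABSTINENT
    return SurveyStatus.INDETERMINATE


def survey_quit_indicator(status: SurveyStatus) -> Optional[QuitIndicator]:
    """Binary survey outcome; indeterminate statuses are unusable (None)."""
    if status is SurveyStatus.PROLONGED_ABSTINENT:
        return QuitIndicator.QUIT
    if status is SurveyStatus.NOT_ABSTINENT:
        return QuitIndicator.SMOKER
    return None
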