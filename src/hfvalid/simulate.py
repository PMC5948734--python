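"""Synthetic smoking-cessation cohort with two asynchronous observers.

The generator produces the statistical structure the validation analysis
assumes, so every pipeline stage is testable without access to clinical
data:

* a per-patient daily smoking **trajectory** over the study horizon.  Every
  patient smokes at day 0 (the trial enrolled current smokers).  Quit
  attempts arrive while smoking as a Poisson process whose rate is a
  constant background plus a burst that decays after enrollment — quit
  activity in a cessation trial is front-loaded.  Each attempt is either
  durable (abstinent through the horizon) or ends in relapse after a
  geometric number of days with a short mean: most attempts collapse within
  weeks, the heavy-early-relapse pattern of real quit attempts;

* a **survey observer**: one mailed follow-up at the configured mailing
  day.  Response is Bernoulli from a logistic model on age and mental
  illness (responders older, less mental illness).  Responders answer the
  three abstinence items truthfully from their trajectory (an optional
  item-missingness probability exists, default 0);

* an **EHR observer**: clinic visits per patient as a Poisson count over
  the horizon, site-specific rates.  At each visit the site records a
  tobacco health factor with its recording probability.  The recorded
  status reflects the truth on the visit day, except that with the
  carry-forward probability the staff copy the status from the previous
  contact instead of re-assessing, and the label can misstate the status
  (an abstinent patient recorded with a smoker label and vice versa —
  templated fields lag behind true behavior).  A small fraction of entries
  use an unclassifiable site-local label.

Default rates are calibrated so that true 6-month prolonged abstinence at
the 12-month mailing sits near 10-11% and per-site health-factor
availability spans roughly 4% to 80%.  All randomness flows from a single
integer seed; identical config + seed reproduce identical output files.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import (
    CohortDataset,
    CovariateRecord,
    HFRecord,
    SurveyRecord,
    assemble_cohort,
    write_cohort,
)
from .status import Vocabulary, default_vocabulary

logger = logging.getLogger(__name__)

#: Calendar anchor for day 0; a Monday, so weekday(day) = day % 7 (5 = Saturday).
ANCHOR_DATE = dt.date(2010, 1, 4)


def day_to_date(day: int) -> dt.date:
    return ANCHOR_DATE + dt.timedelta(days=int(day))


@dataclass(frozen=True)
class SiteProfile:
    """One site's observation process: clinic contact rate and HF recording."""

    site_id: str
    visit_rate: float  # visits per person-year
    record_prob: float  # probability a visit produces a tobacco HF
    weight: float = 1.0  # share of patients enrolled at this site

    def __post_init__(self) -> None:
        if self.visit_rate < 0 or not 0 <= self.record_prob <= 1 or self.weight < 0:
            raise ValueError("invalid site profile")


#: Availability extremes across sites mirror the wide between-site spread
#: (one site records HFs for ~4/5 of patients, another for almost none).
DEFAULT_SITES = (
    SiteProfile("A", visit_rate=4.0, record_prob=0.65),
    SiteProfile("B", visit_rate=3.0, record_prob=0.35),
    SiteProfile("C", visit_rate=2.0, record_prob=0.03),
    SiteProfile("D", visit_rate=3.5, record_prob=0.45),
)


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the calibrated study conditions."""

    n_patients: int = 5000
    sites: Sequence[SiteProfile] = DEFAULT_SITES
    mailing_day: int = 365
    max_window_days: int = 120

    # quit-attempt process (rates per person-year while smoking)
    base_attempt_rate: float = 0.10
    burst_attempt_rate: float = 2.6
    burst_decay_days: float = 75.0
    p_permanent: float = 0.21
    temp_duration_mean: float = 14.0  # days, geometric relapse clock

    # EHR recording imperfections
    p_carry_forward: float = 0.35
    p_false_smoker: float = 0.45  # abstinent patient recorded with a smoker label
    p_false_quit: float = 0.04  # smoking patient recorded with a quitter label
    p_smokeless_label: float = 0.02  # abstinent entry uses a smokeless label
    p_unclassified_label: float = 0.03

    # survey response model (logistic)
    response_intercept: float = 0.72
    response_age_per_decade: float = 0.35
    response_mental_illness: float = -0.25
    item_missing_prob: float = 0.0

    # covariate distribution (echoes the trial's baseline table)
    age_mean: float = 56.2
    age_sd: float = 12.0
    p_mental_illness: float = 0.48
    p_respiratory: float = 0.187
    p_hospitalized: float = 0.106
    p_male: float = 0.943
    race_probs: tuple[float, float, float] = (0.58, 0.28, 0.14)  # white/black/other
    charlson_mean: float = 1.03

    @property
    def horizon(self) -> int:
        """Days simulated: day 0 through mailing_day + max_window_days."""
        return self.mailing_day + self.max_window_days + 1

    def validate(self) -> None:
        probs = [
            self.p_permanent, self.p_carry_forward, self.p_false_smoker,
            self.p_false_quit, self.p_smokeless_label, self.p_unclassified_label,
            self.item_missing_prob, self.p_mental_illness, self.p_respiratory,
            self.p_hospitalized, self.p_male,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_patients < 0 or self.mailing_day <= 0 or self.max_window_days <= 0:
            raise ValueError("sizes and windows must be positive")
        if min(self.base_attempt_rate, self.burst_attempt_rate) < 0:
            raise ValueError("attempt rates must be non-negative")
        if self.temp_duration_mean < 1:
            raise ValueError("temporary abstinence must last at least one day")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["sites"] = [dataclasses.asdict(s) for s in self.sites]
        return out


@dataclass
class Trajectory:
    """Piecewise daily smoking history: contiguous (start, end, smoking)
    segments covering [0, horizon); the patient smokes at day 0."""

    patient_id: str
    horizon: int
    segments: list[tuple[int, int, bool]]

    def __post_init__(self) -> None:
        if not self.segments or self.segments[0][0] != 0:
            raise ValueError("segments must start at day 0")
        if not self.segments[0][2]:
            raise ValueError("patient must smoke at baseline")
        prev_end = 0
        for start, end, _ in self.segments:
            if start != prev_end or end <= start:
                raise ValueError("segments must be contiguous and non-empty")
            prev_end = end
        if prev_end != self.horizon:
            raise ValueError("segments must cover the horizon")

    def smoking_array(self) -> np.ndarray:
        """Daily smoking indicator of length horizon."""
        out = np.empty(self.horizon, dtype=bool)
        for start, end, smoking in self.segments:
            out[start:end] = smoking
        return out

    def smoking_on(self, day: int) -> bool:
        if not 0 <= day < self.horizon:
            raise ValueError(f"day {day} outside horizon")
        for start, end, smoking in self.segments:
            if start <= day < end:
                return smoking
        raise AssertionError("unreachable: segments cover the horizon")


def _abstinence_intervals(
    rng: np.random.Generator, config: SimulationConfig
) -> list[tuple[int, int]]:
    """Abstinence intervals [start, end) for one patient, by thinning a
    decaying-rate attempt process that runs only while smoking."""
    horizon = config.horizon
    base = config.base_attempt_rate / 365.0
    burst = config.burst_attempt_rate / 365.0
    tau = config.burst_decay_days
    lam_max = base + burst
    if lam_max <= 0:
        return []
    intervals: list[tuple[int, int]] = []
    t = 0.0
    while t < horizon:
        t += rng.exponential(1.0 / lam_max)
        if t >= horizon:
            break
        if rng.random() >= (base + burst * np.exp(-t / tau)) / lam_max:
            continue  # thinned-out candidate event
        start = max(int(t), 1)  # the patient smokes at day 0 by eligibility
        if rng.random() < config.p_permanent:
            intervals.append((start, horizon))
            break
        if config.temp_duration_mean <= 1.0:
            dur = 1
        else:
            dur = 1 + int(rng.geometric(1.0 / (config.temp_duration_mean - 1.0)))
        end = min(start + dur, horizon)
        intervals.append((start, end))
        t = float(end)
    return intervals


def _intervals_to_segments(
    intervals: list[tuple[int, int]], horizon: int
) -> list[tuple[int, int, bool]]:
    segments: list[tuple[int, int, bool]] = []
    cursor = 0
    for start, end in intervals:
        if start > cursor:
            segments.append((cursor, start, True))
        segments.append((start, end, False))
        cursor = end
    if cursor < horizon:
        segments.append((cursor, horizon, True))
    return segments


def simulate_trajectories(
    config: SimulationConfig, seed: int
) -> list[Trajectory]:
    """Generate all patient trajectories; deterministic under fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(config.n_patients):
        intervals = _abstinence_intervals(rng, config)
        out.append(
            Trajectory(
                patient_id=f"P{i:06d}",
                horizon=config.horizon,
                segments=_intervals_to_segments(intervals, config.horizon),
            )
        )
    return out


def survey_item_truth(
    trajectory: Trajectory, mailing_day: int
) -> tuple[bool, bool, bool]:
    """Truthful values of the three abstinence items at the mailing day.

    Recall window: the 183 days [mailing_day - 182, mailing_day].
    Items: smoked in the past 30 days; smoked on 7 consecutive days; smoked
    on two consecutive calendar weekends (Saturday/Sunday; a weekend counts
    as smoked if smoking occurred on at least one of its in-window days).
    """
    lo = mailing_day - 182
    if lo < 0 or mailing_day >= trajectory.horizon:
        raise ValueError("trajectory does not cover the 6-month recall window")
    sm = trajectory.smoking_array()
    window = sm[lo : mailing_day + 1]
    past30 = bool(sm[mailing_day - 29 : mailing_day + 1].any())
    run7 = False
    run = 0
    for v in window:
        run = run + 1 if v else 0
        if run >= 7:
            run7 = True
            break
    saturdays = [d for d in range(lo - 1, mailing_day + 1) if d % 7 == 5]
    smoked_weekend = []
    for sat in saturdays:
        days = [d for d in (sat, sat + 1) if lo <= d <= mailing_day]
        if days:
            smoked_weekend.append(bool(sm[days].any()) if len(days) > 1 else bool(sm[days[0]]))
    two_weekends = any(
        smoked_weekend[i] and smoked_weekend[i + 1]
        for i in range(len(smoked_weekend) - 1)
    )
    return past30, run7, two_weekends


def true_prolonged_abstinence(trajectory: Trajectory, mailing_day: int) -> bool:
    """Ground-truth 6-month prolonged abstinence: no item triggers."""
    return not any(survey_item_truth(trajectory, mailing_day))


def _sample_covariates(
    rng: np.random.Generator, config: SimulationConfig, patient_id: str
) -> CovariateRecord:
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 80.0))
    sex = "M" if rng.random() < config.p_male else "F"
    race = ("white", "black", "other")[rng.choice(3, p=config.race_probs)]
    return CovariateRecord(
        patient_id=patient_id,
        age=round(age, 1),
        sex=sex,
        race=race,
        mental_illness=bool(rng.random() < config.p_mental_illness),
        respiratory_disease=bool(rng.random() < config.p_respiratory),
        hospitalized_past_year=bool(rng.random() < config.p_hospitalized),
        charlson=int(rng.poisson(config.charlson_mean)),
    )


def observe_survey(
    trajectory: Trajectory,
    covariates: CovariateRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SurveyRecord:
    """One mailed survey: logistic response, truthful items if returned."""
    logit = (
        config.response_intercept
        + config.response_age_per_decade * (covariates.age - 57.0) / 10.0
        + config.response_mental_illness * covariates.mental_illness
    )
    responded = bool(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
    mailing_date = day_to_date(config.mailing_day)
    if not responded:
        return SurveyRecord(trajectory.patient_id, mailing_date, False)
    truth = survey_item_truth(trajectory, config.mailing_day)
    items = [
        None if config.item_missing_prob and rng.random() < config.item_missing_prob
        else bool(v)
        for v in truth
    ]
    return SurveyRecord(trajectory.patient_id, mailing_date, True, *items)


def observe_hf(
    trajectory: Trajectory,
    site: SiteProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    vocab: Optional[Vocabulary] = None,
) -> list[HFRecord]:
    """The EHR's view of one patient: visit process plus recording model.

    Every patient also carries one baseline smoker HF dated up to 90 days
    before day 0 — the screen that made them trial-eligible.
    """
    vocab = vocab or _VOCAB_CACHE.get()
    smoker_labels = sorted(vocab.smoker_labels)
    quitter_labels = sorted(vocab.quitter_labels)
    smokeless_labels = sorted(vocab.smokeless_labels)
    sm = trajectory.smoking_array()
    records = [
        HFRecord(
            trajectory.patient_id,
            site.site_id,
            day_to_date(-int(rng.integers(0, 91))),
            smoker_labels[int(rng.integers(len(smoker_labels)))],
        )
    ]
    n_visits = rng.poisson(site.visit_rate * config.horizon / 365.0)
    if n_visits == 0:
        return records
    visit_days = np.sort(rng.integers(0, config.horizon, size=n_visits))
    prev_day = 0
    for day in visit_days:
        day = int(day)
        recorded = rng.random() < site.record_prob
        carried = rng.random() < config.p_carry_forward
        if recorded:
            source_day = prev_day if carried else day
            smoking = bool(sm[source_day])
            if smoking:
                report_smoker = rng.random() >= config.p_false_quit
            else:
                report_smoker = rng.random() < config.p_false_smoker
            if rng.random() < config.p_unclassified_label:
                label = f"ZZ {site.site_id} LOCAL TOBACCO FIELD"
            elif report_smoker:
                label = smoker_labels[int(rng.integers(len(smoker_labels)))]
            elif smokeless_labels and rng.random() < config.p_smokeless_label:
                label = smokeless_labels[int(rng.integers(len(smokeless_labels)))]
            else:
                label = quitter_labels[int(rng.integers(len(quitter_labels)))]
            records.append(
                HFRecord(trajectory.patient_id, site.site_id, day_to_date(day), label)
            )
        prev_day = day
    return records


class _VocabCache:
    """Default vocabulary loaded once per process."""

    def __init__(self) -> None:
        self._vocab: Optional[Vocabulary] = None

    def get(self) -> Vocabulary:
        if self._vocab is None:
            self._vocab = default_vocabulary()
        return self._vocab


_VOCAB_CACHE = _VocabCache()


def generate_cohort(
    config: SimulationConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> tuple[CohortDataset, dict]:
    """Generate the full synthetic cohort.

    Returns the assembled dataset plus a manifest (config + seed).  When
    ``outdir`` is given, writes hf.csv / survey.csv / covariates.csv and
    manifest.json there; regenerating with the same config and seed gives
    byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    vocab = _VOCAB_CACHE.get()
    site_weights = np.array([s.weight for s in config.sites], dtype=float)
    site_weights = site_weights / site_weights.sum() if site_weights.sum() else site_weights

    hf_records: list[HFRecord] = []
    surveys: list[SurveyRecord] = []
    covariates: list[CovariateRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        site = config.sites[int(rng.choice(len(config.sites), p=site_weights))]
        intervals = _abstinence_intervals(rng, config)
        trajectory = Trajectory(
            pid, config.horizon, _intervals_to_segments(intervals, config.horizon)
        )
        cov = _sample_covariates(rng, config, pid)
        covariates.append(cov)
        surveys.append(observe_survey(trajectory, cov, config, rng))
        hf_records.extend(observe_hf(trajectory, site, config, rng, vocab))

    dataset = assemble_cohort(hf_records, surveys, covariates)
    manifest = {
        "generator": "hfvalid.simulate",
        "seed": int(seed),
        "config": config.to_dict(),
        "n_hf_records": len(hf_records),
        "n_patients": config.n_patients,
    }
    if outdir is not None:
        outdir = Path(outdir)
        write_cohort(dataset, outdir)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("generated cohort: %d patients, %d HF records", config.n_patients, len(hf_records))
    return dataset, manifest
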