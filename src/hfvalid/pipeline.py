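"""End-to-end orchestration: ingest -> classify -> link -> agreement -> report.

``analyze_cohort`` is the library entry point; ``run_pipeline`` wraps it
with config handling and file output (JSON report plus CSV tables shaped
like the published agreement-by-window/site and subgroup tables).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .agreement import (
    AgreementResult,
    agreement_summary,
    availability_by_window,
    build_confusion,
    single_source_quit_rates,
    stratified_agreement,
)
from .linkage import SourceGroup, assign_source_groups, link_cohort
from .records import CohortDataset, load_cohort
from .status import (
    QuitIndicator,
    SurveyStatus,
    Vocabulary,
    classify_survey,
    default_vocabulary,
    load_vocabulary,
    survey_quit_indicator,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = (120, 90, 60, 30)

#: Subgroup definitions over the covariate table (column, predicate label).
SUBGROUP_COLUMNS = {
    "age_65_plus": lambda cov: cov["age"] >= 65,
    "respiratory_disease": lambda cov: cov["respiratory_disease"],
    "mental_illness": lambda cov: cov["mental_illness"],
    "hospitalized_past_year": lambda cov: cov["hospitalized_past_year"],
}

#: Analysis decisions recorded in every report, so a reader can audit the
#: choices made where the underlying procedure is underdetermined.
ANALYSIS_DECISIONS = {
    "gold_standard": "survey 6-month prolonged abstinence",
    "window_bounds": "inclusive on both sides",
    "tie_break": "equidistant records resolved toward the pre-mailing record",
    "same_day_conflict": "smoker > quitter > smokeless-only, with warning",
    "indeterminate_survey": "treated as lacking survey data",
    "smokeless_only": "counted as quit (cigarette-abstinent)",
    "kappa_se": "large-sample asymptotic (Fleiss-type, agreement-weighted)",
    "mcnemar": "no continuity correction",
    "ci": "Wald, 1.96*SE, truncated to [0, 100] percent / [-1, 1] kappa",
    "multiple_testing": "none applied",
}


@dataclass
class RunConfig:
    """One pipeline run: either three input CSVs or a simulate block."""

    hf_path: Optional[str] = None
    survey_path: Optional[str] = None
    covariates_path: Optional[str] = None
    simulate: Optional[dict] = None
    vocabulary_path: Optional[str] = None
    windows: Sequence[int] = DEFAULT_WINDOWS
    min_stratum: int = 30
    outdir: str = "hfvalid_out"
    seed: int = 0

    def validate(self) -> None:
        have_paths = self.hf_path is not None and self.survey_path is not None
        if have_paths == (self.simulate is not None):
            raise ValueError(
                "config must provide exactly one of input paths or a simulate block"
            )
        windows = list(self.windows)
        if len(set(windows)) != len(windows) or any(w <= 0 for w in windows):
            raise ValueError("windows must be positive and unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def classify_surveys(dataset: CohortDataset) -> dict[str, SurveyStatus]:
    """Survey status for every responder (nonresponders have no status)."""
    return {
        pid: classify_survey(rec)
        for pid, rec in dataset.surveys.items()
        if rec.responded
    }


def analyze_cohort(
    dataset: CohortDataset,
    vocab: Optional[Vocabulary] = None,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    min_stratum: int = 30,
    se_method: str = "fleiss",
) -> dict:
    """Run the full validation analysis on an assembled cohort.

    Returns a report dict with per-window and per-site agreement, subgroup
    agreement, the four-way source-group split, availability by window,
    single-source quit rates, and the decision metadata.
    """
    vocab = vocab or default_vocabulary()
    windows = sorted(set(int(w) for w in windows), reverse=True)
    wmax = windows[0]

    survey_status = classify_surveys(dataset)
    survey_quit = {
        pid: survey_quit_indicator(status) for pid, status in survey_status.items()
    }

    hf_frame = dataset.hf_frame()
    survey_frame = dataset.survey_frame()
    linked = {w: link_cohort(hf_frame, survey_frame, w, vocab) for w in windows}

    # per-patient site of the matched (widest-window) record
    match_wmax = linked[wmax].set_index("patient_id")
    site_by_patient = (
        hf_frame.drop_duplicates("patient_id").set_index("patient_id")["site_id"]
        if "site_id" in hf_frame.columns and not hf_frame.empty
        else pd.Series(dtype=object)
    )

    def both_frame(window: int) -> pd.DataFrame:
        sub = linked[window]
        rows = []
        for row in sub.itertuples(index=False):
            sq = survey_quit.get(row.patient_id)
            if sq is None or row.hf_quit is None:
                continue
            rows.append((row.patient_id, sq, row.hf_quit))
        return pd.DataFrame(rows, columns=["patient_id", "survey_quit", "hf_quit"])

    frames = {w: both_frame(w) for w in windows}
    base = frames[wmax].copy()
    if not base.empty:
        base["site"] = base["patient_id"].map(site_by_patient)
    cov = dataset.covariate_frame()

    report: dict = {
        "package_version": __version__,
        "windows": {},
        "sites": {},
        "subgroups": {},
        "metadata": dict(ANALYSIS_DECISIONS) | {
            "se_method": se_method,
            "windows": windows,
            "min_stratum": min_stratum,
        },
    }
    for w in windows:
        frame = frames[w]
        report["windows"][w] = (
            agreement_summary(build_confusion(frame), se_method=se_method).to_dict()
            if len(frame)
            else None
        )

    if not base.empty and base["site"].notna().any():
        by_site = stratified_agreement(
            base.dropna(subset=["site"]), "site", min_n=min_stratum, se_method=se_method
        )
        report["sites"] = {
            str(site): (res.to_dict() if res is not None else {"excluded": True})
            for site, res in by_site.items()
        }

    if not cov.empty and not base.empty:
        merged = base.merge(cov, left_on="patient_id", right_on="patient_id", how="left")
        missing = merged["age"].isna().sum()
        if missing:
            logger.warning(
                "%d linked patients lack covariates; excluded from subgroups", missing
            )
            merged = merged.dropna(subset=["age"])
        for name, predicate in SUBGROUP_COLUMNS.items():
            sub = merged[predicate(merged)]
            if len(sub) < min_stratum:
                report["subgroups"][name] = {"excluded": True, "n": int(len(sub))}
                continue
            report["subgroups"][name] = agreement_summary(
                build_confusion(sub), se_method=se_method
            ).to_dict()

    # four-way source grouping at the widest window
    groups = assign_source_groups(
        dataset.patients, survey_status, linked[wmax]["patient_id"]
    )
    group_counts = groups.value_counts()
    report["source_groups"] = {
        g.value: int(group_counts.get(g, 0)) for g in SourceGroup
    }

    hf_quit_by_patient = dict(zip(match_wmax.index, match_wmax["hf_quit"]))
    quit_by_patient = {
        pid: {
            "survey_quit": survey_quit.get(pid),
            "hf_quit": hf_quit_by_patient.get(pid),
        }
        for pid in dataset.patients
    }
    report["single_source_quit"] = single_source_quit_rates(groups, quit_by_patient)

    report["availability_by_window"] = availability_by_window(
        {w: frames[w]["patient_id"] for w in windows}, frames[wmax]["patient_id"]
    )
    return report


def _window_table(report: dict) -> pd.DataFrame:
    """Flatten per-window and per-site results into one published-style table."""
    rows = []
    avail = report.get("availability_by_window", {})
    for scope, results in (("window", report["windows"]), ("site", report["sites"])):
        for key, res in results.items():
            if res is None or res.get("excluded"):
                rows.append({"scope": scope, "stratum": key, "excluded": True})
                continue
            rows.append(
                {
                    "scope": scope,
                    "stratum": key,
                    "n": res["n"],
                    "pct_available": avail.get(key) if scope == "window" else None,
                    "pct_quit_survey": res["quit_rate_survey"],
                    "pct_quit_hf": res["quit_rate_hf"],
                    "sensitivity": res["sensitivity"]["estimate"],
                    "specificity": res["specificity"]["estimate"],
                    "kappa": res["kappa"]["estimate"],
                    "kappa_ci_low": res["kappa"]["ci_low"],
                    "kappa_ci_high": res["kappa"]["ci_high"],
                    "pct_agreement": 100.0 * res["concordance"],
                    "mcnemar_p": res["mcnemar_p"],
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


def _subgroup_table(report: dict) -> pd.DataFrame:
    rows = []
    for name, res in report.get("subgroups", {}).items():
        if res.get("excluded"):
            rows.append({"subgroup": name, "excluded": True})
            continue
        rows.append(
            {
                "subgroup": name,
                "n": res["n"],
                "pct_quit_survey": res["quit_rate_survey"],
                "pct_quit_hf": res["quit_rate_hf"],
                "sensitivity": res["sensitivity"]["estimate"],
                "specificity": res["specificity"]["estimate"],
                "kappa": res["kappa"]["estimate"],
                "pct_agreement": 100.0 * res["concordance"],
                "excluded": False,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured run and write the report bundle.

    Outputs under config.outdir: report.json, agreement_by_window_site.csv,
    agreement_by_subgroup.csv, and (for simulated runs) the generated data
    plus its manifest.  Identical config and inputs give identical files.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        from .simulate import SimulationConfig, SiteProfile, generate_cohort

        sim_kwargs = dict(config.simulate)
        if "sites" in sim_kwargs:
            sim_kwargs["sites"] = tuple(
                SiteProfile(**s) for s in sim_kwargs["sites"]
            )
        sim_config = SimulationConfig(**sim_kwargs)
        dataset, _ = generate_cohort(sim_config, config.seed, outdir / "data")
    else:
        dataset = load_cohort(
            config.hf_path, config.survey_path, config.covariates_path
        )

    vocab = (
        load_vocabulary(config.vocabulary_path)
        if config.vocabulary_path
        else default_vocabulary()
    )
    report = analyze_cohort(
        dataset, vocab, windows=config.windows, min_stratum=config.min_stratum
    )
    report["metadata"]["seed"] = config.seed

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    _window_table(report).to_csv(outdir / "agreement_by_window_site.csv", index=False)
    _subgroup_table(report).to_csv(outdir / "agreement_by_subgroup.csv", index=False)
    logger.info("report written to %s", outdir)
    return report
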