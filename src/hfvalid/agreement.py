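"""Agreement and diagnostic-accuracy statistics for the 2x2 survey-vs-HF table.

The unit of analysis is the patient with both a determinate survey status
and a matched health factor.  The survey (gold standard) indexes the rows,
the HF the columns, "quit" is the positive class:

    =============  =========  ===========
                   HF quit    HF smoker
    survey quit    a          b
    survey smoker  c          d
    =============  =========  ===========

Statistics:

* percent agreement (a+d)/n;
* Cohen's kappa with the large-sample asymptotic (Fleiss-type) variance —
  the agreement-weighted form used by standard statistical software;
* sensitivity a/(a+b), specificity d/(c+d), PPV a/(a+c), NPV d/(b+d), each
  with a standard error from a first-order Taylor (delta-method) expansion
  of a ratio of multinomial count sums, since the denominators are random;
* McNemar's chi-square (b-c)^2/(b+c) without continuity correction for
  marginal homogeneity of the two quit rates.

Confidence intervals are Wald-type, estimate ± 1.96·SE, truncated to
[0, 100] on the percent scale and [-1, 1] for kappa.

A reconstruction utility recovers the 2x2 cell counts from published
marginals (n, % quit by each source, % concordant quit) by nearest-integer
rounding, which makes published agreement tables recomputable without the
raw data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .status import QuitIndicator

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateTableError(ValueError):
    """A statistic is undefined on this table (empty margin, p_e = 1...)."""


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-classification; survey is the row (gold) dimension."""

    a: int  # survey quit,   HF quit
    b: int  # survey quit,   HF smoker
    c: int  # survey smoker, HF quit
    d: int  # survey smoker, HF smoker

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def transpose(self) -> "ConfusionTable":
        return ConfusionTable(self.a, self.c, self.b, self.d)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[QuitIndicator, QuitIndicator]]
    ) -> "ConfusionTable":
        """Build from per-patient (survey, HF) quit indicators.

        Every pair must be determinate from both sources; callers restrict
        to the both-sources group first.
        """
        counts = [0, 0, 0, 0]
        npairs = 0
        for survey, hf in pairs:
            if survey is None or hf is None:
                raise ValueError("pairs must have determinate values from both sources")
            idx = (0 if survey is QuitIndicator.QUIT else 2) + (
                0 if hf is QuitIndicator.QUIT else 1
            )
            counts[idx] += 1
            npairs += 1
        if npairs == 0:
            raise DegenerateTableError("no pairs to tabulate")
        return cls(*counts)


@dataclass(frozen=True)
class EstimateCI:
    """A point estimate with Wald SE and truncated 95% CI."""

    estimate: float
    se: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    @classmethod
    def wald(
        cls, estimate: float, se: float, lo: float = -math.inf, hi: float = math.inf
    ) -> "EstimateCI":
        return cls(
            estimate,
            se,
            max(lo, estimate - Z95 * se),
            min(hi, estimate + Z95 * se),
        )


@dataclass
class AgreementResult:
    """All agreement statistics for one 2x2 table (percent scale metrics)."""

    table: ConfusionTable
    concordance: float
    kappa: EstimateCI
    sensitivity: Optional[EstimateCI]
    specificity: Optional[EstimateCI]
    ppv: Optional[EstimateCI]
    npv: Optional[EstimateCI]
    mcnemar_stat: float
    mcnemar_p: float
    quit_rate_survey: float  # percent
    quit_rate_hf: float  # percent

    def to_dict(self) -> dict:
        def ci(x: Optional[EstimateCI]) -> Optional[dict]:
            if x is None:
                return None
            return {
                "estimate": x.estimate,
                "se": x.se,
                "ci_low": x.ci_low,
                "ci_high": x.ci_high,
            }

        return {
            "n": self.table.n,
            "counts": self.table.counts,
            "concordance": self.concordance,
            "kappa": ci(self.kappa),
            "sensitivity": ci(self.sensitivity),
            "specificity": ci(self.specificity),
            "ppv": ci(self.ppv),
            "npv": ci(self.npv),
            "mcnemar_stat": self.mcnemar_stat,
            "mcnemar_p": self.mcnemar_p,
            "quit_rate_survey": self.quit_rate_survey,
            "quit_rate_hf": self.quit_rate_hf,
        }


def concordance(table: ConfusionTable) -> float:
    """Percent agreement as a proportion, (a+d)/n."""
    if table.n < 1:
        raise DegenerateTableError("concordance needs n >= 1")
    return (table.a + table.d) / table.n


def cohen_kappa(table: ConfusionTable, se_method: str = "fleiss") -> EstimateCI:
    """Cohen's kappa with an asymptotic SE and 95% CI.

    ``se_method='fleiss'`` (default) is the large-sample agreement-weighted
    variance of Fleiss, Cohen & Everitt, as implemented in standard
    software; ``'cohen'`` is the simpler p_o-based form
    sqrt(p_o(1-p_o)) / ((1-p_e) sqrt(n)).
    """
    n = table.n
    if n < 2:
        raise DegenerateTableError("kappa needs n >= 2")
    p = np.array([[table.a, table.b], [table.c, table.d]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = p[0, 0] + p[1, 1]
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateTableError("p_e = 1: both sources report a single category")
    kappa = (p_o - p_e) / (1 - p_e)
    if se_method == "cohen":
        var = p_o * (1 - p_o) / (n * (1 - p_e) ** 2)
    elif se_method == "fleiss":
        term_a = sum(
            p[i, i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(2)
        )
        term_b = (1 - kappa) ** 2 * sum(
            p[i, j] * (col[i] + row[j]) ** 2
            for i in range(2)
            for j in range(2)
            if i != j
        )
        term_c = (kappa - p_e * (1 - kappa)) ** 2
        var = (term_a + term_b - term_c) / ((1 - p_e) ** 2 * n)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return EstimateCI.wald(kappa, math.sqrt(max(var, 0.0)), lo=-1.0, hi=1.0)


def _delta_ratio_se(n: int, p_x: float, p_y: float) -> float:
    """First-order delta-method SE of X/Y for multinomial sums with X ⊆ Y.

    With X a cell count and Y a superset sum, Var(X) = n p_x (1-p_x),
    Var(Y) = n p_y (1-p_y) and Cov(X, Y) = n p_x (1-p_y), the first-order
    expansion collapses to Var(X/Y) ≈ p_x (p_y - p_x) / (n p_y^3).
    """
    if p_y <= 0:
        raise DegenerateTableError("zero denominator")
    return math.sqrt(max(p_x * (p_y - p_x), 0.0) / (n * p_y**3))


def diagnostic_metrics(table: ConfusionTable) -> dict[str, Optional[EstimateCI]]:
    """Sensitivity / specificity / PPV / NPV on the percent scale.

    Quit is the positive class and the survey is the reference standard.
    Each SE comes from the first-order delta method for a ratio of random
    multinomial sums; CIs are truncated to [0, 100].  A metric whose
    denominator is empty is reported as None.
    """
    n = table.n
    if n < 1:
        raise DegenerateTableError("metrics need n >= 1")
    a, b, c, d = (x / n for x in table.counts)
    defs = {
        "sensitivity": (a, a + b),
        "specificity": (d, c + d),
        "ppv": (a, a + c),
        "npv": (d, b + d),
    }
    out: dict[str, Optional[EstimateCI]] = {}
    for name, (p_x, p_y) in defs.items():
        if p_y == 0:
            logger.warning("%s undefined: empty denominator", name)
            out[name] = None
            continue
        est = 100.0 * p_x / p_y
        se = 100.0 * _delta_ratio_se(n, p_x, p_y)
        out[name] = EstimateCI.wald(est, se, lo=0.0, hi=100.0)
    return out


def mcnemar(table: ConfusionTable) -> tuple[float, float]:
    """McNemar chi-square for marginal homogeneity, without continuity
    correction; (stat, p).  b + c = 0 gives (0, 1) by convention."""
    b, c = table.b, table.c
    if b + c == 0:
        return 0.0, 1.0
    stat = (b - c) ** 2 / (b + c)
    return stat, float(stats.chi2.sf(stat, df=1))


def reconstruct_counts(
    n: int,
    pct_survey_quit: float,
    pct_hf_quit: float,
    pct_concordant_quit: float,
) -> ConfusionTable:
    """Recover the 2x2 cells from published marginals by nearest-integer
    rounding.

    a = round(n * %concordant), the survey-quit row total is
    round(n * %survey) and the HF-quit column total round(n * %hf); the
    remaining cells follow by subtraction.  Inconsistent marginals (a
    negative implied cell) raise.
    """
    for pct in (pct_survey_quit, pct_hf_quit, pct_concordant_quit):
        if not 0 <= pct <= 100:
            raise ValueError("percents must be in [0, 100]")
    a = round(n * pct_concordant_quit / 100)
    row1 = round(n * pct_survey_quit / 100)
    col1 = round(n * pct_hf_quit / 100)
    b = row1 - a
    c = col1 - a
    d = n - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"inconsistent marginals: implied cells ({a}, {b}, {c}, {d})"
        )
    return ConfusionTable(a, b, c, d)


def agreement_summary(table: ConfusionTable, se_method: str = "fleiss") -> AgreementResult:
    """Bundle every statistic computed on one table."""
    diag = diagnostic_metrics(table)
    stat, p = mcnemar(table)
    return AgreementResult(
        table=table,
        concordance=concordance(table),
        kappa=cohen_kappa(table, se_method=se_method),
        sensitivity=diag["sensitivity"],
        specificity=diag["specificity"],
        ppv=diag["ppv"],
        npv=diag["npv"],
        mcnemar_stat=stat,
        mcnemar_p=p,
        quit_rate_survey=100.0 * (table.a + table.b) / table.n,
        quit_rate_hf=100.0 * (table.a + table.c) / table.n,
    )


def build_confusion(frame: pd.DataFrame) -> ConfusionTable:
    """Tabulate a frame with QuitIndicator columns survey_quit / hf_quit."""
    return ConfusionTable.from_pairs(
        zip(frame["survey_quit"], frame["hf_quit"])
    )


def stratified_agreement(
    frame: pd.DataFrame,
    by: str,
    min_n: int = 30,
    se_method: str = "fleiss",
) -> dict[object, Optional[AgreementResult]]:
    """Per-stratum agreement on a both-sources analysis frame.

    ``frame`` needs survey_quit / hf_quit plus the stratum column ``by``.
    Strata smaller than ``min_n`` are flagged as excluded (None value), as
    is conventional for sites with too few linked patients.
    """
    if by not in frame.columns:
        raise KeyError(f"unknown stratum variable {by!r}")
    out: dict[object, Optional[AgreementResult]] = {}
    for stratum, sub in frame.groupby(by, sort=True):
        if len(sub) < min_n:
            logger.warning(
                "stratum %s=%r excluded: n=%d below minimum %d",
                by, stratum, len(sub), min_n,
            )
            out[stratum] = None
            continue
        out[stratum] = agreement_summary(build_confusion(sub), se_method=se_method)
    return out


def single_source_quit_rates(
    groups: pd.Series, quit_by_patient: Mapping[str, Mapping[str, object]]
) -> dict[str, Optional[dict]]:
    """Quit percentages among the survey-only and HF-only groups.

    ``groups`` maps patient_id -> SourceGroup; ``quit_by_patient`` maps
    patient_id -> {'survey_quit': QuitIndicator|None, 'hf_quit': ...}.
    Returns per-group dicts {'quit': k, 'total': m, 'percent': 100k/m},
    or None for an empty group.
    """
    from .linkage import SourceGroup  # local import avoids a cycle

    out: dict[str, Optional[dict]] = {}
    for group, key in (
        (SourceGroup.SURVEY_ONLY, "survey_quit"),
        (SourceGroup.HF_ONLY, "hf_quit"),
    ):
        ids = groups[groups == group].index
        quits = total = 0
        for pid in ids:
            val = quit_by_patient.get(pid, {}).get(key)
            if val is None:
                continue
            total += 1
            quits += val is QuitIndicator.QUIT
        if total == 0:
            logger.warning("group %s empty: quit rate undefined", group.value)
            out[group.value] = None
        else:
            out[group.value] = {
                "quit": quits,
                "total": total,
                "percent": 100.0 * quits / total,
            }
    return out


def availability_by_window(
    matched_ids_by_window: Mapping[int, Iterable[str]],
    reference_ids: Iterable[str],
) -> dict[int, float]:
    """Percent of the widest-window linked population retained per window.

    ``reference_ids`` is the both-sources population at the widest window;
    narrower windows can only lose members (nesting), so each availability
    is <= 100 and the widest window reports 100 by construction.
    """
    ref = set(reference_ids)
    if not ref:
        return {w: float("nan") for w in matched_ids_by_window}
    return {
        w: 100.0 * len(ref & set(ids)) / len(ref)
        for w, ids in matched_ids_by_window.items()
    }


def multinomial_se_oracle(
    table: ConfusionTable,
    n_reps: int = 100_000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Parametric-resampling check of the delta-method SEs.

    Resamples the table from Multinomial(n, p-hat) and reports, for each
    diagnostic metric, the resampled SD (percent scale) and the
    Monte-Carlo standard error of that SD computed from the empirical
    fourth moment.  Replicates with an empty denominator are dropped
    (vanishingly rare for the tables used here).
    """
    rng = np.random.default_rng(seed)
    n = table.n
    p = np.asarray(table.counts, dtype=float) / n
    draws = rng.multinomial(n, p, size=n_reps)
    defs = {
        "sensitivity": (draws[:, 0], draws[:, 0] + draws[:, 1]),
        "specificity": (draws[:, 3], draws[:, 2] + draws[:, 3]),
        "ppv": (draws[:, 0], draws[:, 0] + draws[:, 2]),
        "npv": (draws[:, 3], draws[:, 1] + draws[:, 3]),
    }
    out = {}
    for name, (x, y) in defs.items():
        valid = y > 0
        ratio = 100.0 * x[valid] / y[valid]
        sd = float(ratio.std(ddof=1))
        centered = ratio - ratio.mean()
        mu4 = float((centered**4).mean())
        mc_se = math.sqrt(max(mu4 - sd**4, 0.0) / (4 * sd**2 * len(ratio)))
        out[name] = {"resampled_sd": sd, "mc_se": mc_se}
    return out
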