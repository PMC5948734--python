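"""Agreement statistics: kappa, delta-method accuracy metrics, McNemar,
marginal reconstruction.  Independent oracles: closed forms computed by
hand, statsmodels, and multinomial resampling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hfvalid import (
    ConfusionTable,
    QuitIndicator,
    agreement_summary,
    cohen_kappa,
    concordance,
    diagnostic_metrics,
    mcnemar,
    reconstruct_counts,
)
from hfvalid.agreement import (
    DegenerateTableError,
    availability_by_window,
    build_confusion,
    multinomial_se_oracle,
    stratified_agreement,
)

tables = st.tuples(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
).filter(lambda t: sum(t) >= 2)


class TestConcordance:
    @pytest.mark.parametrize(
        "counts, expected",
        [((99, 83, 88, 1443), 1542 / 1713), ((10, 0, 0, 90), 1.0), ((0, 5, 5, 0), 0.0)],
    )
    def test_examples(self, counts, expected):
        assert concordance(ConfusionTable(*counts)) == pytest.approx(expected)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionTable(10, 0, 0, 90)).estimate == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # (1,9,9,81): p_o = p_e = 0.82 exactly
        assert cohen_kappa(ConfusionTable(1, 9, 9, 81)).estimate == pytest.approx(0.0)

    def test_full_sample_value_and_ci(self, full_table):
        res = cohen_kappa(full_table)
        assert res.estimate == pytest.approx(0.48066, abs=1e-4)
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.41, 0.55)

    def test_cohen_se_variant(self, full_table):
        # sqrt(p_o (1-p_o)) / ((1-p_e) sqrt(n)) computed by hand
        res = cohen_kappa(full_table, se_method="cohen")
        assert res.se == pytest.approx(0.037680, abs=1e-5)

    def test_degenerate_single_category(self):
        with pytest.raises(DegenerateTableError):
            cohen_kappa(ConfusionTable(0, 0, 0, 50))

    @given(tables)
    def test_matches_statsmodels(self, counts):
        """Estimate and Fleiss-type SE agree with the independent
        statsmodels implementation on arbitrary non-degenerate tables."""
        from statsmodels.stats.inter_rater import cohens_kappa

        a, b, c, d = counts
        table = ConfusionTable(a, b, c, d)
        arr = np.array([[a, b], [c, d]], dtype=float)
        row, col = arr.sum(1), arr.sum(0)
        p_e = (row @ col) / arr.sum() ** 2
        if p_e >= 1 - 1e-12:
            return
        ours = cohen_kappa(table)
        ref = cohens_kappa(arr)
        assert ours.estimate == pytest.approx(ref.kappa, abs=1e-10)
        assert ours.se == pytest.approx(ref.std_kappa, abs=1e-10)

    @given(tables)
    def test_kappa_one_iff_no_discordance(self, counts):
        a, b, c, d = counts
        if a == 0 or d == 0:
            return
        table = ConfusionTable(a, b, c, d)
        kappa = cohen_kappa(table).estimate
        if b == 0 and c == 0:
            assert kappa == pytest.approx(1.0)
        else:
            assert kappa < 1.0


class TestDiagnosticMetrics:
    def test_full_sample_estimates(self, full_table):
        res = diagnostic_metrics(full_table)
        assert res["sensitivity"].estimate == pytest.approx(100 * 99 / 182, abs=1e-9)
        assert round(res["sensitivity"].estimate, 1) == 54.4
        assert round(res["specificity"].estimate, 1) == 94.3
        assert round(res["ppv"].estimate, 1) == 52.9
        assert round(res["npv"].estimate, 1) == 94.6

    def test_narrow_window_row(self):
        res = diagnostic_metrics(ConfusionTable(25, 26, 24, 473))
        assert round(res["sensitivity"].estimate, 1) == 49.0

    def test_degenerate_perfect_sensitivity(self):
        res = diagnostic_metrics(ConfusionTable(10, 0, 0, 90))
        assert res["sensitivity"].estimate == 100.0
        assert res["sensitivity"].se == 0.0

    def test_zero_denominator_reported_undefined(self):
        res = diagnostic_metrics(ConfusionTable(0, 0, 5, 95))
        assert res["sensitivity"] is None
        assert res["specificity"] is not None

    def test_ci_truncated_to_percent_scale(self):
        res = diagnostic_metrics(ConfusionTable(1, 1, 1, 97))
        for metric in res.values():
            assert 0.0 <= metric.ci_low <= metric.ci_high <= 100.0

    @given(tables)
    def test_concordance_identity(self, counts):
        """(a+d)/n == sens*prev + spec*(1-prev) with prev = (a+b)/n, exactly."""
        a, b, c, d = counts
        if a + b == 0 or c + d == 0:
            return
        table = ConfusionTable(a, b, c, d)
        res = diagnostic_metrics(table)
        prev = (a + b) / table.n
        combined = (
            res["sensitivity"].estimate / 100 * prev
            + res["specificity"].estimate / 100 * (1 - prev)
        )
        assert concordance(table) == pytest.approx(combined, abs=1e-12)

    @given(tables)
    def test_transpose_swaps_sens_ppv_and_preserves_kappa(self, counts):
        a, b, c, d = counts
        table = ConfusionTable(a, b, c, d)
        transposed = table.transpose()
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        ours, swapped = diagnostic_metrics(table), diagnostic_metrics(transposed)
        assert ours["sensitivity"].estimate == pytest.approx(swapped["ppv"].estimate)
        assert ours["specificity"].estimate == pytest.approx(swapped["npv"].estimate)
        arr = np.array([[a, b], [c, d]], float)
        p_e = (arr.sum(1) @ arr.sum(0)) / arr.sum() ** 2
        if p_e < 1 - 1e-12:
            assert cohen_kappa(table).estimate == pytest.approx(
                cohen_kappa(transposed).estimate, abs=1e-12
            )

    def test_delta_se_close_to_resampling(self, full_table):
        """Quick version of the resampling cross-check (small rep count)."""
        oracle = multinomial_se_oracle(full_table, n_reps=20_000, seed=0)
        res = diagnostic_metrics(full_table)
        for name, check in oracle.items():
            delta = res[name].se
            assert abs(delta - check["resampled_sd"]) <= 3 * check["mc_se"]


class TestMcNemar:
    def test_symmetric_discordance_is_zero(self):
        stat, p = mcnemar(ConfusionTable(5, 40, 40, 5))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_full_sample_closed_form(self, full_table):
        stat, _ = mcnemar(full_table)
        assert stat == pytest.approx(25 / 171)

    def test_one_sided_discordance(self):
        stat, _ = mcnemar(ConfusionTable(0, 10, 0, 0))
        assert stat == pytest.approx(10.0)

    def test_no_discordance_convention(self):
        assert mcnemar(ConfusionTable(10, 0, 0, 10)) == (0.0, 1.0)

    @given(tables)
    def test_matches_statsmodels(self, counts):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        a, b, c, d = counts
        if b + c == 0:
            return
        stat, p = mcnemar(ConfusionTable(a, b, c, d))
        ref = sm_mcnemar(np.array([[a, b], [c, d]]), exact=False, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestReconstruction:
    @pytest.mark.parametrize(
        "marginals, expected",
        [
            ((1713, 10.6, 10.9, 5.8), (99, 83, 88, 1443)),
            ((1357, 10.6, 10.8, 5.6), (76, 68, 71, 1142)),
            ((548, 9.3, 8.9, 4.6), (25, 26, 24, 473)),
            ((100, 10.0, 10.0, 10.0), (10, 0, 0, 90)),
        ],
    )
    def test_published_rows(self, marginals, expected):
        assert reconstruct_counts(*marginals).counts == expected

    def test_inconsistent_marginals_raise(self):
        with pytest.raises(ValueError, match="inconsistent"):
            reconstruct_counts(100, 5.0, 5.0, 20.0)

    @pytest.mark.parametrize(
        "marginals",
        [
            (1713, 10.6, 10.9, 5.8),
            (1357, 10.6, 10.8, 5.6),
            (548, 9.3, 8.9, 4.6),
            (620, 11.9, 10.7, 5.2),
            (492, 9.6, 13.8, 7.3),
            (579, 10.2, 8.8, 5.0),
        ],
    )
    def test_marginal_round_trip_to_printed_precision(self, marginals):
        """Recomputing the three input percents from the reconstructed
        table reproduces them to within one unit in the printed decimal.
        (Exact equality after rounding is impossible for one published
        marginal — 10.7% of 620 has no integer preimage — so the check
        allows the half-unit boundary slop of the source's own rounding.)"""
        n, ps, ph, pc = marginals
        table = reconstruct_counts(n, ps, ph, pc)
        assert abs(100 * (table.a + table.b) / n - ps) <= 0.1
        assert abs(100 * (table.a + table.c) / n - ph) <= 0.1
        assert abs(100 * table.a / n - pc) <= 0.1


class TestTabulation:
    def test_from_pairs(self):
        table = ConfusionTable.from_pairs(
            [
                (QuitIndicator.QUIT, QuitIndicator.QUIT),
                (QuitIndicator.SMOKER, QuitIndicator.SMOKER),
            ]
        )
        assert table.counts == (1, 0, 0, 1)

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError, match="determinate"):
            ConfusionTable.from_pairs([(QuitIndicator.QUIT, None)])

    def test_empty_rejected(self):
        with pytest.raises(DegenerateTableError):
            ConfusionTable.from_pairs([])


class TestStratified:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "survey_quit", "hf_quit", "site"])

    def test_pooled_equals_overall(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            rows.append(
                (
                    f"p{i}",
                    QuitIndicator.QUIT if rng.random() < 0.2 else QuitIndicator.SMOKER,
                    QuitIndicator.QUIT if rng.random() < 0.2 else QuitIndicator.SMOKER,
                    "A" if i % 2 else "B",
                )
            )
        frame = self._frame(rows)
        by_site = stratified_agreement(frame, "site", min_n=10)
        pooled = np.zeros(4, dtype=int)
        for res in by_site.values():
            pooled += np.array(res.table.counts)
        assert tuple(pooled) == build_confusion(frame).counts

    def test_small_stratum_excluded(self):
        rows = [
            (
                f"p{i}",
                QuitIndicator.QUIT if i % 5 == 0 else QuitIndicator.SMOKER,
                QuitIndicator.QUIT if i % 4 == 0 else QuitIndicator.SMOKER,
                "A" if i < 40 else "C",
            )
            for i in range(62)
        ]
        frame = self._frame(rows)
        out = stratified_agreement(frame, "site", min_n=30)
        assert out["C"] is None  # n=22 stratum flagged, not analyzed
        assert out["A"] is not None

    def test_unknown_stratum_fatal(self):
        with pytest.raises(KeyError):
            stratified_agreement(self._frame([]), "arm")


def test_availability_nesting():
    avail = availability_by_window(
        {120: ["p1", "p2", "p3"], 90: ["p1", "p2"], 30: ["p1"]},
        reference_ids=["p1", "p2", "p3"],
    )
    assert avail[120] == 100.0
    assert avail[120] >= avail[90] >= avail[30]
    assert avail[30] == pytest.approx(100 / 3)
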