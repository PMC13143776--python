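"""Composite scoring, ROC cutoff, survival and contingency machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nelfyap import clinical as cl
from nelfyap import synthdata
from nelfyap.clinical import (
    SurvivalGrouping,
    chi2_contingency,
    composite_score,
    km_at,
    km_curve,
    logrank_test,
    median_split,
    percent_bin,
    roc_cutoff,
    stratify,
)


class TestCompositeScore:
    @pytest.mark.parametrize(
        "percent,intensity,score",
        [(75, 3, 9), (0, 3, 0), (10, 2, 2), (11, 2, 4), (50, 1, 2), (51, 1, 3), (5, 0, 0)],
    )
    def test_binning_and_product(self, percent, intensity, score):
        assert composite_score(percent, intensity) == score

    def test_bin_boundaries_as_printed(self):
        assert percent_bin(10) == 1 and percent_bin(11) == 2
        assert percent_bin(0) == 0 and percent_bin(100) == 3

    def test_range_is_exactly_products_of_bins(self):
        observed = {
            composite_score(p, i)
            for p in (0, 5, 30, 80)
            for i in (0, 1, 2, 3)
        }
        assert observed == {b * i for b in range(4) for i in range(4)}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            composite_score(120, 2)
        with pytest.raises(ValueError):
            composite_score(50, 4)


class TestRocCutoff:
    def test_perfect_separation_returns_smallest_midpoint(self):
        scores = [1, 2, 8, 9]
        outcome = [0, 0, 1, 1]
        cut, sens, spec = roc_cutoff(scores, outcome)
        assert cut == pytest.approx(5.0)  # midpoint between 2 and 8
        assert sens == 1.0 and spec == 1.0

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="ROC undefined"):
            roc_cutoff([3, 3, 3, 3], [0, 1, 0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            roc_cutoff([1, 2, 3], [1, 1, 1])

    def test_matches_exhaustive_threshold_search(self):
        rng = np.random.default_rng(51)
        for _ in range(10):
            scores = rng.integers(0, 10, 40).astype(float)
            outcome = rng.integers(0, 2, 40)
            if len(np.unique(outcome)) < 2 or len(np.unique(scores)) < 2:
                continue
            cut, sens, spec = roc_cutoff(scores, outcome)
            # oracle: per-candidate confusion-matrix counting over every
            # midpoint between distinct observed scores
            distinct = sorted(set(scores))
            best_j, best_c = None, None
            for lo, hi in zip(distinct, distinct[1:]):
                c = (lo + hi) / 2
                tp = sum(1 for s, y in zip(scores, outcome) if s >= c and y == 1)
                fn = sum(1 for s, y in zip(scores, outcome) if s < c and y == 1)
                tn = sum(1 for s, y in zip(scores, outcome) if s < c and y == 0)
                fp = sum(1 for s, y in zip(scores, outcome) if s >= c and y == 0)
                j = tp / (tp + fn) + tn / (tn + fp) - 1
                if best_j is None or j > best_j + 1e-12:
                    best_j, best_c = j, c
            assert cut == pytest.approx(best_c, abs=1e-12)
            assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)


class TestMedianSplit:
    def test_even_split(self):
        cut, labels = median_split(list(range(1, 11)))
        assert cut == 5.5
        assert labels.count("high") == 5 and labels.count("low") == 5

    def test_value_at_median_labeled_low(self):
        cut, labels = median_split([1, 2, 3, 4, 5])
        assert cut == 3 and labels[2] == "low"

    @given(st.lists(st.integers(0, 100), min_size=6, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_monotone_transform(self, values):
        # integer scores and an exact affine map keep float comparisons exact
        if len(set(values)) < 2:
            return
        _, labels = median_split([float(v) for v in values])
        _, labels2 = median_split([2.0 * v + 1.0 for v in values])
        assert labels == labels2

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([2.0] * 8)


def _grouping(times, events, groups):
    return SurvivalGrouping(
        pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(len(times))],
                "group": groups,
                "time": times,
                "event": events,
            }
        )
    )


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        g = _grouping([5, 10, 15], [0, 0, 0], ["A"] * 3)
        km = km_curve(g, "A")
        assert np.allclose(km["survival"], 1.0)

    def test_single_event_drops_to_zero(self):
        g = _grouping([5.0], [1], ["A"])
        assert km_at(g, "A", 5.0) == 0.0
        assert km_at(g, "A", 4.9) == 1.0

    def test_exponential_cohort_matches_closed_form_at_median(self):
        lam = 0.02
        recs, _ = synthdata.simulate_cohort(
            n=200,
            group_hazards={k: lam for k in synthdata.DEFAULT_GROUP_HAZARDS},
            seed=3,
        )
        g = _grouping(
            [r.os_months for r in recs], [r.os_event for r in recs], ["all"] * len(recs)
        )
        assert km_at(g, "all", np.log(2) / lam) == pytest.approx(0.5, abs=0.08)


class TestLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        g = _grouping([5, 8, 12] * 2, [1, 0, 1] * 2, ["A"] * 3 + ["B"] * 3)
        stat, df, p = logrank_test(g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_four_groups_have_df_three(self):
        rng = np.random.default_rng(1)
        g = _grouping(
            rng.exponential(20, 40), rng.integers(0, 2, 40), list("ABCD") * 10
        )
        _, df, _ = logrank_test(g)
        assert df == 3

    def test_no_events_rejected(self):
        g = _grouping([5, 8], [0, 0], ["A", "B"])
        with pytest.raises(ValueError, match="no events"):
            logrank_test(g)

    def test_matches_hand_rolled_mantel_cox(self):
        """Two-group statistic equals the textbook observed-vs-expected sum
        with hypergeometric variance, computed independently here."""
        rng = np.random.default_rng(8)
        times = np.round(rng.exponential(20, 60), 1)
        events = rng.integers(0, 2, 60)
        groups = np.array(["A"] * 30 + ["B"] * 30)
        g = _grouping(times, events, groups)
        stat, _, p = logrank_test(g)

        o_minus_e, var = 0.0, 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & (groups == "A")).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (groups == "A")).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e**2 / var
        assert stat == pytest.approx(expected_stat, rel=1e-6)
        assert p == pytest.approx(stats.chi2.sf(expected_stat, 1), rel=1e-6)


class TestContingency:
    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            r, c = rng.integers(2, 5, 2)
            table = rng.integers(1, 40, (r, c))
            res = chi2_contingency(table)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            stat = ((table - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.df == (r - 1) * (c - 1)
            assert res.p == pytest.approx(stats.chi2.sf(stat, res.df), abs=1e-12)

    def test_proportional_rows_independent(self):
        res = chi2_contingency([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="zero marginal"):
            chi2_contingency([[0, 0], [5, 3]])


class TestStratify:
    def _records(self, n=80, seed=21):
        recs, truth = synthdata.simulate_cohort(n=n, seed=seed)
        return recs, truth

    def test_joint_groups_partition_cohort(self):
        recs, _ = self._records()
        g = stratify(recs, mode="joint", cutoffs={"YAP": 4, "NELFA": 4})
        assert len(g.table) == len(recs)
        assert set(g.table["group"]) <= set(cl.JOINT_GROUPS)

    def test_high_high_patient_assigned_correctly(self):
        recs, _ = self._records()
        scores = cl.marker_scores(recs)
        g = stratify(recs, mode="joint", cutoffs={"YAP": 4, "NELFA": 4})
        labels = g.table.set_index("patient_id")["group"]
        both_high = scores[(scores["yap_score"] >= 4) & (scores["nelfa_score"] >= 4)]
        assert (labels[both_high.index] == "HighYAP_HighNELFA").all()

    def test_single_marker_mode(self):
        recs, _ = self._records()
        g = stratify(recs, mode="single_marker", marker="NELFA", cutoffs={"NELFA": 4})
        assert set(g.table["group"]) <= {"high", "low"}

    def test_missing_cutoff_rejected(self):
        recs, _ = self._records(n=20)
        with pytest.raises(ValueError):
            stratify(recs, mode="joint", cutoffs={"YAP": 4})

    def test_km_ordering_tracks_planted_hazards(self):
        """Group-level 36-month survival follows the planted hazard ordering
        in most cohorts at n=200."""
        hz = synthdata.DEFAULT_GROUP_HAZARDS
        wins = 0
        for seed in range(10):
            recs, truth = synthdata.simulate_cohort(n=200, seed=100 + seed)
            g = SurvivalGrouping(
                pd.DataFrame(
                    {
                        "patient_id": truth["patient_id"],
                        "group": truth["risk_group"],
                        "time": [r.os_months for r in recs],
                        "event": [r.os_event for r in recs],
                    }
                )
            )
            surv = {grp: km_at(g, grp, 36.0) for grp in g.groups()}
            order = sorted(surv, key=surv.get)  # worst survival first
            expected = sorted(hz, key=hz.get, reverse=True)
            wins += order[0] == expected[0] and order[-1] == expected[-1]
        assert wins >= 9
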