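"""Evaluation statistics against independent brute-force oracles."""
import datetime as dt
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biphasic.core import (
    CycleRecord,
    FailureReason,
    Method,
    OvulationEstimate,
    ReferenceOvulation,
)
from biphasic.evaluate import (
    MethodEvaluation,
    bonferroni,
    cliff_delta,
    detection_rate_ci,
    fisher_detection_test,
    fold_change,
    mae_sem,
    mann_whitney_test,
    subgroup_labels,
    within_k,
)

from conftest import day


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


def u_delta_oracle(a, b):
    """Brute-force cross-pair counts: (U for a, Cliff's delta)."""
    gt = sum(1 for x in a for y in b if x > y)
    lt = sum(1 for x in a for y in b if x < y)
    ties = len(a) * len(b) - gt - lt
    return gt + ties / 2, (lt - gt) / (len(a) * len(b))


class TestProportions:
    def test_detection_rate_ci_closed_form(self):
        rate, lo, hi = detection_rate_ci(5, 10)
        half = 1.96 * np.sqrt(0.25 / 10) * 100
        assert rate == 50.0
        assert lo == pytest.approx(50 - half)
        assert hi == pytest.approx(50 + half)

    def test_ci_clipped_at_zero(self):
        rate, lo, hi = detection_rate_ci(0, 10)
        assert (rate, lo) == (0.0, 0.0)

    def test_invalid_total_raises(self):
        with pytest.raises(ValueError):
            detection_rate_ci(0, 0)

    def test_within_k_counts_undetected_in_denominator(self):
        errors = [0.0, 1.0, -2.0, 3.0, np.nan]  # one undetected cycle
        assert within_k(errors, 2) == pytest.approx(100 * 3 / 5)
        assert within_k([], 2, n_total=10) == 0.0


class TestMaeSem:
    def test_hand_arithmetic(self):
        mae, sem = mae_sem([1, -1, 0, 2])
        assert mae == pytest.approx(1.0)
        abs_errs = np.array([1.0, 1.0, 0.0, 2.0])
        assert sem == pytest.approx(abs_errs.std(ddof=1) / 2)

    def test_degenerate_cases(self):
        assert mae_sem([0, 0, 0]) == (0.0, 0.0)
        assert mae_sem([-3]) == (3.0, 0.0)
        with pytest.raises(ValueError):
            mae_sem([])


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(3.44, 1.26, 2.7), (6.63, 2.51, 2.6), (6.63, 1.48, 4.5), (2.0, 2.0, 1.0)]
    )
    def test_ratios(self, a, b, expected):
        assert fold_change(a, b) == expected

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestFisher:
    def test_identical_degenerate_groups(self):
        res = fisher_detection_test(10, 0, 10, 0)
        assert res.statistic == 1.0 and res.p_raw == 1.0

    def test_p_matches_enumeration(self):
        res = fisher_detection_test(8, 2, 2, 8)
        assert res.p_raw == pytest.approx(fisher_oracle(8, 2, 2, 8), rel=1e-9)

    def test_reconstructed_cohort_odds_ratio(self):
        # counts rebuilt from rounded subgroup percentages; the printed
        # odds ratio (3.56) is only approximately recoverable
        res = fisher_detection_test(649, 13, 164, 12, m_comparisons=3)
        assert res.statistic == pytest.approx(3.56, abs=0.15)
        assert res.p_bonferroni == pytest.approx(min(1, 3 * res.p_raw))

    def test_zero_cell_gives_one_sided_ci(self):
        res = fisher_detection_test(10, 0, 5, 5)
        assert np.isinf(res.statistic) or res.statistic > 1
        assert res.ci_95[1] == np.inf


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney_test([1, 2, 3], [1, 2, 3])
        assert res.cliff_delta == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_complete_separation(self):
        res = mann_whitney_test([0, 0], [5, 5])
        assert res.cliff_delta == 1.0

    def test_u_and_delta_match_pair_counting(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 6, 8).astype(float)
        b = rng.integers(0, 6, 8).astype(float)
        u_oracle, d_oracle = u_delta_oracle(np.abs(a), np.abs(b))
        res = mann_whitney_test(a, b)
        assert res.statistic == pytest.approx(u_oracle)
        assert res.cliff_delta == pytest.approx(d_oracle)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=10),
        st.lists(st.integers(0, 8), min_size=1, max_size=10),
    )
    @settings(max_examples=150, derandomize=True)
    def test_u_delta_identity(self, a, b):
        # delta = 2*U_a/(n_a n_b) - 1 with U_a counting pairs favoring a
        res = mann_whitney_test(a, b)
        n = len(a) * len(b)
        u_a = n - res.statistic  # scipy's U counts pairs a > b (+ half ties)
        assert res.cliff_delta == pytest.approx(2 * u_a / n - 1)


class TestBonferroni:
    @given(st.floats(1e-12, 1.0), st.integers(1, 10))
    @settings(max_examples=100, derandomize=True)
    def test_never_decreases_and_caps_at_one(self, p, m):
        adj = bonferroni(p, m)
        assert adj >= p and adj <= 1.0


def _fake_results(n_users=30, seed=0):
    """Hand-built estimates/references with known per-cycle errors."""
    rng = np.random.default_rng(seed)
    estimates, references = [], {}
    cycles = []
    for i in range(n_users):
        length = int(rng.integers(24, 38))
        start = day(1 + 40 * i)
        c = CycleRecord("u%03d" % i, start, period_end=start + dt.timedelta(days=4),
                        next_period_start=start + dt.timedelta(days=length),
                        age_years=int(rng.integers(18, 50)))
        cycles.append(c)
        ov = start + dt.timedelta(days=int(length - 12) - 1)
        references[c.cycle_id] = ReferenceOvulation(c, ov - dt.timedelta(days=1))
        for method, spread in ((Method.PHYSIOLOGY, 1), (Method.CALENDAR, 3)):
            if rng.random() < 0.1:
                estimates.append(OvulationEstimate(
                    c, method, False, None, FailureReason.INSUFFICIENT_DATA))
            else:
                err = int(rng.integers(-spread, spread + 1))
                estimates.append(OvulationEstimate(
                    c, method, True, ov + dt.timedelta(days=err)))
    return estimates, references


class TestReport:
    def test_subgroup_counts_conserved(self):
        estimates, references = _fake_results()
        report = MethodEvaluation(estimates, references).fit()
        for table in (report.by_length, report.by_age):
            per_method = table["n"].groupby(level="method").sum()
            for m, total in per_method.items():
                assert total == report.overall.loc[m, "n"]

    def test_overall_consistent_with_per_cycle_errors(self):
        estimates, references = _fake_results(seed=3)
        report = MethodEvaluation(estimates, references).fit()
        phys = [e for e in estimates if e.method is Method.PHYSIOLOGY]
        detected = [e for e in phys if e.detected]
        errs = [
            (e.estimated_date - references[e.cycle.cycle_id].reference_date).days
            for e in detected
        ]
        assert report.overall.loc["physiology", "n"] == len(phys)
        assert report.overall.loc["physiology", "n_detected"] == len(detected)
        assert report.overall.loc["physiology", "mae"] == pytest.approx(
            np.abs(errs).mean()
        )

    def test_single_length_class_populates_one_row(self):
        # all cycles length 28: only the medium row carries counts
        estimates, references = [], {}
        for i in range(6):
            start = day(1 + 40 * i)
            c = CycleRecord(f"u{i}", start, period_end=start + dt.timedelta(days=4),
                            next_period_start=start + dt.timedelta(days=28),
                            age_years=30)
            ov = start + dt.timedelta(days=15)
            references[c.cycle_id] = ReferenceOvulation(c, ov - dt.timedelta(days=1))
            estimates.append(OvulationEstimate(c, Method.PHYSIOLOGY, True, ov))
        report = MethodEvaluation(estimates, references).fit()
        lengths = report.by_length["n"].groupby(level="length_class").sum()
        assert lengths["medium"] == 6
        assert lengths.drop("medium").sum() == 0

    def test_summary_renders(self):
        estimates, references = _fake_results(n_users=12, seed=5)
        text = MethodEvaluation(estimates, references).fit().summary()
        assert "Overall" in text and "By cycle length" in text

    def test_variability_labels_from_trailing_cycles(self):
        # three consecutive 28/33/28-day cycles: the fourth cycle sees
        # diffs 5,5 -> moderately irregular
        starts = [day(1), day(29), day(62), day(90)]
        cycles = [
            CycleRecord("u", s, period_end=s + dt.timedelta(days=4),
                        next_period_start=e, age_years=30)
            for s, e in zip(starts, starts[1:] + [day(118)])
        ]
        labels = subgroup_labels(cycles)
        assert labels[cycles[3].cycle_id].variability_class.value == "moderately_irregular"
        assert labels[cycles[0].cycle_id].variability_class.value == "unknown"
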