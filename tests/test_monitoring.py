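"""Statistical monitoring: rank tests, CIs, classification, grids, timelines."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dvhregistry.monitoring import (
    CATEGORIES,
    ComparisonGrid,
    EndpointTestResult,
    agreement_fraction,
    classify_change,
    compare_cohorts,
    compare_plan_cohorts,
    distribution_summary,
    mann_whitney_u,
    mean_diff_ci,
    percent_change_of_median,
    population_mean_dvh,
    render_report,
    timeline,
)
from dvhregistry.registry import ENDPOINTS, Registry
from dvhregistry.synthgen import StudyConfig, generate_cohorts


# ---------------------------------------------------------------------------
# Independent enumeration oracle for the exact Mann-Whitney p-value
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def enumerated_u_distribution(n1, n2):
    """All C(n1+n2, n1) rank assignments, via explicit itertools enumeration."""
    n = n1 + n2
    counts = {}
    for ranks in itertools.combinations(range(1, n + 1), n1):
        u1 = sum(ranks) - n1 * (n1 + 1) // 2
        counts[u1] = counts.get(u1, 0) + 1
    total = sum(counts.values())
    return counts, total


def oracle_exact_p(x, y):
    """Two-tailed exact p by brute-force enumeration of rank assignments."""
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u = min(u1, n1 * n2 - u1)
    counts, total = enumerated_u_distribution(n1, n2)
    p = 2 * sum(c for uu, c in counts.items() if uu <= u + 1e-9) / total
    return min(1.0, p)


class TestMannWhitney:
    def test_extreme_separation_small_samples(self):
        """{1,2,3} vs {10,11,12}: U = 0 and exact two-tailed p = 2/20 = 0.1."""
        u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_are_non_significant(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)
        assert p >= 0.05

    def test_fully_tied_samples_give_p_one(self):
        _, p = mann_whitney_u([5.0] * 4, [5.0] * 3)
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 2), (3, 3), (4, 3), (4, 4), (5, 4)])
    def test_exact_p_equals_enumeration_for_random_samples(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(30):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(oracle_exact_p(list(x), list(y)), abs=1e-12)

    def test_exact_p_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.3, 1.5, 5)
            _, p = mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_data_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.integers(0, 5, 8).astype(float)
            y = rng.integers(0, 5, 7).astype(float)
            if len(set(np.concatenate([x, y]))) == 15:
                continue
            _, p = mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_and_approximate_agree_at_moderate_n(self):
        """At the 10 vs 9 study scale the corrected normal approximation
        tracks the exact enumeration closely."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.4, 1, 9)
            _, p_exact = mann_whitney_u(x, y, exact_limit=20)
            _, p_approx = mann_whitney_u(x, y, exact_limit=0)
            assert p_approx == pytest.approx(p_exact, abs=0.02)


class TestMeanDiffCi:
    def test_identical_samples_centered_on_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        diff, lo, hi = mean_diff_ci(x, x)
        assert diff == 0.0
        assert lo == pytest.approx(-hi)
        assert lo < 0 < hi

    def test_zero_variance_degenerate_interval(self):
        diff, lo, hi = mean_diff_ci([0.0] * 4, [1.0] * 4)
        assert (diff, lo, hi) == (1.0, 1.0, 1.0)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            mean_diff_ci([1.0], [1.0, 2.0])

    def test_welch_interval_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(0, 1, 10)
            y = rng.normal(1, 2, 9)
            diff, lo, hi = mean_diff_ci(x, y)
            res = stats.ttest_ind(y, x, equal_var=False)
            ref = res.confidence_interval(0.95)
            assert diff == pytest.approx(y.mean() - x.mean())
            assert lo == pytest.approx(ref.low)
            assert hi == pytest.approx(ref.high)

    def test_pooled_interval_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 6)
        _, lo, hi = mean_diff_ci(x, y, pooled=True)
        ref = stats.ttest_ind(y, x, equal_var=True).confidence_interval(0.95)
        assert lo == pytest.approx(ref.low)
        assert hi == pytest.approx(ref.high)


class TestDistributionSummary:
    def test_order_statistic_interpolation_quartiles(self):
        s = distribution_summary([1, 2, 3, 4])
        assert s.median == pytest.approx(2.5)
        assert s.q1 == pytest.approx(1.75)
        assert s.q3 == pytest.approx(3.25)
        assert s.iqr == pytest.approx(1.5)

    def test_symmetric_sample(self):
        s = distribution_summary([1, 2, 3])
        assert s.mean == s.median == 2.0

    def test_constant_sample_degenerate(self):
        s = distribution_summary([7.0, 7.0, 7.0])
        assert s.iqr == 0.0 and s.sd == 0.0
        assert s.ci95_low == s.ci95_high == 7.0

    def test_ci_contains_mean(self):
        rng = np.random.default_rng(6)
        s = distribution_summary(rng.normal(10, 2, 15))
        assert s.ci95_low <= s.mean <= s.ci95_high
        assert s.q1 <= s.median <= s.q3

    def test_single_observation_spread_undefined(self):
        s = distribution_summary([3.0])
        assert math.isnan(s.sd) and math.isnan(s.ci95_low)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            distribution_summary([])


class TestClassifyChange:
    @pytest.mark.parametrize(
        "p,diff,expected",
        [
            (0.01, -2.0, "significant_reduction"),
            (0.30, -1.0, "nonsignificant_reduction"),
            (0.30, 0.0, "no_change"),
            (0.001, 0.0, "no_change"),
            (0.30, 1.0, "nonsignificant_increase"),
            (0.01, 2.0, "significant_increase"),
        ],
    )
    def test_category_table(self, p, diff, expected):
        assert classify_change(p, diff) == expected

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=-50, max_value=50, allow_nan=False),
    )
    def test_partition_is_total_over_five_categories(self, p, diff):
        assert classify_change(p, diff) in CATEGORIES

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            classify_change(0.5, 1.0, alpha=1.5)


class TestComparisonGrid:
    def test_ten_organs_times_eight_endpoints(self, study_registry, all_organs):
        grid = compare_cohorts(
            study_registry, "preconstraints", "postconstraints", all_organs
        )
        assert grid.n_evaluations == 80
        assert len(grid.organs) == 10 and len(grid.endpoints) == 8

    def test_one_organ_gives_eight_evaluations(self, study_registry):
        grid = compare_cohorts(
            study_registry, "preconstraints", "postconstraints", ("heart",)
        )
        assert grid.n_evaluations == 8

    def test_missing_organ_excluded_and_reported(self, study_registry):
        grid = compare_cohorts(
            study_registry, "preconstraints", "postconstraints", ("heart", "spleen")
        )
        assert grid.missing_organs == ("spleen",)
        assert grid.n_evaluations == 8

    def test_identical_cohorts_never_significant(self, study_registry):
        grid = compare_cohorts(
            study_registry, "preconstraints", "preconstraints", ("heart", "liver")
        )
        for r in grid.results:
            assert r.p_value >= 0.9
            assert r.category in ("no_change", *[c for c in CATEGORIES if "nonsig" in c])

    def test_injected_reduction_detected(self, study_plans):
        """A halved-d50 post cohort must flag the shifted organ as a
        significant reduction on Dmean while matching cells stay calm."""
        config = StudyConfig(seed=77).with_effects({"liver": 0.5})
        pre, post = generate_cohorts(config)
        grid = compare_plan_cohorts(pre, post, ("liver",), ("d_mean",))
        assert grid.cell("liver", "d_mean").category == "significant_reduction"


def make_cell(organ, ep, p, ci_lo, ci_hi, diff=-1.0):
    return EndpointTestResult(
        organ=organ,
        endpoint=ep,
        n_pre=10,
        n_post=9,
        u_statistic=10.0,
        p_value=p,
        mean_diff=diff,
        ci95_low=ci_lo,
        ci95_high=ci_hi,
        direction="reduction",
        category=classify_change(p, diff),
    )


class TestAgreement:
    def test_all_agreeing_cells(self):
        cells = [make_cell("heart", ep, 0.01, -2.0, -0.5) for ep in ENDPOINTS]
        grid = ComparisonGrid(tuple(cells), 0.05, ("heart",), ENDPOINTS)
        n_agree, n_total, fraction, disagreements = agreement_fraction(grid)
        assert (n_agree, n_total, fraction) == (8, 8, 1.0)
        assert disagreements == []

    def test_constructed_75_of_80_grid(self, all_organs):
        """Five cells where the rank test rejects but the CI covers zero:
        75/80 agreement, i.e. 93.75 %, displayed as 94 %."""
        cells = []
        n_disagree = 0
        for organ in all_organs:
            for ep in ENDPOINTS:
                if n_disagree < 5 and ep == "v10":
                    cells.append(make_cell(organ, ep, 0.01, -2.0, 0.5))
                    n_disagree += 1
                else:
                    cells.append(make_cell(organ, ep, 0.01, -2.0, -0.5))
        grid = ComparisonGrid(tuple(cells), 0.05, all_organs, ENDPOINTS)
        n_agree, n_total, fraction, disagreements = agreement_fraction(grid)
        assert (n_agree, n_total) == (75, 80)
        assert fraction == pytest.approx(0.9375)
        assert f"{100 * fraction:.0f}%" == "94%"
        assert len(disagreements) == 5

    def test_empty_grid_rejected(self):
        grid = ComparisonGrid((), 0.05, (), ENDPOINTS)
        with pytest.raises(ValueError):
            agreement_fraction(grid)


class TestPercentChangeOfMedian:
    def test_halving_is_fifty_percent_reduction(self):
        assert percent_change_of_median([10.0] * 3, [5.0] * 3) == pytest.approx(50.0)

    def test_identity_is_zero(self):
        assert percent_change_of_median([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_increase_is_negative(self):
        assert percent_change_of_median([10.0] * 3, [12.0] * 3) == pytest.approx(-20.0)

    def test_zero_pre_median_rejected(self):
        with pytest.raises(ValueError):
            percent_change_of_median([0.0, 0.0], [1.0, 1.0])


class TestPopulationMeanDvh:
    def test_single_plan_mean_is_the_plan(self, study_registry):
        reg = study_registry
        serial = reg.get_cohort("preconstraints").serials[0]
        reg.define_cohort("solo", [serial])
        grid = np.arange(0, 30, 0.5)
        mdvh = population_mean_dvh(reg, "solo", "heart", grid)
        from dvhregistry.dvh_core import v_at_dose

        plan = reg.load_plan(serial)
        expected = [v_at_dose(plan.dvhs["heart"], float(d)) for d in grid]
        assert mdvh.n == 1
        np.testing.assert_allclose(mdvh.mean_rel_volume, expected)
        assert np.all(np.isnan(mdvh.sem_rel_volume))

    def test_per_edge_oracle(self, study_registry):
        grid = np.arange(0, 25, 1.0)
        mdvh = population_mean_dvh(study_registry, "preconstraints", "liver", grid)
        from dvhregistry.dvh_core import v_at_dose

        cohort = study_registry.get_cohort("preconstraints")
        curves = np.array(
            [
                [
                    v_at_dose(study_registry.load_plan(s).dvhs["liver"], float(d))
                    for d in grid
                ]
                for s in cohort.serials
            ]
        )
        np.testing.assert_allclose(mdvh.mean_rel_volume, curves.mean(axis=0))
        np.testing.assert_allclose(
            mdvh.sem_rel_volume, curves.std(axis=0, ddof=1) / np.sqrt(len(cohort))
        )

    def test_identical_plans_zero_sem(self):
        from test_constraints import plan_with_v5

        reg = Registry()
        serials = [
            reg.insert_plan(plan_with_v5("p", 50.0, 2010)),
            reg.insert_plan(plan_with_v5("q", 50.0, 2011)),
        ]
        reg.define_cohort("c", serials)
        mdvh = population_mean_dvh(reg, "c", "heart", np.arange(0, 31, 0.5))
        np.testing.assert_allclose(mdvh.sem_rel_volume, 0.0)


class TestTimeline:
    def test_yearly_means_match_groupby_oracle(self, study_registry):
        tl = timeline(study_registry, None, "heart", (2014, 2015))
        by_year = {}
        for serial in study_registry.serials():
            year = study_registry.plan_year(serial)
            by_year.setdefault(year, []).append(
                study_registry.plan_metrics(serial, "heart").d_mean
            )
        assert [p.year for p in tl.points] == sorted(by_year)
        for p in tl.points:
            assert p.mean_of_dmean == pytest.approx(np.mean(by_year[p.year]))
            if p.n == 1:
                assert math.isnan(p.sd)
            else:
                assert p.sd == pytest.approx(np.std(by_year[p.year], ddof=1))

    def test_reference_medians_split_by_years(self, study_registry):
        tl = timeline(study_registry, None, "heart", (2015, 2015))
        pre_vals = [
            study_registry.plan_metrics(s, "heart").d_mean
            for s in study_registry.serials()
            if study_registry.plan_year(s) < 2015
        ]
        assert tl.median_pre == pytest.approx(np.median(pre_vals))

    def test_absent_organ_rejected(self, study_registry):
        with pytest.raises(Exception, match="absent"):
            timeline(study_registry, None, "spleen", (2014, 2015))


class TestRenderReport:
    def test_report_files_written(self, tmp_path, study_registry, all_organs):
        grid = compare_cohorts(
            study_registry, "preconstraints", "postconstraints", ("heart", "liver")
        )
        tl = timeline(study_registry, None, "heart", (2014, 2015))
        mdvh_pre = population_mean_dvh(
            study_registry, "preconstraints", "heart", np.arange(0, 30, 0.5)
        )
        mdvh_post = population_mean_dvh(
            study_registry, "postconstraints", "heart", np.arange(0, 30, 0.5)
        )
        dmean = {
            "heart": (
                study_registry.cohort_metric_sample("preconstraints", "heart", "d_mean")[0],
                study_registry.cohort_metric_sample("postconstraints", "heart", "d_mean")[0],
            )
        }
        files = render_report(
            tmp_path,
            grid,
            mean_dvhs={"heart": (mdvh_pre, mdvh_post)},
            timelines={"heart": tl},
            dmean_samples=dmean,
        )
        assert (tmp_path / "comparison_results.csv").exists()
        assert (tmp_path / "category_grid.png").exists()
        assert (tmp_path / "mean_dvh_heart.png").exists()
        assert (tmp_path / "timeline_heart.png").exists()
        assert (tmp_path / "dmean_violins.png").exists()
        # results CSV: one row per cell plus header
        lines = (tmp_path / "comparison_results.csv").read_text().strip().splitlines()
        assert len(lines) == 1 + grid.n_evaluations
        assert all(f in files for f in [tmp_path / "comparison_results.csv"])
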