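import numpy as np
import pytest

from mitofoi import (
    GradeGroup,
    RaterGroup,
    RaterSelection,
    cohen_kappa,
    foi_pixel_dims,
    grade_group,
    pearson_corr,
    percentile_score,
    rater_report,
)
from mitofoi.evaluation import spearman_corr


class TestPearson:
    def test_self_correlation_is_one(self):
        x = [1.0, 2.5, 3.0, 7.0]
        assert pearson_corr(x, x) == pytest.approx(1.0)

    def test_negative_affine_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson_corr(x, -2 * x + 5) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_corr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_corr([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_and_short(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_corr([1], [2])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(20), rng.random(20)
        r = pearson_corr(x, y)
        assert pearson_corr(3.7 * x + 2, y) == pytest.approx(r, abs=1e-12)
        assert pearson_corr(x, 0.5 * y - 11) == pytest.approx(r, abs=1e-12)

    def test_spearman_option(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_corr(x, x ** 3) == pytest.approx(1.0)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        assert cohen_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_complementary_balanced_is_minus_one(self):
        assert cohen_kappa([1, 0, 1, 0], [0, 1, 0, 1]) == pytest.approx(-1.0)

    def test_degenerate_marginals(self):
        # both raters constant on the same label: p_e = 1, perfect agreement
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 0], [1])
        with pytest.raises(ValueError):
            cohen_kappa([], [])

    def test_matches_sklearn_on_random_labels(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 2, 30)
            b = np.where(rng.random(30) < 0.7, a, 1 - a)
            ref = sklearn_metrics.cohen_kappa_score(a, b)
            if np.isnan(ref):
                continue
            assert cohen_kappa(a, b) == pytest.approx(ref, abs=1e-12)


class TestGradeGroup:
    def test_all_below_threshold_is_clearly_low(self):
        assert grade_group(np.arange(7)) is GradeGroup.CLEARLY_LOW

    def test_eighty_percent_above_is_clearly_high(self):
        dist = np.r_[np.full(80, 9.0), np.full(20, 3.0)]
        assert grade_group(dist) is GradeGroup.CLEARLY_HIGH

    def test_exactly_75_percent_is_borderline(self):
        """The clearly-high rule is strictly 'more than 75%'."""
        dist = np.r_[np.full(75, 9.0), np.full(25, 3.0)]
        assert grade_group(dist) is GradeGroup.BORDERLINE

    def test_half_above_is_borderline(self):
        dist = np.r_[np.full(50, 9.0), np.full(50, 3.0)]
        assert grade_group(dist) is GradeGroup.BORDERLINE

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            grade_group([])


class TestPercentileScore:
    def test_max_is_top_everything(self):
        dist = np.arange(1, 51)
        assert percentile_score(50, dist) == (True, True)

    def test_below_min_is_nothing(self):
        assert percentile_score(0, np.arange(1, 51)) == (False, False)

    def test_order_statistic_boundary(self):
        dist = np.arange(1, 101)
        assert percentile_score(75, dist) == (True, True)
        assert percentile_score(74, dist) == (True, False)

    def test_monotone_in_selected(self):
        rng = np.random.default_rng(4)
        dist = np.sort(rng.integers(0, 30, 40))
        prev = (False, False)
        for v in range(31):
            th, tq = percentile_score(v, dist)
            assert th >= prev[0] and tq >= prev[1]
            prev = (th, tq)
            assert tq <= th  # upper quarter implies upper half


class TestRaterReport:
    def _sets(self):
        from mitofoi import SyntheticConfig, generate_annotations, generate_tissue

        sets, tissues = [], {}
        for seed in (21, 22):
            cfg = SyntheticConfig.coarse(seed=seed, parent_rate=1.5, offspring_mean=10)
            tissue, _ = generate_tissue(cfg)
            aset = generate_annotations(cfg, tissue)
            sets.append(aset)
            tissues[aset.slide_id] = tissue
        return sets, tissues

    def test_oracle_selector_scores_top(self):
        from mitofoi import GridSpec, oracle_density, select_foi, valid_mask

        sets, tissues = self._sets()
        shape = foi_pixel_dims(mpp=2.5)
        selections = []
        for aset in sets:
            grid = GridSpec.cover(aset.geometry, 20)
            vm = valid_mask(tissues[aset.slide_id], grid, shape, geometry=aset.geometry)
            res = select_foi(oracle_density(aset, shape, grid), vm, shape)
            selections.append(
                RaterSelection(aset.slide_id, "algo", RaterGroup.ALGORITHM, res.center_x, res.center_y)
            )
        reports, summaries = rater_report(
            sets, selections, shape, stride=20, tissues=tissues
        )
        for r in reports:
            assert all(th and tq for (_, _, _, _, th, tq) in r.raters)
        s = summaries["algorithm"]
        assert s["prop_top_half"] == 1.0 and s["prop_top_quarter"] == 1.0
        lo, hi = s["ci_top_half"]
        assert 0 <= lo <= 1.0 <= hi + 1e-12

    def test_bad_rater_flags_false(self):
        sets, tissues = self._sets()
        shape = foi_pixel_dims(mpp=2.5)
        # always select the slide corner: window clipped, mostly off-tissue
        selections = [
            RaterSelection(aset.slide_id, "bad", RaterGroup.VPIT, 2, 2) for aset in sets
        ]
        with pytest.warns(UserWarning, match="clipped"):
            reports, summaries = rater_report(sets, selections, shape, stride=20, tissues=tissues)
        assert summaries["VPIT"]["prop_top_quarter"] == 0.0

    def test_identical_raters_pairwise_kappa_one(self):
        sets, tissues = self._sets()
        shape = foi_pixel_dims(mpp=2.5)
        selections = []
        for aset in sets:
            mid = (aset.geometry.width_px // 2, aset.geometry.height_px // 2)
            for rater in ("a", "b"):
                selections.append(
                    RaterSelection(aset.slide_id, rater, RaterGroup.BCVP, *mid)
                )
        reports, summaries = rater_report(
            sets, selections, shape, stride=20, tissues=tissues, kappa_mode="pairwise"
        )
        assert summaries["BCVP"]["kappa"] == pytest.approx(1.0)

    def test_unknown_slide_rejected(self):
        sets, tissues = self._sets()
        shape = foi_pixel_dims(mpp=2.5)
        sel = [RaterSelection("nope", "a", RaterGroup.BCVP, 10, 10)]
        with pytest.raises(ValueError, match="unknown slide"):
            rater_report(sets, sel, shape, stride=20, tissues=tissues)


def test_plotting_smoke(tmp_path):
    matplotlib = pytest.importorskip("matplotlib")
    matplotlib.use("Agg")
    from mitofoi.evaluation import CaseReport
    from mitofoi.plotting import plot_case_reports, plot_group_proportions

    reports = [
        CaseReport("s1", GradeGroup.BORDERLINE, 0, 2, 5, 8, 12,
                   [("a", RaterGroup.BCVP, 6, False, True, False)]),
        CaseReport("s2", GradeGroup.CLEARLY_HIGH, 5, 8, 10, 12, 20,
                   [("a", RaterGroup.BCVP, 19, True, True, True)]),
    ]
    ax = plot_case_reports(reports)
    assert ax is not None
    summaries = {"BCVP": {"n": 2, "prop_top_half": 1.0, "ci_top_half": (0.34, 1.0),
                          "prop_top_quarter": 0.5, "ci_top_quarter": (0.09, 0.91), "kappa": 1.0}}
    assert plot_group_proportions(summaries) is not None
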