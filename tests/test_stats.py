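"""Agreement statistics against arithmetic, enumeration and simulation
oracles, plus an independent ICC cross-check."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import screenwatch as sw
from screenwatch.stats import WilcoxonResult, _icc_a1


class TestMetricsFromCounts:
    def test_perfect_counts(self):
        m = sw.metrics_from_counts(sw.ConfusionCounts(5, 5, 0, 0))
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0

    def test_hand_computed_mixed_counts(self):
        m = sw.metrics_from_counts(sw.ConfusionCounts(tp=1, tn=6, fp=2, fn=1))
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(0.75)
        assert m["ppv"] == pytest.approx(1 / 3)
        assert m["npv"] == pytest.approx(6 / 7)
        assert m["fpr"] == pytest.approx(0.25)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = sw.metrics_from_counts(sw.ConfusionCounts(tp=3, tn=0, fp=0, fn=1))
        assert m["specificity"] is None and m["fpr"] is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sw.ConfusionCounts(-1, 0, 0, 0)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=60))
    def test_agrees_with_recount_from_series(self, pairs):
        pred = [p for p, _ in pairs]
        gold = [g for _, g in pairs]
        c = sw.counts_from_series(pred, gold)
        # brute-force recount
        tp = sum(p and g for p, g in pairs)
        tn = sum(not p and not g for p, g in pairs)
        fp = sum(p and not g for p, g in pairs)
        fn = sum(not p and g for p, g in pairs)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        m = sw.metrics_from_counts(c)
        if tp + fn:
            assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        if m["fpr"] is not None:
            assert m["fpr"] == pytest.approx(1 - m["specificity"])


class TestPabak:
    def test_identical_series(self):
        assert sw.pabak([True, False, True], [True, False, True]) == 1.0

    def test_half_agreement_is_zero(self):
        assert sw.pabak([True, True, False, False],
                        [True, False, False, True]) == 0.0

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=60))
    def test_matches_agreement_count_oracle(self, pairs):
        pred = [p for p, _ in pairs]
        gold = [g for _, g in pairs]
        agree = sum(p == g for p, g in pairs)
        assert sw.pabak(pred, gold) == pytest.approx(2 * agree / len(pairs) - 1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sw.pabak([], [])

    def test_equals_kappa_when_marginals_balanced(self):
        """Prevalence 0.5 for both raters and symmetric errors: PABAK and
        Cohen's kappa coincide."""
        pred = [True] * 3 + [False] * 2 + [True] * 2 + [False] * 3
        gold = [True] * 3 + [True] * 2 + [False] * 2 + [False] * 3
        assert sum(pred) == sum(gold) == 5
        assert sw.pabak(pred, gold) == pytest.approx(sw.cohen_kappa(pred, gold))

    def test_ci_brackets_point_estimate(self, rng):
        pred = rng.uniform(size=500) < 0.5
        gold = rng.uniform(size=500) < 0.5
        lo, hi = sw.pabak_ci(pred, gold)
        assert lo <= sw.pabak(pred, gold) <= hi


class TestCohenKappa:
    def test_identical_categorical_series(self):
        codes = [sw.WATCHING, sw.NOT_WATCHING, sw.OUT_OF_FRAME,
                 sw.CANNOT_TELL] * 3
        assert sw.cohen_kappa(codes, codes) == pytest.approx(1.0)

    def test_toy_2x2_table_hand_computed(self):
        # table: a=20 agree-pos, d=15 agree-neg, b=5, c=10 (n=50)
        c1 = ["p"] * 25 + ["n"] * 25
        c2 = ["p"] * 20 + ["n"] * 5 + ["p"] * 10 + ["n"] * 15
        po = 35 / 50
        pe = (25 / 50) * (30 / 50) + (25 / 50) * (20 / 50)
        assert sw.cohen_kappa(c1, c2) == pytest.approx((po - pe) / (1 - pe))

    def test_independent_uniform_series_center_on_zero(self):
        rng = np.random.default_rng(11)
        kappas = [sw.cohen_kappa(rng.integers(0, 4, 400),
                                 rng.integers(0, 4, 400))
                  for _ in range(60)]
        se = np.std(kappas, ddof=1) / np.sqrt(len(kappas))
        assert abs(np.mean(kappas)) < 3 * se

    def test_degenerate_marginals_undefined(self):
        assert sw.cohen_kappa(["a", "a"], ["a", "a"]) is None


class TestIccFrame:
    def test_perfect_agreement(self):
        pred = [True, False, True, False, True, False]
        fam = [0, 0, 0, 1, 1, 1]
        assert sw.icc_frame(pred, pred, fam)["icc"] == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(60):
            pred = rng.uniform(size=300) < 0.5
            gold = rng.uniform(size=300) < 0.5
            fam = np.repeat([0, 1, 2], 100)
            vals.append(sw.icc_frame(pred, gold, fam)["icc"])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_two_family_fixture_matches_mean_squares_by_hand(self):
        pred = np.array([1, 0, 1, 1, 0, 0], dtype=float)
        gold = np.array([1, 0, 0, 1, 0, 1], dtype=float)
        fam = [0, 0, 0, 1, 1, 1]
        ratings = np.column_stack([pred, gold])
        n, k = ratings.shape
        grand = ratings.mean()
        msr = k * ((ratings.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((ratings.mean(0) - grand) ** 2).sum() / (k - 1)
        resid = ratings - ratings.mean(1)[:, None] - ratings.mean(0) + grand
        mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert sw.icc_frame(pred, gold, fam)["icc"] == pytest.approx(expected)

    def test_rater_swap_invariance(self, rng):
        pred = rng.uniform(size=200) < 0.4
        gold = rng.uniform(size=200) < 0.4
        fam = np.repeat([0, 1], 100)
        assert sw.icc_frame(pred, gold, fam)["icc"] == pytest.approx(
            sw.icc_frame(gold, pred, fam)["icc"])

    def test_single_family_errors(self):
        with pytest.raises(ValueError, match="famil"):
            sw.icc_frame([1, 0], [1, 0], [0, 0])

    def test_cross_check_against_pingouin(self, rng):
        """ICC(A,1) matches an independent implementation (ICC2)."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.standard_normal(40)
        y = x + 0.5 * rng.standard_normal(40)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(40), 2),
            "raters": np.tile(["a", "b"], 40),
            "ratings": np.column_stack([x, y]).ravel(),
        })
        res = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="ratings")
        mask = res["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(res.loc[mask, "ICC"].iloc[0])
        assert _icc_a1(np.column_stack([x, y])) == pytest.approx(icc2, abs=1e-6)


class TestIccTotalTime:
    def test_identical_totals(self):
        t = [10.0, 20.0, 35.0, 5.0]
        assert sw.icc_total_time(t, t) == pytest.approx(1.0)

    def test_constant_rater_contract(self):
        est = [10.0, 10.0, 10.0, 10.0]
        gold = [5.0, 15.0, 25.0, 35.0]
        val = sw.icc_total_time(est, gold)
        assert val is None or val <= 0.5

    def test_non_positive_total_errors(self):
        with pytest.raises(ValueError, match="positive"):
            sw.icc_total_time([1.0, 0.0, 2.0], [1.0, 1.0, 1.0])

    def test_recovers_variance_ratio(self):
        """Subject + noise model on the log scale: ICC estimates
        sigma_b^2 / (sigma_b^2 + sigma_w^2)."""
        rng = np.random.default_rng(8)
        sb, sw_ = 1.0, 0.5
        rho = sb**2 / (sb**2 + sw_**2)
        subj = rng.normal(3.0, sb, size=400)
        est = np.exp(subj + rng.normal(0, sw_, size=400))
        gold = np.exp(subj + rng.normal(0, sw_, size=400))
        assert sw.icc_total_time(est, gold) == pytest.approx(rho, abs=0.07)


class TestClassifyIcc:
    @pytest.mark.parametrize("value,band", [
        (0.725, "high"),
        (0.401, "moderate"),
        (0.35, "weak"),
        (0.354, "moderate"),
        (0.68, "high"),
        (0.9, "very_high"),
        (0.95, "very_high"),
        (-0.2, "weak"),
    ])
    def test_bands(self, value, band):
        assert sw.classify_icc(value) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            sw.classify_icc(1.5)


def _exact_two_sided_p(diffs):
    """Enumerate all sign assignments of |differences| (no ties) and
    compute the exact two-sided signed-rank p-value."""
    absd = np.abs(diffs)
    ranks = np.argsort(np.argsort(absd)) + 1
    w_obs = ranks[np.asarray(diffs) > 0].sum()
    n = len(diffs)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    total = ranks.sum()
    # two-sided: fold around the mean of the null distribution
    dist = np.abs(ws - total / 2)
    return float(np.mean(dist >= abs(w_obs - total / 2) - 1e-12))


class TestWilcoxonVisits:
    def test_identical_pairs_degenerate_p_one(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = sw.wilcoxon_visits(v, v)
        assert isinstance(res, WilcoxonResult)
        assert res.degenerate and res.pvalue == 1.0

    def test_shifted_pairs_match_enumeration_oracle(self):
        v1 = [1.0, 2.0, 3.0, 4.0, 5.0]
        v2 = [2.0, 4.0, 6.0, 8.0, 10.0]
        res = sw.wilcoxon_visits(v1, v2)
        assert res.method == "exact"
        expected = _exact_two_sided_p(np.asarray(v1) - np.asarray(v2))
        assert res.pvalue == pytest.approx(expected)

    def test_random_pairs_match_enumeration_oracle(self, rng):
        for _ in range(5):
            v1 = rng.standard_normal(8)
            v2 = rng.standard_normal(8)
            res = sw.wilcoxon_visits(v1, v2)
            assert res.pvalue == pytest.approx(
                _exact_two_sided_p(v1 - v2), abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            sw.wilcoxon_visits([1, 2], [2, 3])

    def test_type_i_error_near_alpha_quick(self):
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 400
        for _ in range(reps):
            v1 = rng.standard_normal(10)
            v2 = rng.standard_normal(10)
            if sw.wilcoxon_visits(v1, v2).pvalue <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08


class TestStratifiedSummary:
    def test_identical_group_sd_zero(self):
        out = sw.stratified_summary([5.0, 5.0, 5.0], [6.0, 6.0, 6.0],
                                    ["a", "a", "a"])
        row = out.iloc[0]
        assert row["estimated_sd"] == 0.0 and row["gold_sd"] == 0.0

    def test_two_groups_hand_means(self):
        out = sw.stratified_summary([10.0, 20.0, 30.0], [12.0, 22.0, 28.0],
                                    ["x", "x", "y"]).set_index("group")
        assert out.loc["x", "estimated_mean"] == pytest.approx(15.0)
        assert out.loc["x", "gold_mean"] == pytest.approx(17.0)
        assert out.loc["y", "n"] == 1
        assert np.isnan(out.loc["y", "estimated_sd"])

    def test_relabeling_permutes_rows_only(self):
        est, gold = [1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 4.5]
        a = sw.stratified_summary(est, gold, ["g1", "g1", "g2", "g2"])
        b = sw.stratified_summary(est, gold, ["g2", "g2", "g1", "g1"])
        a_vals = a.set_index("group").loc["g1"].to_numpy()
        b_vals = b.set_index("group").loc["g2"].to_numpy()
        assert np.allclose(a_vals, b_vals, equal_nan=True)


class TestAgreementReport:
    def test_cannot_tell_excluded_out_of_frame_not_watching(self):
        codes = [sw.WATCHING, sw.CANNOT_TELL, sw.OUT_OF_FRAME,
                 sw.NOT_WATCHING]
        gold = sw.GoldLog.from_codes(codes, 15.0)
        log = sw.ViewingLog([True, True, False, False], 15.0)
        rep = sw.agreement_report(log, gold)
        assert rep.n_excluded_cannot_tell == 1
        assert rep.counts.total == 3
        assert rep.counts.tp == 1 and rep.counts.tn == 2
        assert rep.pabak == 1.0

    def test_bands_attached_with_families(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(size=400) < 0.3
        pred = truth.copy()
        flip = rng.uniform(size=400) < 0.05
        pred[flip] = ~pred[flip]
        codes = np.where(truth, sw.WATCHING, sw.NOT_WATCHING)
        gold = sw.GoldLog.from_codes(codes.tolist(), 15.0)
        log = sw.ViewingLog(pred, 15.0)
        rep = sw.agreement_report(log, gold, family_ids=np.repeat([0, 1], 200))
        assert rep.icc_frame is not None
        assert rep.icc_frame_band in ("weak", "moderate", "high", "very_high")
        assert "icc_estimator" in rep.metadata
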