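"""ANOVA variants, rank-based two-way test, post hoc comparisons and the
power computation, each checked against an independent oracle."""

import numpy as np
import pytest
from scipy import stats as sps

from msart.stats import (
    PowerSpec,
    anova_power,
    oneway_anova,
    pairwise_posthoc,
    required_sample_size,
    scheirer_ray_hare,
    welch_anova,
)


@pytest.fixture
def random_groups():
    rng = np.random.default_rng(314)
    return [rng.normal(10 + d, 1 + d / 2, size=n) for d, n in zip((0, 0.5, 1.5), (14, 18, 25))]


class TestOnewayAnova:
    def test_matches_scipy(self, random_groups):
        res = oneway_anova(random_groups)
        ref = sps.f_oneway(*random_groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.df1 == 2 and res.df2 == sum(map(len, random_groups)) - 3

    def test_eta_from_direct_sums_of_squares(self, random_groups):
        res = oneway_anova(random_groups)
        allv = np.concatenate(random_groups)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        ss_w = sum(((g - g.mean()) ** 2).sum() for g in random_groups)
        assert res.eta_p_sq == pytest.approx((ss_total - ss_w) / ss_total, rel=1e-10)

    def test_perfect_separation(self):
        res = oneway_anova([[0.0, 0.0], [1.0, 1.0]])
        assert res.eta_p_sq == 1.0
        assert np.isinf(res.statistic)

    def test_identical_groups_zero_f(self):
        res = oneway_anova([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0
        assert res.eta_p_sq == 0.0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([[1.0, 2.0]])


def _welch_oracle(groups):
    # Welch (1951) formulas, written straight from the textbook
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = (((1 - w / w.sum()) ** 2) / (n - 1)).sum()
    f = num / (1 + 2 * (k - 2) * lam / (k * k - 1))
    df2 = (k * k - 1) / (3 * lam)
    return f, k - 1.0, df2


class TestWelchAnova:
    def test_matches_formula_oracle(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 10.0]]
        res = welch_anova(groups)
        f, df1, df2 = _welch_oracle(groups)
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.df1 == df1
        assert res.df2 == pytest.approx(df2, rel=1e-12)
        assert not float(res.df2).is_integer()  # fractional Welch df

    def test_matches_pingouin(self, random_groups):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        res = welch_anova(random_groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(random_groups),
                "g": np.repeat(np.arange(3), [len(g) for g in random_groups]),
            }
        )
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_equal_means_near_zero_f(self):
        g = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        assert welch_anova(g).statistic == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_classical_under_homoscedasticity(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(i * 0.3, 1.0, 40) for i in range(3)]
        w = welch_anova(groups)
        c = oneway_anova(groups)
        assert w.statistic == pytest.approx(c.statistic, rel=0.15)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="positive variance"):
            welch_anova([[1.0, 1.0], [2.0, 3.0]])


def _srh_bruteforce(values, fa, fb):
    """Rank partition computed longhand on explicit subsets."""
    values = np.asarray(values, float)
    fa, fb = np.asarray(fa), np.asarray(fb)
    r = sps.rankdata(values)
    n = len(r)
    ms_total = ((r - r.mean()) ** 2).sum() / (n - 1)

    def ss_for(labels):
        tot = 0.0
        for lv in np.unique(labels):
            rr = r[labels == lv]
            tot += len(rr) * (rr.mean() - r.mean()) ** 2
        return tot

    ss_a, ss_b = ss_for(fa), ss_for(fb)
    cells = np.array([f"{a}|{b}" for a, b in zip(fa, fb)])
    ss_ab = ss_for(cells) - ss_a - ss_b
    return {k: ss / ms_total for k, ss in (("A", ss_a), ("B", ss_b), ("A:B", ss_ab))}


class TestScheirerRayHare:
    def test_small_layout_matches_bruteforce(self):
        values = [2.0, 3.1, 5.5, 1.2, 9.9, 8.1, 4.4, 6.6, 7.2, 0.5, 3.3, 2.2]
        fa = ["x", "x", "x", "x", "y", "y", "y", "y", "x", "x", "y", "y"]
        fb = [1, 1, 2, 2, 1, 1, 2, 2, 1, 2, 1, 2]
        res = scheirer_ray_hare(values, fa, fb)
        ref = _srh_bruteforce(values, fa, fb)
        for key in ("A", "B", "A:B"):
            assert res[key].statistic == pytest.approx(ref[key], rel=1e-10)
            assert res[key].p_value == pytest.approx(
                sps.chi2.sf(ref[key], res[key].df1), rel=1e-10
            )
            assert res[key].df2 == len(values)  # reported alongside as N

    def test_reduces_to_kruskal_wallis_when_b_constant(self):
        rng = np.random.default_rng(77)
        groups = [rng.normal(i, 1, 15) for i in range(3)]
        values = np.concatenate(groups)
        fa = np.repeat(["a", "b", "c"], 15)
        fb = np.zeros(45)
        res = scheirer_ray_hare(values, fa, fb)
        ref = sps.kruskal(*groups)
        assert res["A"].statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res["A"].p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_kruskal_equivalence_with_ties(self):
        values = [1, 2, 2, 3, 3, 3, 4, 5, 5, 6, 1, 2]
        fa = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        fb = [0] * 12
        res = scheirer_ray_hare(values, fa, fb)
        ref = sps.kruskal(values[:4], values[4:8], values[8:])
        assert res["A"].statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_all_equal_gives_zero_h(self):
        res = scheirer_ray_hare([5.0] * 8, ["a", "b"] * 4, [0, 0, 1, 1] * 2)
        assert all(r.statistic == 0.0 for r in res.values())

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=24)
        fa = np.repeat(["a", "b"], 12)
        fb = np.tile(np.repeat([0, 1], 6), 2)
        r1 = scheirer_ray_hare(values, fa, fb)
        r2 = scheirer_ray_hare(np.exp(values * 3), fa, fb)
        for key in ("A", "B", "A:B"):
            assert r1[key].statistic == pytest.approx(r2[key].statistic, rel=1e-12)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cell"):
            scheirer_ray_hare([1.0, 2.0, 3.0], ["a", "a", "b"], [0, 1, 0])


class TestPosthoc:
    def test_identical_groups_p_near_one(self):
        g = [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]]
        for method in ("tukey", "games_howell", "bonferroni"):
            p = pairwise_posthoc(g, method=method)
            assert p.shape == (2, 2)
            assert p[0, 1] > 0.99

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown post hoc"):
            pairwise_posthoc([[1.0, 2.0], [3.0, 4.0]], method="scheffe")

    def test_games_howell_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(21)
        groups = [rng.normal(0, 1, 12), rng.normal(0.8, 2.5, 20), rng.normal(2.0, 0.5, 9)]
        p = pairwise_posthoc(groups, method="games_howell")
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        lookup = {tuple(sorted((row["A"], row["B"]))): row["pval"] for _, row in ref.iterrows()}
        labels = ["a", "b", "c"]
        for i in range(3):
            for j in range(i + 1, 3):
                assert p[i, j] == pytest.approx(lookup[(labels[i], labels[j])], rel=1e-6)

    def test_tukey_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(9)
        groups = [rng.normal(d, 1, 15) for d in (0, 0.5, 1.2)]
        p = pairwise_posthoc(groups, method="tukey")
        res = sm.pairwise_tukeyhsd(
            np.concatenate(groups), np.repeat([0, 1, 2], 15)
        )
        ref = np.asarray(res.pvalues)
        assert p[0, 1] == pytest.approx(ref[0], abs=1e-6)
        assert p[0, 2] == pytest.approx(ref[1], abs=1e-6)
        assert p[1, 2] == pytest.approx(ref[2], abs=1e-6)

    def test_separated_severity_groups_all_significant(self):
        rng = np.random.default_rng(3)
        mild = rng.normal(1.77, 0.4, 40)
        moderate = rng.normal(1.69, 0.4, 40)
        severe = rng.normal(0.6, 0.4, 40)
        p = pairwise_posthoc([mild, moderate, severe], method="games_howell")
        # the clearly separated pairs are significant; the close pair is not
        assert p[0, 2] < 0.001 and p[1, 2] < 0.001
        assert p[0, 1] > 0.05


class TestPower:
    def test_required_n_reference_case(self):
        assert required_sample_size(PowerSpec(0.25, 0.05, 0.80, 3)) == 159

    def test_power_brackets_the_answer(self):
        spec = PowerSpec(0.25, 0.05, 0.80, 3)
        assert anova_power(159, spec) >= 0.80
        assert anova_power(159 - 3, spec) < 0.80

    def test_per_unit_search_not_larger(self):
        spec = PowerSpec(0.25, 0.05, 0.80, 3)
        assert required_sample_size(spec, step=1) <= 159

    def test_monotone_in_parameters(self):
        base = required_sample_size(PowerSpec(0.25, 0.05, 0.80, 3))
        assert required_sample_size(PowerSpec(0.40, 0.05, 0.80, 3)) <= base
        assert required_sample_size(PowerSpec(0.25, 0.10, 0.80, 3)) <= base
        assert required_sample_size(PowerSpec(0.25, 0.05, 0.90, 3)) >= base

    def test_huge_effect_small_n(self):
        # with f = 2 the search stops at the first N (>= 2 per group)
        # whose noncentral-F power clears the target
        spec = PowerSpec(2.0, 0.05, 0.80, 2)
        n = required_sample_size(spec)
        assert n == 6
        assert anova_power(n, spec) >= 0.80
        assert anova_power(n - 2, spec) < 0.80

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_size_f=0.0)
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5)
        with pytest.raises(ValueError):
            PowerSpec(k_groups=1)


class TestLongFormatBridge:
    def test_window_anova_from_long_csv(self, tmp_path):
        from msart.engine import SessionConfig, run_session
        from msart.io import write_windows_csv
        from msart.metrics import window_metrics
        from msart.responder import MarkovResponder, ResponderParams
        from msart.stats import anova_from_window_long, results_to_table

        windows = {}
        for seed in range(8):
            log = run_session(
                SessionConfig(session_duration=1800.0, rng_seed=seed),
                MarkovResponder(ResponderParams(severity=0.5)),
            )
            windows[f"s{seed}"] = window_metrics(log)
        path = write_windows_csv(tmp_path / "win.csv", windows)

        res = anova_from_window_long(path, "d_prime", test="welch")
        assert res.df1 == 5  # six windows
        assert 0.0 <= res.p_value <= 1.0
        table = results_to_table(res)
        assert list(table.columns) == [
            "effect", "statistic_name", "statistic", "df1", "df2", "p_value", "eta_p_sq",
        ]
        assert table.loc[0, "effect"] == "window:d_prime"

    def test_unknown_metric_rejected(self, tmp_path):
        import pandas as pd

        from msart.stats import anova_from_window_long

        df = pd.DataFrame({"session_id": [], "window": [], "metric": [], "value": []})
        with pytest.raises(ValueError, match="no observations"):
            anova_from_window_long(df, "d_prime")
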