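"""Statistics layer vs independent oracles: closed-form t and chi-square,
hand sums-of-squares ANOVA decomposition, Bonferroni bookkeeping, null
calibration of the serial tests."""

import numpy as np
import pytest
from scipy import stats as sps

import plethykit as pk


class TestBonferroni:
    def test_protocol_threshold(self):
        p = pk.build_protocol("adult", "hypoxia")
        thr = pk.bonferroni_threshold(0.05, p.total_minutes)
        assert thr == pytest.approx(0.05 / 44)
        assert float(f"{thr:.2g}") == 0.0011

    @pytest.mark.parametrize("alpha,m,expected",
                             [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_identity_and_division(self, alpha, m, expected):
        assert pk.bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_comparisons_raise(self):
        with pytest.raises(ValueError):
            pk.bonferroni_threshold(0.05, 0)


class TestTwoSampleTtest:
    def test_textbook_pair_matches_pooled_formula(self):
        # A={1,2,3}, B={2,3,4}: s_p^2=1, t = -1/sqrt(2/3) = -1.224745, df=4
        r = pk.two_sample_ttest([1, 2, 3], [2, 3, 4])
        assert r.statistic == pytest.approx(-np.sqrt(1.5), rel=1e-9)
        assert r.df == 4
        assert r.p_value == pytest.approx(0.287864, abs=1e-5)

    def test_identical_groups(self):
        r = pk.two_sample_ttest([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        r1, r2 = pk.two_sample_ttest(a, b), pk.two_sample_ttest(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_welch_option(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 5, 20)
        r = pk.two_sample_ttest(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert r.statistic == pytest.approx(float(ref.statistic))


class TestChiSquare:
    def test_perfect_independence(self):
        r = pk.chi_square_2x2([[10, 10], [10, 10]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_inclusion_table_value(self):
        # Pearson without continuity correction on the 23/33 vs 12/16 table
        r = pk.chi_square_2x2([[23, 10], [12, 4]])
        assert r.statistic == pytest.approx(0.1485, abs=2e-4)
        assert r.df == 1

    def test_matches_z_squared_of_proportions(self):
        """Algebraic identity: Pearson chi-square on a 2x2 equals the squared
        pooled z statistic for two proportions."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = rng.integers(1, 60, size=(2, 2))
            n1, n2 = t[0].sum(), t[1].sum()
            p1, p2 = t[0, 0] / n1, t[1, 0] / n2
            pbar = (t[0, 0] + t[1, 0]) / (n1 + n2)
            z = (p1 - p2) / np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
            assert pk.chi_square_2x2(t).statistic == pytest.approx(z * z,
                                                                   rel=1e-9)

    def test_invalid_tables_raise(self):
        with pytest.raises(ValueError):
            pk.chi_square_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError, match="margin"):
            pk.chi_square_2x2([[0, 0], [3, 4]])


def _hand_anova_balanced(y, a, b):
    """Independent sums-of-squares decomposition for a balanced two-factor
    design (classic textbook formulas; equals Type II when balanced)."""
    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    ss_a = sum((y[a == lv].mean() - grand) ** 2 * (a == lv).sum()
               for lv in np.unique(a))
    ss_b = sum((y[b == lv].mean() - grand) ** 2 * (b == lv).sum()
               for lv in np.unique(b))
    ss_cells = sum(
        (y[(a == la) & (b == lb)].mean() - grand) ** 2
        * ((a == la) & (b == lb)).sum()
        for la in np.unique(a) for lb in np.unique(b))
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((y - grand) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_tot - ss_cells


@pytest.fixture(scope="module")
def balanced_data():
    rng = np.random.default_rng(7)
    geno = np.repeat(["ctl", "cko"], 12)
    trt = np.tile(np.repeat(["none", "caffeine"], 6), 2)
    y = rng.normal(10, 1, 24) + 2.0 * (geno == "cko")
    return y, geno, trt


class TestTwoWayAnova:
    def test_matches_hand_ss_decomposition(self, balanced_data):
        y, geno, trt = balanced_data
        table, _ = pk.two_way_anova_tukey(y, geno, trt)
        ss_a, ss_b, ss_ab, ss_e = _hand_anova_balanced(y, geno, trt)
        assert table.loc["C(genotype)", "sum_sq"] == pytest.approx(ss_a)
        assert table.loc["C(treatment)", "sum_sq"] == pytest.approx(ss_b)
        assert table.loc["C(genotype):C(treatment)", "sum_sq"] \
            == pytest.approx(ss_ab)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_e)

    def test_ss_conservation(self, balanced_data):
        y, geno, trt = balanced_data
        table, _ = pk.two_way_anova_tukey(y, geno, trt)
        total = ((y - y.mean()) ** 2).sum()
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_additive_shift_detected_without_interaction(self, balanced_data):
        y, geno, trt = balanced_data
        table, tukey = pk.two_way_anova_tukey(y, geno, trt)
        assert table.loc["C(genotype)", "PR(>F)"] < 0.001
        # with a purely additive effect the interaction F stays inside the
        # 99% envelope of its null distribution
        f_int = table.loc["C(genotype):C(treatment)", "F"]
        df_res = table.loc["Residual", "df"]
        assert f_int < sps.f.ppf(0.99, 1, df_res)
        assert tukey is not None and len(tukey) == 6   # 4 cells -> 6 pairs

    def test_degenerate_constant_data(self):
        table, tukey = pk.two_way_anova_tukey(
            [5.0] * 8, ["a"] * 4 + ["b"] * 4, ["x", "y"] * 4)
        assert (table["sum_sq"] == 0).all()
        assert tukey is None

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError, match="cell"):
            pk.two_way_anova_tukey([1, 2, 3, 4], ["a", "a", "b", "b"],
                                   ["x", "x", "y", "y"])
        with pytest.raises(ValueError, match="levels"):
            pk.two_way_anova_tukey([1, 2, 3, 4], ["a", "a", "b", "b"],
                                   ["x", "x", "x", "x"])

    def test_null_no_posthoc(self):
        rng = np.random.default_rng(123)
        y = rng.normal(0, 1, 24)
        geno = np.repeat(["ctl", "cko"], 12)
        trt = np.tile(np.repeat(["none", "caffeine"], 6), 2)
        table, tukey = pk.two_way_anova_tukey(y, geno, trt)
        if (table["PR(>F)"].drop("Residual").dropna() >= 0.05).all():
            assert tukey is None


class TestSerialGroupTests:
    def _sessions(self, profile, protocol, seeds, param="vf"):
        return [
            pk.normalize_response(
                pk.simulate_session(profile, protocol, seed=s)[0],
                protocol, param)
            for s in seeds
        ]

    def test_identical_groups_flag_nothing(self, adult_protocol):
        g = self._sessions(pk.control_profile(), adult_protocol, range(8))
        res = pk.serial_group_tests(g, g)
        assert len(res) == 44
        assert not any(r.significant for r in res)
        assert res[0].adjusted_alpha == pytest.approx(0.05 / 44)

    def test_challenge_effect_detected_baseline_clean(self, adult_protocol):
        """Frequency halved during challenge only: challenge minutes flag,
        baseline minutes do not (power ~ 1 at 5% within-group CV, n=8)."""
        fac = np.ones(24)
        fac[:9] = 0.5
        ctl = pk.GenotypeProfile(hypoxia_curve={"tv": np.ones(24),
                                                "vf": np.ones(24)})
        cko = pk.GenotypeProfile(hypoxia_curve={"tv": np.ones(24), "vf": fac})
        ga = [pk.normalize_response(
            pk.simulate_session(ctl, adult_protocol, s, minute_cv=0.05)[0],
            adult_protocol, "vf") for s in range(8)]
        gb = [pk.normalize_response(
            pk.simulate_session(cko, adult_protocol, 50 + s, minute_cv=0.05)[0],
            adult_protocol, "vf") for s in range(8)]
        res = pk.serial_group_tests(ga, gb)
        flagged = {r.minute for r in res if r.significant}
        assert set(range(21, 30)) <= flagged
        assert flagged.isdisjoint(range(1, 21))

    def test_missing_minutes_reduce_divisor(self, adult_protocol):
        g1 = np.array([r.values for r in self._sessions(
            pk.control_profile(), adult_protocol, range(6))]).T
        g2 = g1 + 0.0
        g1 = g1.copy()
        g1[5, :] = np.nan          # minute 6 missing in every group-A animal
        res = pk.serial_group_tests(g1, g2)
        assert len(res) == 43
        assert res[0].adjusted_alpha == pytest.approx(0.05 / 43)
        assert all(r.minute != 6 for r in res)

    def test_null_familywise_error_calibrated(self, adult_protocol):
        """Under the null, Bonferroni bounds the familywise error by alpha;
        the simulated count must sit inside the one-sided 99.9% binomial
        envelope of that bound."""
        rng = np.random.default_rng(2024)
        n_rep, n_animals, n_min = 200, 8, 44
        false_pos = 0
        for _ in range(n_rep):
            A = 1.0 + 0.05 * rng.standard_normal((n_min, n_animals))
            B = 1.0 + 0.05 * rng.standard_normal((n_min, n_animals))
            res = pk.serial_group_tests(A, B)
            false_pos += any(r.significant for r in res)
        assert false_pos <= sps.binom.ppf(0.999, n_rep, 0.05)
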