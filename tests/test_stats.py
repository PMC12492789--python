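"""Repeated-measures ANOVA, pairwise contrasts, paired t and McNemar."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from todacc.stats import (
    DegenerateDataError,
    compare_adherence,
    emm_pairwise,
    paired_t,
    rm_anova,
)


def oracle_ss(m):
    """Direct-summation sums of squares, written element by element."""
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_subject = k * sum((r - grand) ** 2 for r in row)
    ss_method = n * sum((c - grand) ** 2 for c in col)
    ss_error = ss_total - ss_subject - ss_method
    return ss_method, ss_subject, ss_error


class TestRmAnova:
    def test_matches_ss_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 11))
            m = rng.normal(100, 20, size=(n, 3))
            res = rm_anova(m)
            ss_m, ss_s, ss_e = oracle_ss(m)
            f = (ss_m / 2) / (ss_e / ((n - 1) * 2))
            assert res.f_stat == pytest.approx(f, rel=1e-10)
            assert res.p_value == pytest.approx(float(sps.f.sf(f, 2, (n - 1) * 2)), rel=1e-10)

    def test_identical_methods_give_f_zero_p_one(self):
        m = np.tile(np.array([[10.0], [20.0], [35.0]]), (1, 3))
        res = rm_anova(m)
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_additive_matrix_is_degenerate(self):
        m = np.array([[10.0, 12, 14], [20, 22, 24], [30, 32, 34]])
        with pytest.raises(DegenerateDataError):
            rm_anova(m)

    def test_constant_matrix_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            rm_anova(np.full((4, 3), 7.0))

    def test_f_equals_t_squared_for_two_methods(self, rng):
        for _ in range(50):
            m = rng.normal(0, 1, size=(8, 2))
            res = rm_anova(m)
            t, df, p = paired_t(m[:, 0], m[:, 1])
            assert res.f_stat == pytest.approx(t * t, rel=1e-8)
            assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.normal(50, 10, size=(12, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "method": np.tile(["a", "b", "c"], 12),
                "y": m.ravel(),
            }
        )
        aov = pingouin.rm_anova(data=long, dv="y", within="method", subject="subject")
        res = rm_anova(m)
        assert res.f_stat == pytest.approx(float(aov["F"][0]), rel=1e-8)
        assert res.p_value == pytest.approx(float(aov["p_unc"][0]), rel=1e-8)
        assert res.gg_epsilon == pytest.approx(float(aov["eps"][0]), rel=1e-6)


class TestPairwiseContrasts:
    def test_hand_computed_fixture(self):
        # within-subject differences a-b: (2, 2, 3, 1, 2)
        b = np.array([10.0, 20, 30, 40, 50])
        a = b + np.array([2.0, 2, 3, 1, 2])
        c = b.copy()
        m = np.column_stack([a, b, c])
        contrasts = {tuple(x.pair): x for x in emm_pairwise(m, ["a", "b", "c"])}
        ab = contrasts[("a", "b")]
        assert ab.estimate == pytest.approx(2.0)
        assert ab.se == pytest.approx(math.sqrt(0.5 / 5))
        assert ab.t_value == pytest.approx(2.0 / math.sqrt(0.1), rel=1e-12)
        p_raw = 2 * sps.t.sf(abs(ab.t_value), 4)
        assert ab.p_bonf == pytest.approx(min(1.0, 3 * p_raw))
        tcrit = sps.t.ppf(1 - (0.05 / 3) / 2, 4)
        assert ab.ci_low == pytest.approx(2.0 - tcrit * ab.se)

    def test_antisymmetry_and_transitivity(self, rng):
        m = rng.normal(0, 5, size=(9, 3))
        cons = {tuple(c.pair): c.estimate for c in emm_pairwise(m, ["a", "b", "c"])}
        rev = {tuple(c.pair): c.estimate for c in emm_pairwise(m[:, ::-1], ["c", "b", "a"])}
        assert cons[("a", "b")] == pytest.approx(-rev[("b", "a")], rel=1e-12)
        assert cons[("a", "c")] == pytest.approx(
            cons[("a", "b")] + cons[("b", "c")], abs=1e-12
        )

    def test_identical_columns_flagged(self):
        m = np.column_stack([np.arange(5.0)] * 3)
        for c in emm_pairwise(m, ["a", "b", "c"]):
            assert c.degenerate and c.estimate == 0.0 and c.p_bonf == 1.0


class TestPairedT:
    def test_identical_samples(self):
        t, df, p = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_sign_flips_with_difference(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        t1, _, p1 = paired_t(a, b)
        t2, _, p2 = paired_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_matches_scipy(self, rng):
        a = rng.normal(10, 2, size=15)
        b = rng.normal(11, 2, size=15)
        t, df, p = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2], [1.0, 2, 3])


class TestCompareAdherence:
    def test_identical_flags(self):
        res = compare_adherence([True, False, True], [True, False, True])
        assert res.p_value == 1.0 and res.note == "no discordant pairs"

    def test_ten_discordant_one_direction(self):
        a = np.array([True] * 10 + [True] * 5)
        b = np.array([False] * 10 + [True] * 5)
        res = compare_adherence(a, b)
        assert res.n_a_only == 10 and res.n_b_only == 0
        assert res.p_value == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_symmetric_discordance(self):
        a = np.array([True] * 5 + [False] * 5)
        b = ~a
        assert compare_adherence(a, b).p_value == 1.0

    def test_matches_statsmodels_exact(self, rng):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        a = rng.random(40) < 0.7
        b = rng.random(40) < 0.5
        res = compare_adherence(a, b)
        table = [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
        ref = sm.mcnemar(table, exact=True)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)
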