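"""Oracle tests for the statistical primitives."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from mtrkit.stat_battery import (
    bh_fdr,
    clinvar_state_enrichment,
    descriptive,
    fisher_ha,
    kruskal_dunn,
    mann_whitney,
    significance_stars,
    two_prop_z,
    wilson_ci,
)


@lru_cache(maxsize=None)
def _margin_pmf(r1, r2, c1):
    """Oracle pmf over 2x2 tables with fixed margins, from binomial coefficients."""
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(r1 + r2, c1)
    return lo, [math.comb(r1, a) * math.comb(r2, c1 - a) / denom for a in range(lo, hi + 1)]


def fisher_oracle_p(a, b, c, d):
    lo, pmf = _margin_pmf(a + b, c + d, a + c)
    p_obs = pmf[a - lo]
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1 + 1e-7)))


class TestFisherHA:
    def test_balanced_table(self):
        log2_or, p = fisher_ha([[5, 5], [5, 5]])
        assert log2_or == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_haldane_anscombe_zero_cell(self):
        log2_or, _ = fisher_ha([[0, 10], [5, 5]])
        assert log2_or == pytest.approx(math.log2(0.5 / 10.5), abs=1e-9)

    def test_all_zero_table_na(self):
        log2_or, p = fisher_ha([[0, 0], [0, 0]])
        assert np.isnan(log2_or) and np.isnan(p)

    def test_matches_enumeration_small_tables(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b + c + d == 0:
                continue
            _, p = fisher_ha([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle_p(a, b, c, d), rel=1e-9)

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, 4)
            if a + b + c + d == 0:
                continue
            _, p = fisher_ha([[a, b], [c, d]])
            assert p == pytest.approx(
                fisher_exact([[a, b], [c, d]], alternative="two-sided")[1], rel=1e-6
            )


class TestWilson:
    def test_degenerate_endpoints(self):
        assert wilson_ci(0, 10)[0] == pytest.approx(0.0)
        assert wilson_ci(10, 10)[1] == pytest.approx(1.0)

    def test_half_interval(self):
        lo, hi = wilson_ci(5, 10)
        assert (lo, hi) == pytest.approx((0.2366, 0.7634), abs=5e-4)

    def test_score_inequality_inversion(self):
        """Interval endpoints satisfy the score equation |p̂-p| = z·sqrt(p(1-p)/n)."""
        from scipy.stats import norm

        z = norm.ppf(0.975)
        k, n = 13, 40
        for bound in wilson_ci(k, n):
            lhs = abs(k / n - bound)
            rhs = z * math.sqrt(bound * (1 - bound) / n)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_zero_trials_na(self):
        assert all(np.isnan(v) for v in wilson_ci(0, 0))


class TestTwoPropZ:
    def test_equal_proportions(self):
        z, p = two_prop_z(5, 10, 10, 20)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pooled_se_arithmetic(self):
        z, _ = two_prop_z(90, 100, 10, 100)
        expected = 0.8 / math.sqrt(0.5 * 0.5 * (1 / 100 + 1 / 100))
        assert z == pytest.approx(expected, rel=1e-9)

    def test_antisymmetry(self):
        z1, p1 = two_prop_z(30, 50, 10, 40)
        z2, p2 = two_prop_z(10, 40, 30, 50)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_pooled_proportion(self):
        assert two_prop_z(0, 10, 0, 10) == (0.0, 1.0)


class TestKruskalDunn:
    def test_identical_groups_share_one_letter(self):
        groups = [[1.0, 1.0, 1.0]] * 4
        gc = kruskal_dunn(groups)
        assert gc.h_statistic == 0.0 and gc.p_global == 1.0
        assert set(gc.letters.values()) == {"a"}

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(1)
        gc = kruskal_dunn(
            [rng.normal(0, 1, 100), rng.normal(10, 1, 100)], ["lo", "hi"]
        )
        assert gc.letters["lo"] != gc.letters["hi"]
        assert gc.p_global < 1e-6

    def test_letters_symmetric_under_relabeling(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 80) for m in (0, 0, 5, 5)]
        fwd = kruskal_dunn(groups, ["a1", "a2", "b1", "b2"])
        rev = kruskal_dunn(groups[::-1], ["b2", "b1", "a2", "a1"])
        # the same partition of groups into letter classes, letters renamed
        def classes(gc):
            by_letter = {}
            for g, l in gc.letters.items():
                by_letter.setdefault(l, set()).add(g)
            return {frozenset(v) for v in by_letter.values()}

        assert classes(fwd) == classes(rev)

    def test_letters_iff_nonsignificant(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 60) for m in (0, 0.5, 5, 5.5)]
        labels = ["a", "b", "c", "d"]
        gc = kruskal_dunn(groups, labels, alpha=0.05)
        for u, v in itertools.combinations(labels, 2):
            share = bool(set(gc.letters[u]) & set(gc.letters[v]))
            assert share == (gc.dunn_q.loc[u, v] >= 0.05)


class TestMannWhitney:
    def test_fully_tied(self):
        u, p = mann_whitney([2.0] * 6, [2.0] * 4)
        assert u == 12.0 and p == 1.0

    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2], [3, 4])
        assert u == 0.0

    def test_exchange_maps_u(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        u1, p1 = mann_whitney(a, b)
        u2, p2 = mann_whitney(b, a)
        assert u1 + u2 == pytest.approx(len(a) * len(b))
        assert p1 == pytest.approx(p2)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.42])[0] == pytest.approx(0.42)

    def test_stepup_arithmetic(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_q_at_least_p_and_sorted_monotone(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(np.diff(np.sort(q)[np.argsort(np.argsort(np.sort(p)))]) >= -1e-15)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)

    def test_permutation_invariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDescriptive:
    def test_symmetric_data_zero_skew(self):
        d = descriptive([-1.0, 0.0, 1.0])
        assert d.skewness == pytest.approx(0.0)

    def test_constant_data(self):
        d = descriptive([3.0] * 10)
        assert d.stddev == 0.0
        assert np.isnan(d.skewness) and np.isnan(d.kurtosis)

    def test_raw_moment_oracle(self, rng):
        """Bias-corrected moments reduce to the raw Σ(x-x̄)^k/n moments."""
        x = rng.normal(2, 3, 500)
        n = len(x)
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        m4 = ((x - x.mean()) ** 4).mean()
        g1 = m3 / m2**1.5
        skew_adj = g1 * math.sqrt(n * (n - 1)) / (n - 2)
        g2 = m4 / m2**2 - 3
        kurt_adj = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        d = descriptive(x)
        assert d.mean == pytest.approx(x.mean())
        assert d.stddev == pytest.approx(x.std(ddof=1))
        assert d.skewness == pytest.approx(skew_adj, rel=1e-9)
        assert d.kurtosis == pytest.approx(kurt_adj, rel=1e-9)


class TestClinvarEnrichment:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(rows, columns=["state", "clinical_class"])

    def test_sign_of_concentrated_class(self):
        rows = [("order", "pathogenic")] * 30 + [("disorder", "benign")] * 30
        out = clinvar_state_enrichment(self.frame(rows))
        path_order = out[(out["state"] == "order") & (out["clinical_class"] == "pathogenic")]
        ben_order = out[(out["state"] == "order") & (out["clinical_class"] == "benign")]
        assert path_order["log2_or"].iloc[0] > 0
        assert ben_order["log2_or"].iloc[0] < 0

    def test_uniform_distribution_near_zero(self):
        rows = []
        for state in ("order", "disorder"):
            rows += [(state, "pathogenic")] * 20 + [(state, "benign")] * 20
        out = clinvar_state_enrichment(self.frame(rows))
        assert np.allclose(out["log2_or"], 0.0)
        assert (out["q"] == 1.0).all()

    def test_excluded_class_dropped(self):
        rows = [("order", "pathogenic")] * 5 + [("order", "excluded")] * 50 + [
            ("disorder", "benign")
        ] * 5
        out = clinvar_state_enrichment(self.frame(rows))
        assert out["n_class_in_state"].sum() + 0 == 10  # excluded never counted

    def test_stars(self):
        assert significance_stars(0.0001) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.5) == ""
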