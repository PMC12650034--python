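import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fgniche.association import (
    Contingency2x2,
    ac,
    association_network,
    contingency,
    pair_associations,
    pcc,
    to_presence,
    variance_ratio,
    vr_bounds,
    vr_verdict,
    yates_chi2,
)
from .conftest import make_fg_table


# -- independent naive implementations used as oracles ----------------------

def brute_contingency(x, y):
    a = b = c = d = 0
    for xi, yi in zip(x, y):
        if xi and yi:
            a += 1
        elif yi and not xi:
            b += 1
        elif xi and not yi:
            c += 1
        else:
            d += 1
    return a, b, c, d


def brute_vr(mat):
    n_sites, n_fgs = len(mat), len(mat[0])
    sigma2 = 0.0
    for g in range(n_fgs):
        p = sum(mat[j][g] for j in range(n_sites)) / n_sites
        sigma2 += p * (1 - p)
    t = [sum(mat[j]) for j in range(n_sites)]
    tbar = sum(t) / n_sites
    s2 = sum((tj - tbar) ** 2 for tj in t) / n_sites
    return sigma2, s2, s2 / sigma2 if sigma2 else math.nan


tables = st.tuples(*[st.integers(0, 20)] * 4).filter(lambda t: sum(t) >= 2)


class TestPresenceAndContingency:
    def test_all_zero_table_is_all_absent(self):
        assert not to_presence(make_fg_table([[0, 0], [0, 0]])).to_numpy().any()

    def test_any_positive_density_counts_as_present_at_zero_eps(self):
        assert to_presence(make_fg_table([[1e-9]])).iloc[0, 0] == 1

    def test_eps_thresholding_is_strict(self):
        pres = to_presence(make_fg_table([[4, 6]]), eps=5)
        assert pres.iloc[0].tolist() == [0, 1]

    def test_identical_columns_have_no_discordant_sites(self, rng):
        col = rng.integers(0, 2, 10)
        pres = pd.DataFrame({"A": col, "D": col})
        t = contingency(pres, "A", "D")
        assert t.b == t.c == 0

    def test_complementary_columns_never_co_occur(self, rng):
        col = rng.integers(0, 2, 10)
        pres = pd.DataFrame({"A": col, "D": 1 - col})
        t = contingency(pres, "A", "D")
        assert t.a == t.d == 0

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            contingency(pd.DataFrame({"A": [1]}), "A", "Q")

    def test_matches_brute_force_count_on_random_matrices(self, rng):
        for _ in range(500):
            x = rng.integers(0, 2, 12)
            y = rng.integers(0, 2, 12)
            t = contingency(pd.DataFrame({"A": x, "D": y}), "A", "D")
            assert (t.a, t.b, t.c, t.d) == brute_contingency(x, y)
            # swapping the pair swaps the discordant cells
            ts = contingency(pd.DataFrame({"A": x, "D": y}), "D", "A")
            assert (ts.a, ts.b, ts.c, ts.d) == (t.a, t.c, t.b, t.d)


class TestPCC:
    def test_perfect_co_occurrence(self):
        assert pcc(Contingency2x2(4, 0, 0, 4)) == pytest.approx(1.0)

    def test_perfect_exclusion(self):
        assert pcc(Contingency2x2(0, 3, 5, 0)) == pytest.approx(-1.0)

    def test_worked_example(self):
        assert pcc(Contingency2x2(3, 1, 1, 5)) == pytest.approx(14 / 24)

    def test_zero_margin_is_undefined_not_an_exception(self):
        assert math.isnan(pcc(Contingency2x2(3, 0, 2, 0)))

    @given(tables)
    @settings(derandomize=True, deadline=None)
    def test_bounded_and_signed_like_the_determinant(self, cells):
        t = Contingency2x2(*cells)
        v = pcc(t)
        if not math.isnan(v):
            assert -1 - 1e-12 <= v <= 1 + 1e-12
            det = t.a * t.d - t.b * t.c
            assert math.copysign(1, v) == math.copysign(1, det) or det == 0


class TestYatesChi2:
    def test_worked_example(self):
        stat, p = yates_chi2(Contingency2x2(3, 1, 1, 5))
        assert stat == pytest.approx(10 * 81 / 576)
        assert 0 < p < 1

    def test_balanced_independent_table_clamps_to_zero(self):
        stat, _ = yates_chi2(Contingency2x2(5, 5, 5, 5))
        assert stat == 0.0

    def test_zero_margin_undefined(self):
        stat, p = yates_chi2(Contingency2x2(0, 0, 3, 5))
        assert math.isnan(stat) and math.isnan(p)

    @given(tables)
    @settings(derandomize=True, deadline=None)
    def test_uncorrected_statistic_equals_n_phi_squared(self, cells):
        t = Contingency2x2(*cells)
        if 0 in t.margins:
            return
        stat, _ = yates_chi2(t, correction=False)
        assert stat == pytest.approx(t.n * pcc(t) ** 2, abs=1e-10)

    @given(tables)
    @settings(derandomize=True, deadline=None)
    def test_agrees_with_scipy_contingency_routine(self, cells):
        t = Contingency2x2(*cells)
        if 0 in t.margins:
            return
        stat, p = yates_chi2(t)
        # a,b,c,d = both, only-B, only-A, neither -> rows are A, columns B
        res = stats.chi2_contingency([[t.a, t.c], [t.b, t.d]], correction=True)
        assert stat == pytest.approx(res.statistic, abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-10)


class TestAC:
    def test_positive_branch_worked_example(self):
        assert ac(Contingency2x2(3, 1, 1, 5)) == pytest.approx(14 / 24)

    def test_negative_branch_a_not_exceeding_d(self):
        assert ac(Contingency2x2(1, 3, 2, 4)) == pytest.approx(-2 / 12)

    def test_negative_branch_a_exceeding_d(self):
        # bc > ad and a > d -> denominator (b+d)(c+d)
        t = Contingency2x2(3, 4, 5, 1)
        assert ac(t) == pytest.approx((3 - 20) / (5 * 6))

    def test_no_discordance_attains_maximum(self):
        assert ac(Contingency2x2(4, 0, 0, 6)) == pytest.approx(1.0)

    @given(tables)
    @settings(derandomize=True, deadline=None)
    def test_bounded_in_unit_interval(self, cells):
        v = ac(Contingency2x2(*cells))
        if not math.isnan(v):
            assert -1 - 1e-12 <= v <= 1 + 1e-12


class TestVarianceRatio:
    def test_single_group_half_occupied_gives_unit_ratio(self):
        pres = pd.DataFrame({"A": [1, 1, 0, 0]})
        o = variance_ratio(pres)
        assert o.VR == pytest.approx(1.0)
        assert o.W == pytest.approx(o.N)

    def test_perfect_co_occurrence_inflates_richness_variance(self):
        pres = pd.DataFrame({"A": [1, 1, 0, 0], "D": [1, 1, 0, 0]})
        o = variance_ratio(pres)
        assert o.sigma2_T == pytest.approx(0.5)
        assert o.S2_T == pytest.approx(1.0)
        assert o.VR == pytest.approx(2.0)
        assert o.W == pytest.approx(8.0)

    def test_perfect_exclusion_flattens_richness(self):
        pres = pd.DataFrame({"A": [1, 1, 0, 0], "D": [0, 0, 1, 1]})
        o = variance_ratio(pres)
        assert o.S2_T == 0 and o.VR == 0 and o.W == 0

    def test_degenerate_occupancy_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio(pd.DataFrame({"A": [1, 1], "D": [0, 0]}))

    def test_matches_independent_naive_implementation(self, rng):
        done = 0
        while done < 500:
            n_fg = rng.integers(2, 9)
            n_site = rng.integers(2, 13)
            mat = rng.integers(0, 2, (n_site, n_fg))
            sigma2, s2, vr = brute_vr(mat.tolist())
            pres = pd.DataFrame(mat, columns=[f"G{i}" for i in range(n_fg)])
            if sigma2 == 0:
                with pytest.raises(ValueError):
                    variance_ratio(pres)
                continue
            o = variance_ratio(pres)
            assert o.sigma2_T == pytest.approx(sigma2, abs=1e-10)
            assert o.S2_T == pytest.approx(s2, abs=1e-10)
            assert o.VR == pytest.approx(vr, abs=1e-10)
            assert o.W == pytest.approx(vr * n_site, abs=1e-10)
            done += 1

    def test_invariant_under_site_reordering(self, rng):
        mat = rng.integers(0, 2, (10, 5))
        mat[0, 0] = 1; mat[1, 0] = 0
        pres = pd.DataFrame(mat, columns=list("ABCDE"))
        o1 = variance_ratio(pres)
        o2 = variance_ratio(pres.sample(frac=1, random_state=3))
        assert o1.VR == pytest.approx(o2.VR, rel=1e-12)

    def test_mean_near_one_under_independent_occurrences(self, rng):
        vrs = []
        for _ in range(1000):
            mat = (rng.random((12, 6)) < 0.5).astype(int)
            sigma2, s2, vr = brute_vr(mat.tolist())
            if sigma2 > 0:
                vrs.append(s2 / sigma2)
        vrs = np.array(vrs)
        se = vrs.std(ddof=1) / math.sqrt(len(vrs))
        assert abs(vrs.mean() - 1) < 3 * se


class TestVerdict:
    def test_unit_ratio_has_no_association_regardless_of_w(self):
        from fgniche.association import OverallAssociation

        o = OverallAssociation(S=1, N=4, sigma2_T=0.25, S2_T=0.25, VR=1.0, W=4.0)
        assert vr_verdict(o) == "none"

    def test_large_w_is_significant_positive_at_forty_sites(self):
        from fgniche.association import OverallAssociation

        lo, hi = vr_bounds(40)
        assert hi == pytest.approx(stats.chi2.ppf(0.95, 40))
        o = OverallAssociation(S=8, N=40, sigma2_T=1.0, S2_T=70 / 40, VR=70 / 40, W=70.0)
        assert vr_verdict(o) == "significant-positive"

    def test_w_equal_to_site_count_is_not_significant(self):
        from fgniche.association import OverallAssociation

        o = OverallAssociation(S=8, N=40, sigma2_T=1.0, S2_T=0.999, VR=0.999, W=40.0)
        assert vr_verdict(o) == "ns-negative"

    def test_degrees_of_freedom_switch(self):
        lo_n, _ = vr_bounds(40, df="N")
        lo_n1, _ = vr_bounds(40, df="N-1")
        assert lo_n1 == pytest.approx(stats.chi2.ppf(0.05, 39))
        assert lo_n1 < lo_n


class TestPairTableAndNetwork:
    def test_two_group_fixture_yields_single_pair_row(self):
        pres = pd.DataFrame({"A": [1, 0, 1, 0], "D": [1, 1, 0, 0]})
        pairs = pair_associations(pres)
        assert len(pairs) == 1
        assert {"pcc", "chi2", "p", "p_adj", "ac", "sign"} <= set(pairs.columns)

    def test_restrictive_rule_empties_edges_but_keeps_nodes(self, rng):
        mat = rng.integers(0, 2, (10, 4))
        mat[0] = [1, 1, 1, 1]; mat[1] = [0, 0, 0, 0]
        pairs = pair_associations(pd.DataFrame(mat, columns=list("ABCD")))
        pairs["significant"] = False
        edges, nodes, _ = association_network(pairs, include_rule="significant")
        assert edges.empty
        assert nodes == ["A", "B", "C", "D"]

    def test_three_mutual_positives_give_three_positive_edges(self):
        pres = pd.DataFrame(
            {"A": [1, 1, 1, 0, 0], "D": [1, 1, 1, 0, 0], "M": [1, 1, 1, 0, 0]}
        )
        pairs = pair_associations(pres)
        edges, _, counts = association_network(pairs)
        assert counts == {"positive": 3, "negative": 0}
        assert (edges["sign"] == "positive").all()

    def test_edge_counts_recount_pair_table_signs(self, rng):
        mat = rng.integers(0, 2, (15, 6))
        pairs = pair_associations(pd.DataFrame(mat, columns=list("ABCDEF")))
        edges, _, counts = association_network(pairs, include_rule="nonzero")
        assert counts["positive"] == (pairs["sign"] == "positive").sum()
        assert counts["negative"] == (pairs["sign"] == "negative").sum()

    def test_bonferroni_adjustment_uses_pair_count(self):
        pres = pd.DataFrame(
            {c: [1, 0, 1, 0, 1, 1, 0, 0] for c in "AD"}
            | {"M": [1, 1, 0, 0, 1, 0, 1, 0]}
        )
        pairs = pair_associations(pres)
        m = len(pairs)
        ok = ~pairs["p"].isna()
        np.testing.assert_allclose(
            pairs.loc[ok, "p_adj"], np.minimum(1.0, pairs.loc[ok, "p"] * m)
        )
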