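from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import seropanel as sp
from seropanel.stats import (
    ComparisonSpec,
    adjust_bh,
    compare_prevalence,
    fisher_exact_2x2,
    load_covariate_correlation,
    pca_batch_check,
    rank_test_load,
    select_antigens_planar,
)


def enumerate_fisher_two_sided(a, b, c, d):
    """Exact-rational fixed-margin enumeration oracle for the two-sided p."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = comb(n, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), total) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def calls_from_frame(frame: pd.DataFrame) -> sp.CallMatrix:
    return sp.CallMatrix(frame, pd.Series(0.0, index=frame.index), n_factor=1.0)


class TestFisher:
    @pytest.mark.parametrize(
        "table",
        [(0, 10, 0, 10), (3, 2, 1, 4), (6, 119, 1, 167), (20, 105, 17, 151), (5, 0, 0, 5)],
    )
    def test_matches_enumeration_oracle(self, table):
        got = fisher_exact_2x2(*table).p_value
        assert got == pytest.approx(enumerate_fisher_two_sided(*table), abs=1e-12)

    def test_no_positives_p_one(self):
        assert fisher_exact_2x2(0, 10, 0, 10).p_value == 1.0

    def test_one_sided_alternatives_sum_consistently(self):
        a, b, c, d = 7, 3, 2, 8
        greater = fisher_exact_2x2(a, b, c, d, "greater").p_value
        less = fisher_exact_2x2(a, b, c, d, "less").p_value
        # both tails include the observed table's point probability
        point = sps.hypergeom(20, 9, 10).pmf(7)
        assert greater + less == pytest.approx(1 + point)

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b == 0 or c + d == 0 or a + c + b + d == 0:
                continue
            ours = fisher_exact_2x2(int(a), int(b), int(c), int(d)).p_value
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_row_and_column_swap_invariance(self):
        a, b, c, d = 9, 4, 3, 11
        p = fisher_exact_2x2(a, b, c, d).p_value
        assert fisher_exact_2x2(c, d, a, b).p_value == pytest.approx(p)
        assert fisher_exact_2x2(b, a, d, c).p_value == pytest.approx(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_zero_cell_odds_ratio_haldane_flagged(self):
        res = fisher_exact_2x2(5, 5, 0, 10)
        assert res.haldane_corrected
        assert np.isfinite(res.odds_ratio)
        assert not fisher_exact_2x2(3, 2, 1, 4).haldane_corrected


class TestComparePrevalence:
    def test_planted_antigen_has_smallest_p_and_flag(self, rng):
        n1, n2 = 60, 60
        frame = pd.DataFrame(
            (rng.random((n1 + n2, 10)) < 0.05).astype(int),
            index=[f"s{i}" for i in range(n1 + n2)],
            columns=[f"a{j}" for j in range(10)],
        )
        frame.iloc[:n1, 0] = (rng.random(n1) < 0.4).astype(int)
        frame.iloc[n1:, 0] = (rng.random(n2) < 0.1).astype(int)
        meta = pd.DataFrame(
            {"group": ["AAV"] * n1 + ["HC"] * n2},
            index=frame.index,
        )
        results = compare_prevalence(
            calls_from_frame(frame), meta, ComparisonSpec("group", "AAV", "HC")
        )
        best = min(results, key=lambda r: r.p_value)
        assert best.antigen_id == "a0"
        assert best.passes_gap

    def test_identical_groups_zero_gap(self, rng):
        frame = pd.DataFrame(
            (rng.random((30, 5)) < 0.3).astype(int),
            index=[f"s{i}" for i in range(30)],
            columns=list("abcde"),
        )
        meta = pd.DataFrame({"g": ["x"] * 30}, index=frame.index)
        doubled = pd.concat(
            [frame.rename(index=lambda s: s + "_1"), frame.rename(index=lambda s: s + "_2")]
        )
        meta2 = pd.DataFrame(
            {"g": ["x"] * 30 + ["y"] * 30}, index=doubled.index
        )
        results = compare_prevalence(
            calls_from_frame(doubled), meta2, ComparisonSpec("g", "x", "y")
        )
        assert all(r.prevalence_gap == 0 for r in results)
        assert all(r.p_value == 1.0 for r in results)

    def test_group_swap_reciprocal_odds(self, rng):
        frame = pd.DataFrame(
            (rng.random((40, 4)) < 0.3).astype(int),
            index=[f"s{i}" for i in range(40)],
            columns=list("abcd"),
        )
        meta = pd.DataFrame({"g": ["x"] * 20 + ["y"] * 20}, index=frame.index)
        fwd = compare_prevalence(calls_from_frame(frame), meta, ComparisonSpec("g", "x", "y"))
        rev = compare_prevalence(calls_from_frame(frame), meta, ComparisonSpec("g", "y", "x"))
        for f, r in zip(fwd, rev):
            assert f.p_value == pytest.approx(r.p_value)
            if not f.haldane_corrected and f.odds_ratio > 0:
                assert f.odds_ratio == pytest.approx(1 / r.odds_ratio)

    def test_empty_group_is_error_naming_level(self, rng):
        frame = pd.DataFrame([[1, 0]], index=["s1"], columns=["a", "b"])
        meta = pd.DataFrame({"g": ["x"]}, index=["s1"])
        with pytest.raises(ValueError, match="'y'"):
            compare_prevalence(calls_from_frame(frame), meta, ComparisonSpec("g", "x", "y"))

    def test_bh_adjustment_attached(self, phase2_cohort):
        calls = sp.call_reactivity(phase2_cohort["matrix"], sp.CutoffSpec(50.0))
        results = compare_prevalence(
            calls,
            phase2_cohort["metadata"],
            ComparisonSpec("group", "AAV", "HC", bh_adjust=True),
        )
        qs = np.array([r.q_value for r in results])
        ps = np.array([r.p_value for r in results])
        assert (qs >= ps - 1e-12).all() and (qs <= 1.0).all()


class TestRankTests:
    def test_identical_groups_exact_p_one(self):
        loads = pd.Series([1, 2, 3, 1, 2, 3], index=list("abcdef"), name="load")
        meta = pd.DataFrame({"g": ["x"] * 3 + ["y"] * 3}, index=loads.index)
        res = rank_test_load(loads, meta, "g")
        assert res.p_value == 1.0
        assert res.test == "mann_whitney_exact"

    def test_fully_separated_small_groups(self):
        loads = pd.Series([1, 2, 3, 101, 102, 103], index=list("abcdef"), name="load")
        meta = pd.DataFrame({"g": ["x"] * 3 + ["y"] * 3}, index=loads.index)
        res = rank_test_load(loads, meta, "g")
        assert res.p_value == pytest.approx(0.1)  # smallest attainable two-sided p at 3 vs 3

    def test_three_groups_use_kruskal(self, rng):
        loads = pd.Series(rng.poisson(5, 90), index=[f"s{i}" for i in range(90)], name="load")
        meta = pd.DataFrame({"g": ["x", "y", "z"] * 30}, index=loads.index)
        res = rank_test_load(loads, meta, "g")
        assert res.test == "kruskal_wallis"
        ref = sps.kruskal(*[loads[meta["g"] == lvl] for lvl in ("x", "y", "z")])
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_shifted_groups_direction_matches_medians(self, rng):
        n = 80
        loads = pd.Series(
            np.concatenate([rng.poisson(5, n), rng.poisson(4, n)]),
            index=[f"s{i}" for i in range(2 * n)],
            name="load",
        )
        meta = pd.DataFrame({"sex": ["M"] * n + ["F"] * n}, index=loads.index)
        res = rank_test_load(loads, meta, "sex", levels=["F", "M"])
        assert res.group_medians["M"] >= res.group_medians["F"]
        assert 0 <= res.p_value <= 1

    def test_single_group_is_error(self):
        loads = pd.Series([1, 2], index=["a", "b"], name="load")
        meta = pd.DataFrame({"g": ["x", "x"]}, index=loads.index)
        with pytest.raises(ValueError):
            rank_test_load(loads, meta, "g")


class TestCorrelation:
    def test_perfect_and_reversed_ranks(self):
        loads = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        rho, _ = load_covariate_correlation(loads, loads.copy())
        assert rho == pytest.approx(1.0)
        rho, _ = load_covariate_correlation(loads, -loads)
        assert rho == pytest.approx(-1.0)

    def test_independent_covariate_small_rho(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            loads = pd.Series(rng.poisson(5, 200), index=[f"s{i}" for i in range(200)])
            cov = pd.Series(rng.normal(size=200), index=loads.index)
            rho, _ = load_covariate_correlation(loads, cov)
            assert abs(rho) < 0.2

    def test_missing_pairs_excluded_listwise(self):
        loads = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        cov = pd.Series([1.0, np.nan, 3, 4], index=list("abcd"))
        rho, _ = load_covariate_correlation(loads, cov)
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_error(self):
        loads = pd.Series([1.0, 2], index=list("ab"))
        with pytest.raises(ValueError):
            load_covariate_correlation(loads, loads)


class TestPlanarSelection:
    def test_boundary_inclusion(self):
        frame = pd.DataFrame(
            {"a": [1, 1, 0, 0], "b": [1, 0, 0, 0], "c": [0, 0, 0, 0]},
            index=[f"s{i}" for i in range(4)],
        )
        assert select_antigens_planar(calls_from_frame(frame), 2) == ["a"]

    def test_planted_recurrent_antigens_recovered(self, rng):
        """80-sample screen: exactly the 40 planted recurrent antigens pass."""
        n_samples, n_antigens = 80, 100
        calls = np.zeros((n_samples, n_antigens), dtype=int)
        recurrent = rng.choice(n_antigens, size=40, replace=False)
        for j in range(n_antigens):
            k = rng.integers(2, 6) if j in recurrent else rng.integers(0, 2)
            calls[rng.choice(n_samples, size=k, replace=False), j] = 1
        frame = pd.DataFrame(
            calls,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"a{j}" for j in range(n_antigens)],
        )
        selected = select_antigens_planar(calls_from_frame(frame), 2)
        assert sorted(selected) == sorted(f"a{j}" for j in recurrent)


class TestPca:
    def test_identical_samples_identical_scores(self):
        data = pd.DataFrame(
            [[1.0, 2, 3, 1], [1.0, 2, 3, 1], [4.0, 0, 1, 2]],
            index=["s1", "s2", "s3"],
            columns=list("abcd"),
        )
        nmad = sp.NMadMatrix(data, data.median(axis=1), data.std(axis=1))
        res = pca_batch_check(nmad, n_components=2)
        np.testing.assert_allclose(
            res.scores.loc["s1"], res.scores.loc["s2"], atol=1e-10
        )

    def test_rank_one_matrix_single_component(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=8)
        data = pd.DataFrame(np.outer(u, v), index=[f"s{i}" for i in range(10)],
                            columns=[f"a{j}" for j in range(8)])
        nmad = sp.NMadMatrix(data, data.median(axis=1), data.std(axis=1))
        res = pca_batch_check(nmad, n_components=3)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_no_site_effect_no_site_separation(self):
        """With site_effect_log_sd = 0 the PC1 between-site variance stays
        below 10% of the total PC1 variance."""
        import dataclasses

        config = dataclasses.replace(sp.phase_config("phase2", seed=4), site_effect_log_sd=0.0)
        matrix, samples, _, _ = sp.generate_cohort(config)
        meta = sp.samples_to_frame(samples)
        nmad = sp.normalize_nmad(matrix)
        res = pca_batch_check(nmad, n_components=2)
        pc1 = res.scores["PC1"]
        grand = pc1.var(ddof=0)
        between = sum(
            len(ids) * (pc1.loc[ids].mean() - pc1.mean()) ** 2
            for _, ids in pc1.groupby(meta["site"]).groups.items()
        ) / len(pc1)
        assert between / grand < 0.10


class TestAdjustBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.04])[0] == pytest.approx(0.04)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(adjust_bh([0.2] * 5), 0.2)

    def test_matches_direct_step_up_formula(self, rng):
        p = rng.random(40)
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(adjust_bh(p), expected, rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_never_decreases_and_capped(self, ps):
        q = adjust_bh(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])
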