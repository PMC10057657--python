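"""The moderated-statistics core against hand computations and oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mirtriage.io import ExpressionMatrix
from mirtriage.stats import (
    EbayesPrior,
    FilterSpec,
    benjamini_hochberg,
    de_filter,
    estimate_ebayes_prior,
    fit_groups,
    moderated_f,
    moderated_t,
    run_de,
    signed_fc,
    tukey_biweight,
)


class TestTukeyBiweight:
    def test_constant_input(self):
        assert tukey_biweight([3.0, 3.0, 3.0]) == 3.0

    def test_symmetric_input_gives_median(self):
        assert tukey_biweight([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_outlier_downweighted(self):
        # median 1, MAD 0 -> scale eps only: the outlier gets weight 0,
        # the three on-median points weight 1, so the summary is exactly 1.0
        val = tukey_biweight([1.0, 1.0, 1.0, 10.0], c=5, eps=1e-4)
        assert val == pytest.approx(1.0)
        assert val < np.mean([1.0, 1.0, 1.0, 10.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tukey_biweight([])

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=20)
    )
    @settings(deadline=None, derandomize=True)
    def test_bounded_by_input_range_and_mean_limit(self, xs):
        val = tukey_biweight(xs)
        assert min(xs) - 1e-12 <= val <= max(xs) + 1e-12
        # as c -> infinity every weight tends to 1, so the summary tends
        # to the arithmetic mean -- provided the MAD scale is nonzero
        # (with MAD = 0 the scale stays at eps regardless of c)
        med = np.median(xs)
        if np.median(np.abs(np.asarray(xs) - med)) > 1e-3:
            assert tukey_biweight(xs, c=1e12) == pytest.approx(np.mean(xs), abs=1e-6)


class TestSignedFC:
    @pytest.mark.parametrize("d,expected", [(0.0, 1.0), (1.0, 2.0), (-1.0, -2.0)])
    def test_definition(self, d, expected):
        assert signed_fc(d) == expected

    def test_published_value_miR509(self):
        # the -1.85-fold-down call corresponds to a log2 difference of -0.8875
        assert signed_fc(-0.8875) == pytest.approx(-1.85, abs=0.005)

    @given(st.floats(min_value=0.01, max_value=30))
    @settings(deadline=None, derandomize=True)
    def test_odd_under_negation_and_magnitude_floor(self, d):
        assert signed_fc(-d) == pytest.approx(-signed_fc(d))
        assert abs(signed_fc(d)) >= 1.0
        assert abs(signed_fc(-d)) >= 1.0


class TestFitGroups:
    def test_two_group_exact_fit(self):
        values = pd.DataFrame(
            {"a": [1.0], "b": [1.0], "c": [3.0], "d": [3.0]}, index=["f"]
        )
        fit = fit_groups(
            ExpressionMatrix(values, {"a": "N", "b": "N", "c": "T", "d": "T"})
        )
        assert fit.means.loc["f", "N"] == 1.0
        assert fit.means.loc["f", "T"] == 3.0
        assert fit.d_g == 2
        assert fit.zero_variance.loc["f"]  # raw pooled variance is 0

    def test_three_group_pooled_variance(self):
        # N={0,2}, T={1,3}, F1={2,4}: means 1,2,3; within-group SS = 2 each
        # -> pooled s^2 = 6/3 = 2 with d_g = 3
        values = pd.DataFrame(
            {"n1": [0.0], "n2": [2.0], "t1": [1.0], "t2": [3.0], "f1": [2.0], "f2": [4.0]},
            index=["f"],
        )
        fit = fit_groups(
            ExpressionMatrix(
                values,
                {"n1": "N", "n2": "N", "t1": "T", "t2": "T", "f1": "F1", "f2": "F1"},
            )
        )
        assert list(fit.means.loc["f"]) == [1.0, 2.0, 3.0]
        assert fit.s_sq.loc["f"] == pytest.approx(2.0)
        assert fit.d_g == 3

    def test_single_sample_group_rejected(self):
        values = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["f"])
        with pytest.raises(ValueError, match="variance undefined"):
            fit_groups(ExpressionMatrix(values, {"a": "N", "b": "N", "c": "T"}))


class TestEbayesPrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_ebayes_prior(np.full(50, 0.25), d_g=4)
        assert math.isinf(prior.d0)
        # the moment-matched s0^2 under infinite d0 is exp(mean(e_g))
        half = 2.0
        from scipy.special import digamma

        expected = math.exp(math.log(0.25) - digamma(half) + math.log(half))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-12)

    def test_recovers_known_hyperparameters(self):
        # 200 variances from the hierarchical model with d0=4, s0^2=0.05
        rng = np.random.default_rng(7)
        d0, s0_sq, d_g, n = 4.0, 0.05, 3, 200
        sigma_sq = d0 * s0_sq / rng.chisquare(d0, n)
        s_sq = sigma_sq * rng.chisquare(d_g, n) / d_g
        prior = estimate_ebayes_prior(s_sq, d_g)
        assert abs(prior.d0 - d0) / d0 <= 0.5
        assert abs(prior.s0_sq - s0_sq) / s0_sq <= 0.25

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            estimate_ebayes_prior([0.1], d_g=3)


class TestModeratedT:
    def test_zero_diff_gives_null(self):
        prior = EbayesPrior(d0=4.0, s0_sq=0.1)
        t, p = moderated_t(np.array([0.0]), 0.5, np.array([0.2]), 3, prior)
        assert t[0] == 0.0
        assert p[0] == 1.0

    def test_hand_computed_fixture(self):
        # s~^2 = (4*0.1 + 3*0.2)/7 = 1/7; t = 1/sqrt(s~^2 * 0.5)
        prior = EbayesPrior(d0=4.0, s0_sq=0.1)
        t, p = moderated_t(np.array([1.0]), 0.5, np.array([0.2]), 3, prior)
        s_tilde_sq = (4 * 0.1 + 3 * 0.2) / 7
        assert t[0] == pytest.approx(1.0 / math.sqrt(s_tilde_sq * 0.5), rel=1e-12)
        assert p[0] == pytest.approx(2 * sps.t.sf(t[0], df=7), rel=1e-12)

    def test_d0_zero_equals_classical_pooled_t(self):
        rng = np.random.default_rng(0)
        prior = EbayesPrior(d0=0.0, s0_sq=1.0)
        for _ in range(100):
            na, nb = rng.integers(3, 8, size=2)
            a, b = rng.normal(0, 1, na), rng.normal(0.5, 1, nb)
            values = pd.DataFrame(
                [np.concatenate([a, b])],
                index=["f"],
                columns=[f"s{i}" for i in range(na + nb)],
            )
            groups = {f"s{i}": ("N" if i < na else "T") for i in range(na + nb)}
            fit = fit_groups(ExpressionMatrix(values, groups))
            diff = fit.means.loc["f", "T"] - fit.means.loc["f", "N"]
            t, p = moderated_t(
                np.array([diff]), 1 / na + 1 / nb, fit.s_sq.to_numpy(), fit.d_g, prior
            )
            ref = sps.ttest_ind(b, a)
            assert t[0] == pytest.approx(ref.statistic, abs=1e-10)
            assert p[0] == pytest.approx(ref.pvalue, abs=1e-10)


class TestModeratedF:
    def test_equal_means_give_zero_F(self):
        values = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [3.0, 2.5], "c": [1.0, 2.0], "d": [3.0, 2.5],
             "e": [1.0, 2.0], "f": [3.0, 2.5]},
            index=["f1", "f2"],
        )
        fit = fit_groups(
            ExpressionMatrix(
                values, {"a": "N", "b": "N", "c": "T", "d": "T", "e": "F1", "f": "F1"}
            )
        )
        F, p = moderated_f(fit, EbayesPrior(d0=4.0, s0_sq=0.5))
        assert np.allclose(F, 0.0)
        assert np.allclose(p, 1.0)

    def test_d0_zero_equals_classical_anova(self):
        rng = np.random.default_rng(1)
        prior = EbayesPrior(d0=0.0, s0_sq=1.0)
        for _ in range(100):
            ns = rng.integers(2, 6, size=3)
            samples = [rng.normal(m, 1, n) for m, n in zip((0, 0.3, 1.0), ns)]
            cols, groups = [], {}
            row = np.concatenate(samples)
            i = 0
            for g, arr in zip(("N", "T", "F1"), samples):
                for _ in arr:
                    cols.append(f"s{i}")
                    groups[f"s{i}"] = g
                    i += 1
            values = pd.DataFrame([row], index=["f"], columns=cols)
            fit = fit_groups(ExpressionMatrix(values, groups))
            F, p = moderated_f(fit, prior)
            ref = sps.f_oneway(*samples)
            assert F[0] == pytest.approx(ref.statistic, abs=1e-10)
            assert p[0] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_hand_computed_fixture(self):
        # means 1,2,3 with n=2 each: SSB = 2*((1-2)^2+(3-2)^2) = 4, MSB = 2
        values = pd.DataFrame(
            {"n1": [0.0], "n2": [2.0], "t1": [1.0], "t2": [3.0], "f1": [2.0], "f2": [4.0]},
            index=["f"],
        )
        fit = fit_groups(
            ExpressionMatrix(
                values,
                {"n1": "N", "n2": "N", "t1": "T", "t2": "T", "f1": "F1", "f2": "F1"},
            )
        )
        prior = EbayesPrior(d0=4.0, s0_sq=0.1)
        F, p = moderated_f(fit, prior)
        s_tilde_sq = (4 * 0.1 + 3 * 2.0) / 7
        assert F[0] == pytest.approx(2.0 / s_tilde_sq, rel=1e-12)
        assert p[0] == pytest.approx(sps.f.sf(F[0], 2, 7), rel=1e-12)


def _bh_oracle(p):
    """Independent brute force: adj_i = min over candidate thresholds
    t >= p_i of n*t/#{j: p_j <= t}, scanning every observed p as t."""
    n = len(p)
    out = []
    for pi in p:
        cands = [
            n * t / sum(1 for q in p if q <= t) for t in p if t >= pi
        ]
        out.append(min(1.0, min(cands)))
    return out


class TestBenjaminiHochberg:
    def test_hand_example(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_and_singleton(self):
        assert np.allclose(benjamini_hochberg([0.3, 0.3, 0.3]), 0.3)
        assert benjamini_hochberg([0.7]) == pytest.approx([0.7])

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                benjamini_hochberg(bad)

    def test_matches_brute_force_on_grid_vectors(self):
        import itertools

        grid = [0.001, 0.02, 0.3, 0.77, 1.0]
        for length in range(1, 7):
            for p in itertools.product(grid, repeat=length):
                assert np.allclose(
                    benjamini_hochberg(list(p)), _bh_oracle(list(p))
                ), p

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30
        ),
        st.randoms(use_true_random=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_permutation_invariant_and_dominates_raw_p(self, ps, rnd):
        adj = benjamini_hochberg(ps)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        adj_perm = benjamini_hochberg([ps[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm)
        assert np.all(adj >= np.asarray(ps) - 1e-15)


class TestDeFilter:
    COLS = ["feature_id", "fold_change", "p_value", "f_fdr"]

    def _frame(self, rows):
        return pd.DataFrame(rows, columns=self.COLS)

    def test_boundary_fc_inclusive(self):
        df = self._frame([("hsa-miR-x", 1.5, 0.04, 0.004)])
        assert len(de_filter(df)) == 1

    def test_species_filter_drops_mouse(self):
        df = self._frame([("mmu-miR-x", 2.0, 0.04, 0.004)])
        assert de_filter(df).empty

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        spec = FilterSpec()
        for _ in range(20):
            rows = []
            for i in range(30):
                prefix = rng.choice(["hsa", "mmu", "rno"])
                fc = float(rng.choice([-1, 1]) * rng.uniform(1.0, 4.0))
                rows.append(
                    (
                        f"{prefix}-miR-{i}",
                        fc,
                        float(rng.uniform(0, 0.1)),
                        float(rng.uniform(0, 0.01)),
                    )
                )
            df = self._frame(rows)
            expected = sorted(
                (
                    r
                    for r in rows
                    if abs(r[1]) >= 1.5
                    and r[2] < 0.05
                    and r[3] < 0.005
                    and r[0].startswith("hsa")
                ),
                key=lambda r: -r[1],
            )
            got = de_filter(df, spec)
            assert [r[0] for r in expected] == list(got["feature_id"])

    def test_six_row_example_keeps_exactly_two(self):
        rows = [
            ("hsa-miR-1", 2.0, 0.01, 0.001),   # keep
            ("hsa-miR-2", -1.6, 0.04, 0.004),  # keep
            ("hsa-miR-3", 1.4, 0.01, 0.001),   # |FC| below
            ("hsa-miR-4", 2.0, 0.06, 0.001),   # p too big
            ("hsa-miR-5", 2.0, 0.01, 0.006),   # F-FDR too big
            ("mmu-miR-6", 2.0, 0.01, 0.001),   # wrong species
        ]
        got = de_filter(self._frame(rows))
        assert list(got["feature_id"]) == ["hsa-miR-1", "hsa-miR-2"]


class TestNullCalibration:
    def test_moderated_p_uniform_under_null(self):
        rng = np.random.default_rng(12)
        n = 2000
        cols = [f"s{i}" for i in range(20)]
        groups = {c: ("N" if i < 5 else "T" if i < 12 else "F1") for i, c in enumerate(cols)}
        values = pd.DataFrame(
            rng.normal(7, 0.3, size=(n, 20)), index=[f"f{i}" for i in range(n)], columns=cols
        )
        fit = fit_groups(ExpressionMatrix(values, groups))
        prior = estimate_ebayes_prior(fit.s_sq.to_numpy(), fit.d_g)
        diff = (fit.means["T"] - fit.means["N"]).to_numpy()
        _, p = moderated_t(diff, 1 / 7 + 1 / 5, fit.s_sq.to_numpy(), fit.d_g, prior)
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01


def test_run_de_output_schema(toy_matrix):
    tables = run_de(toy_matrix)
    assert set(tables) == {"TvN", "F1vT"}
    for t in tables.values():
        assert list(t.columns) == [
            "feature_id", "log2_diff", "fold_change", "t_mod",
            "p_value", "fdr", "f_fdr", "passes_filter",
        ]
        assert np.allclose(t["fold_change"], signed_fc(t["log2_diff"].to_numpy()))
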