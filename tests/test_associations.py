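import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from microstab.associations import (
    adjust_p,
    fisher_exact,
    fisher_exact_enumeration,
    forward_aic_glm,
    kolmogorov_smirnov,
    kruskal_wallis,
    permanova,
    students_t,
    taxon_symptom_screen,
    wilcoxon_signed_rank,
)


class TestFisher:
    def test_flat_table_p_one(self):
        assert fisher_exact([[1, 1], [1, 1]]).p == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        # margins (5,5,5,5): only the two extreme tables are as improbable
        assert fisher_exact([[5, 0], [0, 5]]).p == pytest.approx(2 / 252)

    def test_against_enumeration_oracle_sample(self):
        assert fisher_exact([[12, 10], [3, 17]]).p == pytest.approx(
            fisher_exact_enumeration([[12, 10], [3, 17]]), abs=1e-12
        )

    def test_against_enumeration_oracle_random(self, rng):
        for _ in range(50):
            t = rng.integers(0, 10, size=(2, 2))
            assert fisher_exact(t).p == pytest.approx(
                fisher_exact_enumeration(t), abs=1e-10
            )

    def test_bad_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestRankTests:
    def test_identical_groups_h_zero(self):
        v = pd.Series([2.0] * 10)
        g = pd.Series(["a"] * 5 + ["b"] * 5)
        res = kruskal_wallis(v, g)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_kruskal_power_on_planted_shift(self, rng):
        rejections = 0
        for _ in range(100):
            v = pd.Series(np.concatenate([rng.normal(0, 1, 50),
                                          rng.normal(1, 1, 50)]))
            g = pd.Series(["a"] * 50 + ["b"] * 50)
            rejections += kruskal_wallis(v, g).p < 0.05
        assert rejections >= 90

    def test_wilcoxon_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(np.zeros(10))

    def test_wilcoxon_exact_small_samples(self, rng):
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0.5, 0.1, 12)
        res = wilcoxon_signed_rank(x, y)
        assert res.extras["method"] == "exact"

    def test_students_t_two_groups_only(self):
        v = pd.Series([1.0, 2.0, 3.0])
        g = pd.Series(["a", "b", "c"])
        with pytest.raises(ValueError):
            students_t(v, g)

    def test_ks_constant_vector(self):
        res = kolmogorov_smirnov([3.0, 3.0, 3.0])
        assert res.p == 1.0


class TestAdjustP:
    def test_single_p_unchanged(self):
        assert adjust_p([0.03])[0] == pytest.approx(0.03)

    def test_bonferroni_multiplies(self):
        assert adjust_p([0.01] * 5, "bonferroni")[0] == pytest.approx(0.05)

    def test_bh_matches_stepup_oracle(self, rng):
        # brute-force step-up: q_i = min_{j>=i} p_(j) * m / j
        for _ in range(20):
            p = rng.uniform(0, 1, 12)
            order = np.argsort(p)
            m = len(p)
            ranked = p[order]
            q = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q, 1.0)
            np.testing.assert_allclose(adjust_p(p, "BH"), expected, atol=1e-12)

    def test_bonferroni_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 10)
        assert (adjust_p(p, "bonferroni") >= p - 1e-15).all()


class TestPermanova:
    def make_dm(self, rng, n=30, shift=0.0):
        x = rng.normal(size=(n, 4))
        x[: n // 2] += shift
        d = squareform(pdist(x))
        ids = [f"S{i}_T0" for i in range(n)]
        g = pd.Series(["a"] * (n // 2) + ["b"] * (n - n // 2), index=ids)
        return DistanceMatrix(d, ids=ids), g

    def test_matches_skbio_single_factor(self, rng):
        dm, g = self.make_dm(rng, shift=1.0)
        mine = permanova(dm, g.to_frame("grp"), n_perm=999, seed=0)
        sk = skbio_permanova(dm, grouping=g.values, permutations=0)
        assert mine.loc["grp", "pseudo_F"] == pytest.approx(
            float(sk["test statistic"]), rel=1e-9
        )

    def test_separated_clusters_minimal_p(self, rng):
        dm, g = self.make_dm(rng, shift=30.0)
        res = permanova(dm, g.to_frame("grp"), n_perm=999, seed=0)
        assert res.loc["grp", "p"] == pytest.approx(1 / 1000)

    def test_deterministic_under_seed(self, rng):
        dm, g = self.make_dm(rng, shift=0.5)
        a = permanova(dm, g.to_frame("grp"), n_perm=199, seed=5)
        b = permanova(dm, g.to_frame("grp"), n_perm=199, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_to_consistent_relabeling(self, rng):
        dm, g = self.make_dm(rng, shift=0.8)
        perm = rng.permutation(len(g))
        ids_p = [dm.ids[i] for i in perm]
        dm_p = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=ids_p)
        a = permanova(dm, g.to_frame("grp"), n_perm=499, seed=3)
        b = permanova(dm_p, g.loc[ids_p].to_frame("grp"), n_perm=499, seed=3)
        assert a.loc["grp", "pseudo_F"] == pytest.approx(
            b.loc["grp", "pseudo_F"], rel=1e-9
        )

    def test_single_level_factor_rejected(self, rng):
        dm, g = self.make_dm(rng)
        bad = pd.Series(["x"] * len(g), index=g.index)
        with pytest.raises(ValueError):
            permanova(dm, bad.to_frame("grp"), n_perm=99)

    def test_sequential_two_factors_sum_to_total(self, rng):
        dm, g = self.make_dm(rng, shift=1.0)
        f2 = pd.Series(rng.choice(["u", "v"], size=len(g)), index=g.index)
        res = permanova(dm, pd.DataFrame({"grp": g, "other": f2}),
                        n_perm=99, seed=0)
        total = res.loc["Total", "SumOfSqs"]
        parts = res.drop("Total")["SumOfSqs"].sum()
        assert parts == pytest.approx(total, rel=1e-9)


class TestForwardAicGlm:
    def test_no_candidates_residual_100(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        out = forward_aic_glm(y, pd.DataFrame(index=y.index))
        assert out.loc["Residuals", "Variation Explained (%)"] == pytest.approx(100.0)

    def test_noiseless_linear_signal_first_and_full(self, rng):
        n = 60
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = pd.Series(3.0 * x1)
        cand = pd.DataFrame({"x1": x1, "x2": x2})
        out = forward_aic_glm(y, cand, mode="stop")
        assert out.index[0] == "x1"
        assert out.loc["x1", "Variation Explained (%)"] == pytest.approx(100.0, abs=1e-6)

    def test_output_schema(self, rng):
        y = pd.Series(rng.normal(size=40))
        cand = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        out = forward_aic_glm(y, cand, mode="full")
        assert list(out.columns) == ["Df", "Deviance", "AIC", "Pr(>Chi)",
                                     "Variation Explained (%)"]
        assert out.index[-1] == "Residuals"

    def test_percentages_sum_to_100(self, rng):
        n = 50
        cand = pd.DataFrame({
            "a": rng.normal(size=n), "b": rng.normal(size=n),
            "c": rng.choice(["p", "q"], size=n),
        })
        y = pd.Series(0.5 * cand["a"] + rng.normal(0, 1, n))
        out = forward_aic_glm(y, cand, mode="full")
        assert out["Variation Explained (%)"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_orthogonal_predictors_match_marginal_r2(self, rng):
        # exactly orthogonal columns: sequential shares equal marginal R^2
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y_arr = 2 * x1 + 1 * x2 + rng.normal(0, 0.5, n)
        y = pd.Series(y_arr)
        cand = pd.DataFrame({"x1": x1, "x2": x2})
        out = forward_aic_glm(y, cand, mode="full")
        for col, x in [("x1", x1), ("x2", x2)]:
            r2 = np.corrcoef(x, y_arr)[0, 1] ** 2
            assert out.loc[col, "Variation Explained (%)"] == pytest.approx(
                100 * r2, abs=1e-6
            )

    def test_zero_variance_candidate_warned(self, rng):
        y = pd.Series(rng.normal(size=30))
        cand = pd.DataFrame({"flat": np.ones(30), "x": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="flat"):
            forward_aic_glm(y, cand, mode="full")

    def test_complete_cases_only(self, rng):
        y = pd.Series(rng.normal(size=30))
        cand = pd.DataFrame({"x": rng.normal(size=30)})
        cand.iloc[0, 0] = np.nan
        out = forward_aic_glm(y, cand, mode="full")
        # residual df reflects the dropped row: n=29 rows, intercept + x
        assert out.loc["Residuals", "Df"] == 27


class TestTaxonScreen:
    def test_planted_link_ranked_first(self, rng):
        n = 120
        lacto = rng.uniform(0, 1, n)
        rel = pd.DataFrame({
            f"S{i}_T0": [lacto[i], 1 - lacto[i], rng.uniform(0, 0.1)]
            for i in range(n)
        }, index=["Lactobacillus", "Prevotella", "Noise"])
        symptom = pd.Series(
            (4 * (1 - lacto) + rng.normal(0, 0.5, n)).round().clip(0, 4),
            index=rel.columns,
        )
        out = taxon_symptom_screen(rel, symptom, ordinal=True)
        assert out.index[0] == "Lactobacillus"
        assert out.iloc[0]["q"] < 0.05
        assert out.iloc[0]["direction"] == -1

    def test_null_calibration(self, rng):
        n = 100
        hits = []
        for _ in range(20):
            rel = pd.DataFrame(
                rng.uniform(0, 1, size=(10, n)),
                index=[f"g{i}" for i in range(10)],
                columns=[f"S{i}_T0" for i in range(n)],
            )
            symptom = pd.Series(rng.integers(0, 5, n), index=rel.columns)
            out = taxon_symptom_screen(rel, symptom, ordinal=True)
            hits.append((out["q"] < 0.05).mean())
        assert np.mean(hits) <= 0.05

    def test_all_zero_taxon_skipped(self, rng):
        rel = pd.DataFrame({
            "S0_T0": [0.0, 1.0], "S1_T0": [0.0, 1.0], "S2_T0": [0.0, 0.5],
        }, index=["zero", "ok"])
        symptom = pd.Series([1, 2, 3], index=rel.columns)
        with pytest.warns(UserWarning, match="zero"):
            out = taxon_symptom_screen(rel, symptom)
        assert "zero" not in out.index
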