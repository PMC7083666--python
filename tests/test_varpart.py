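import numpy as np
import pandas as pd
import pytest

import streammeta as sm


class TestHellinger:
    def test_hand_example(self):
        raw = pd.DataFrame([[1, 4, 4]], index=["s"], columns=list("ABC"))
        out = sm.hellinger(raw).data
        assert out.iloc[0].tolist() == pytest.approx([1 / 3, 2 / 3, 2 / 3])

    def test_single_taxon_row(self):
        out = sm.hellinger(pd.DataFrame([[5]], index=["s"], columns=["A"])).data
        assert out.iloc[0, 0] == 1.0

    def test_unit_row_sums_of_squares(self, small_community):
        out = sm.hellinger(small_community).data.to_numpy()
        assert np.allclose((out**2).sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_rejected_with_site_list(self):
        raw = pd.DataFrame([[1, 2], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            sm.hellinger(raw)


class TestLogEnv:
    def test_values_before_standardization(self):
        env = pd.DataFrame({"v": [0.0, np.e - 1]})
        out = sm.log1p_env(env, standardize=False)
        assert out["v"].tolist() == pytest.approx([0.0, 1.0])

    def test_standardized_columns(self):
        rng = np.random.default_rng(0)
        env = pd.DataFrame(rng.random((12, 3)) * 10)
        out = sm.log1p_env(env)
        assert np.allclose(out.mean(), 0.0, atol=1e-12)
        assert np.allclose(out.std(ddof=1), 1.0, atol=1e-12)

    def test_entries_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError, match="-1"):
            sm.log1p_env(pd.DataFrame({"v": [-1.0, 0.0]}))


class TestRdaR2:
    def test_perfect_fit(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 3))
        Y = X @ rng.standard_normal((3, 4))
        assert sm.rda_r2(Y, X) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictor_gives_zero(self):
        n = 12
        y = np.zeros((n, 2))
        y[:, 0] = np.tile([1.0, -1.0], n // 2)
        y[:, 1] = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        x = np.arange(n, dtype=float)[:, None]
        x = x - x.mean()
        # make x exactly orthogonal to the centered y columns
        yc = y - y.mean(axis=0)
        x = x - yc @ np.linalg.lstsq(yc, x, rcond=None)[0]
        assert sm.rda_r2(y, x) == pytest.approx(0.0, abs=1e-10)

    def test_matches_per_taxon_regression_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((12, 5))
        X = rng.standard_normal((12, 2))
        yc = Y - Y.mean(axis=0)
        xc = np.column_stack([np.ones(12), X])
        ss_fit = 0.0
        for k in range(5):
            beta, *_ = np.linalg.lstsq(xc, yc[:, k], rcond=None)
            fit = xc @ beta
            ss_fit += np.sum((fit - fit.mean()) ** 2)
        expect = ss_fit / np.sum(yc * yc)
        assert sm.rda_r2(Y, X) == pytest.approx(expect, abs=1e-10)


class TestAdjustments:
    def test_classical_hand_value(self):
        assert sm.adjust_r2_classical(0.5, 20, 4) == pytest.approx(1 - 0.5 * 19 / 15)

    def test_classical_edges(self):
        assert sm.adjust_r2_classical(1.0, 20, 4) == 1.0
        assert sm.adjust_r2_classical(0.37, 20, 0) == 0.37
        with pytest.raises(ValueError):
            sm.adjust_r2_classical(0.5, 5, 5)

    def test_msr_fixed_points(self):
        nulls = np.zeros(99)
        assert sm.adjust_r2_msr(0.4, nulls) == pytest.approx(0.4)
        nulls = np.full(99, 0.4)
        assert sm.adjust_r2_msr(0.4, nulls) == pytest.approx(0.0)
        with pytest.raises(ValueError, match="99"):
            sm.adjust_r2_msr(0.4, np.zeros(10))

    def test_msr_matches_classical_under_white_noise_nulls(self):
        # surrogate R^2 of pure noise has expectation p/(n-1): the MSR ratio
        # then reproduces Ezekiel's correction
        rng = np.random.default_rng(3)
        n, p = 20, 4
        Y = rng.standard_normal((n, 6))
        r2 = 0.3
        nulls = [sm.rda_r2(Y, rng.standard_normal((n, p))) for _ in range(2000)]
        got = sm.adjust_r2_msr(r2, nulls[:1999])
        expect = sm.adjust_r2_classical(r2, n, p)
        assert got == pytest.approx(expect, abs=0.02)


class TestVarpart:
    def test_duplicated_predictor_collapses_uniques(self):
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((15, 6))
        col = rng.standard_normal((15, 1))
        res = sm.varpart(Y, col, col.copy(), "classical")
        assert res.unique_env == pytest.approx(0.0, abs=1e-10)
        assert res.unique_spatial == pytest.approx(0.0, abs=1e-10)
        assert res.shared == pytest.approx(res.env_total, abs=1e-10)
        assert res.delta == pytest.approx(0.0, abs=1e-10)

    def test_env_driven_community_attributes_to_env(self):
        ok = 0
        n_rep = 20
        for r in range(n_rep):
            rng = np.random.default_rng(500 + r)
            E = rng.standard_normal((18, 3))
            M = rng.standard_normal((18, 3))
            # orthogonalize M against E so space carries no real signal
            M = M - E @ np.linalg.lstsq(E, M, rcond=None)[0]
            Y = E @ rng.standard_normal((3, 8)) + 0.05 * rng.standard_normal((18, 8))
            res = sm.varpart(Y, E, M, "classical")
            if res.delta > 0 and res.unique_spatial <= 0.02:
                ok += 1
        assert ok >= int(0.95 * n_rep)

    def test_fraction_identity_both_adjustments(self, small_community, small_env,
                                                small_basis):
        Y = sm.hellinger(small_community)
        E = sm.log1p_env(small_env - small_env.min().min()).iloc[:, :4]
        M = small_basis.positive.iloc[:, :4]
        for adj, kw in (("classical", {}), ("msr", {"basis": small_basis,
                                                    "n_surrogates": 99, "seed": 0})):
            res = sm.varpart(Y, E, M, adj, **kw)
            assert res.identity_gap() < 1e-10

    def test_taxon_order_invariance(self, small_community, small_env, small_basis):
        E = sm.log1p_env(small_env - small_env.min().min()).iloc[:, :4]
        M = small_basis.positive.iloc[:, :4]
        Y1 = sm.hellinger(small_community)
        rng = np.random.default_rng(6)
        shuffled = small_community.abundance.iloc[:, rng.permutation(small_community.n_taxa)]
        Y2 = sm.hellinger(shuffled)
        r1 = sm.varpart(Y1, E, M, "classical")
        r2 = sm.varpart(Y2, E, M, "classical")
        for key, val in r1.fractions().items():
            assert r2.fractions()[key] == pytest.approx(val, abs=1e-10)

    def test_exhausted_degrees_of_freedom_rejected(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((8, 3))
        with pytest.raises(ValueError, match="degrees of freedom"):
            sm.varpart(Y, rng.standard_normal((8, 4)), rng.standard_normal((8, 4)))


class TestStandardized:
    def test_degenerate_resample_equals_plain(self, small_community, small_env,
                                              small_basis):
        E = sm.log1p_env(small_env - small_env.min().min()).iloc[:, :4]
        M = small_basis.positive.iloc[:, :4]
        cfg = sm.StandardizationConfig(S=small_community.n_taxa, n_reps=1, seed=0)
        std = sm.standardized_varpart(small_community, E, M, cfg)
        plain = sm.varpart(sm.hellinger(small_community), E, M, "classical")
        assert std.deltas[0] == pytest.approx(plain.delta, abs=1e-12)

    def test_replicate_count_and_determinism(self, small_community, small_env,
                                             small_basis):
        E = sm.log1p_env(small_env - small_env.min().min()).iloc[:, :4]
        M = small_basis.positive.iloc[:, :4]
        cfg = sm.StandardizationConfig(S=20, n_reps=40, seed=3)
        a = sm.standardized_varpart(small_community, E, M, cfg)
        b = sm.standardized_varpart(small_community, E, M, cfg)
        assert len(a.deltas) == 40
        assert np.array_equal(a.deltas, b.deltas)

    def test_s_larger_than_taxa_rejected(self, small_community, small_env, small_basis):
        cfg = sm.StandardizationConfig(S=small_community.n_taxa + 1, n_reps=1)
        with pytest.raises(ValueError, match="exceeds"):
            sm.standardized_varpart(small_community, small_env.iloc[:, :2],
                                    small_basis.positive.iloc[:, :2], cfg)

    def test_boxplot_stats_fields(self, small_community, small_env, small_basis):
        E = sm.log1p_env(small_env - small_env.min().min()).iloc[:, :4]
        M = small_basis.positive.iloc[:, :4]
        std = sm.standardized_varpart(
            small_community, E, M, sm.StandardizationConfig(S=15, n_reps=30, seed=1))
        stats = std.boxplot_stats()
        assert stats["q1"] <= stats["median"] <= stats["q3"]
        assert stats["n_outliers"] >= 0


class TestTraitSubset:
    def make_community(self):
        ab = pd.DataFrame(np.arange(20).reshape(2, 10) + 1,
                          index=["s1", "s2"],
                          columns=[f"t{k}" for k in range(10)])
        fam = pd.Series([f"F{k // 2}" for k in range(10)], index=ab.columns)
        return sm.CommunityMatrix(abundance=ab, family=fam)

    def test_hand_counted_subset(self):
        com = self.make_community()
        traits = pd.DataFrame(
            {"drifting_propensity": ["high", "low", "high", "low"]},
            index=["F0", "F1", "F2", "F4"])  # F3 unlisted
        sub = sm.subset_by_trait(com, traits, "drifting_propensity", "high")
        # F0 and F2 are high: taxa t0,t1,t4,t5
        assert list(sub.abundance.columns) == ["t0", "t1", "t4", "t5"]
        assert sub.n_excluded == 2  # the two F3 taxa

    def test_all_high_identity(self):
        com = self.make_community()
        fams = sorted(com.family.unique())
        traits = pd.DataFrame({"drifting_propensity": ["high"] * len(fams)}, index=fams)
        sub = sm.subset_by_trait(com, traits, "drifting_propensity", "high")
        assert sub.abundance.equals(com.abundance)

    def test_empty_table_rejected(self):
        com = self.make_community()
        traits = pd.DataFrame({"drifting_propensity": []}, index=pd.Index([]))
        with pytest.raises(ValueError, match="no taxa"):
            sm.subset_by_trait(com, traits, "drifting_propensity", "high")
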