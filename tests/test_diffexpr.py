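import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet import diffexpr as de
from cernet.matrix import ExpressionMatrix

from conftest import nb_matrix


def _mat(values, reps=3, layer="mRNA"):
    values = np.asarray(values, dtype=float)
    cond = pd.Series(["GF_C"] * reps + ["GF_T"] * (values.shape[1] - reps),
                     index=[f"GF_{i+1}" for i in range(values.shape[1])])
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                      columns=cond.index)
    return ExpressionMatrix(layer, df, cond)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        m = _mat(np.tile([[10], [200], [3000], [40]], (1, 6)))
        assert np.allclose(de.tmm_factors(m), 1.0)

    def test_doubled_column_restores_normalized_equality(self):
        rng = np.random.default_rng(0)
        col = rng.integers(10, 2000, size=300).astype(float)
        vals = np.column_stack([col] * 5 + [2 * col])
        m = _mat(vals)
        f = de.tmm_factors(m)
        lib = m.library_sizes().to_numpy() * f.to_numpy()
        norm = vals / lib
        assert np.allclose(norm, norm[:, [0]], rtol=1e-6)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        m = _mat(rng.integers(0, 500, size=(200, 6)).astype(float))
        f = de.tmm_factors(m).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        vals = np.ones((5, 6)) * 10
        vals[:, 2] = 0
        with pytest.raises(ValueError, match="all-zero"):
            de.tmm_factors(_mat(vals))


class TestDispersion:
    def test_poisson_data_gives_near_zero_phi(self):
        rng = np.random.default_rng(5)
        m = nb_matrix(rng, 200, 50, phi=0.0)
        est = de.estimate_dispersion(m)
        assert 0.0 <= est.common_phi <= 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(6)
        m = nb_matrix(rng, 500, 10, phi=0.2)
        est = de.estimate_dispersion(m)
        assert est.common_phi == pytest.approx(0.2, abs=0.05)

    def test_constant_matrix_gives_zero(self):
        m = _mat(np.full((10, 6), 77.0))
        est = de.estimate_dispersion(m)
        assert est.common_phi == 0.0
        assert (est.per_feature_phi == 0.0).all()

    def test_single_replicate_warns(self):
        vals = np.tile([[10.0, 20.0, 30.0]], (5, 1))
        cond = pd.Series(["GF_C", "GF_C", "GF_T"], index=["GF_1", "GF_2", "GF_3"])
        m = ExpressionMatrix("mRNA", pd.DataFrame(
            vals, index=[f"g{i}" for i in range(5)], columns=cond.index), cond)
        with pytest.warns(UserWarning, match="replicates"):
            de.estimate_dispersion(m)


def naive_exact_p(sum_a, sum_b, phi, size_ratio=1.0, phi_b=None):
    """Independent brute-force oracle: plain loop over every split."""
    phi_b = phi if phi_b is None else phi_b
    t = sum_a + sum_b
    mu_a = t * size_ratio / (1 + size_ratio)
    mu_b = t / (1 + size_ratio)

    def pmf(x, mu, ph):
        if ph == 0:
            return stats.poisson.pmf(x, mu)
        r = 1.0 / ph
        return stats.nbinom.pmf(x, r, r / (r + mu))

    probs = [pmf(x, mu_a, phi) * pmf(t - x, mu_b, phi_b) for x in range(t + 1)]
    total = sum(probs)
    obs = probs[sum_a]
    return sum(p for p in probs if p <= obs * (1 + 1e-12)) / total


class TestNbExactTest:
    def test_symmetric_split_gives_p_one(self):
        assert de.nb_exact_test(25, 25, 0.1) == pytest.approx(1.0)
        assert de.nb_exact_test(0, 0 + 7, 0.0) < 1.0

    @pytest.mark.parametrize("t", [1, 5, 17, 60])
    @pytest.mark.parametrize("ratio", [1.0, 0.5, 2.0])
    def test_phi_zero_matches_binomial_tail_oracle(self, t, ratio):
        pi = ratio / (1 + ratio)
        pmf = stats.binom.pmf(np.arange(t + 1), t, pi)
        for x in range(t + 1):
            expected = pmf[pmf <= pmf[x] * (1 + 1e-12)].sum()
            assert de.nb_exact_test(x, t - x, 0.0, ratio) == pytest.approx(
                expected, abs=1e-9
            )

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.5, 2.0])
    @pytest.mark.parametrize("t,ratio", [(7, 1.0), (23, 1.0), (40, 0.5), (61, 2.0)])
    def test_matches_enumeration_oracle(self, phi, t, ratio):
        for x in range(0, t + 1, max(1, t // 11)):
            assert de.nb_exact_test(x, t - x, phi, ratio) == pytest.approx(
                naive_exact_p(x, t - x, phi, ratio), abs=1e-9
            )

    def test_group_swap_preserves_p_exactly(self):
        for (a, b, phi, s) in [(3, 19, 0.1, 1.0), (40, 12, 0.3, 0.7), (5, 5, 0.2, 2.0)]:
            assert de.nb_exact_test(a, b, phi, s) == de.nb_exact_test(b, a, phi, 1.0 / s)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            de.nb_exact_test(0, 0, 0.1)
        with pytest.raises(ValueError):
            de.nb_exact_test(-1, 5, 0.1)
        with pytest.raises(ValueError):
            de.nb_exact_test(1, 5, -0.1)
        with pytest.raises(ValueError):
            de.nb_exact_test(1, 5, 0.1, size_ratio=0.0)


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert de.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert de.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_stay_equal(self):
        assert de.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_order_preserved_and_monotone(self):
        p = np.array([0.9, 0.001, 0.5, 0.04, 0.04])
        f = de.bh_fdr(p)
        # sorting by p sorts fdr the same way (step-up monotonicity)
        order = np.argsort(p)
        assert (np.diff(f[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.5, 1.2])


class TestCallDe:
    def test_threshold_boundaries_by_layer(self, small_counts):
        res = de.call_de(small_counts)
        assert set(res.columns) >= {"log2FC", "p_value", "fdr", "direction", "is_de"}
        # planted 8x features are found with correct directions
        assert res.loc["g0", "is_de"] and res.loc["g0", "direction"] == "up"
        assert res.loc["g1", "is_de"] and res.loc["g1", "direction"] == "down"

    def test_fold_change_exactly_one_is_not_de(self):
        # normalized condition means differ exactly 2x (plus pseudocount
        # keeps |log2FC| <= 1): strict inequality excludes the feature
        vals = np.tile([[100.0] * 3 + [200.0] * 3], (50, 1))
        vals[1:] = 150.0  # bulk of features flat so TMM factors are 1
        res = de.call_de(_mat(vals))
        assert abs(res.loc["g0", "log2FC"]) <= 1.0
        assert not res.loc["g0", "is_de"]

    def test_constant_feature_has_zero_fc(self):
        vals = np.vstack([np.full(6, 500.0), np.full(6, 50.0)])
        res = de.call_de(_mat(vals))
        assert res["log2FC"].abs().max() == pytest.approx(0.0)
        assert not res["is_de"].any()

    def test_label_swap_negates_fc_and_preserves_p(self):
        rng = np.random.default_rng(11)
        m = nb_matrix(rng, 100, 3, phi=0.1)
        res = de.call_de(m)
        flipped_cond = m.conditions.map({"GF_C": "GF_T", "GF_T": "GF_C"})
        m2 = ExpressionMatrix("mRNA", m.values, flipped_cond)
        res2 = de.call_de(m2)
        assert np.allclose(res["log2FC"], -res2["log2FC"])
        assert (res["p_value"].to_numpy() == res2["p_value"].to_numpy()).all()

    def test_group_exclusive_flagged_not_infinite(self):
        vals = np.tile([[0.0, 0.0, 0.0, 80.0, 90.0, 100.0]], (30, 1))
        vals[1:] = 100.0
        res = de.call_de(_mat(vals))
        assert res.loc["g0", "group_exclusive"]
        assert np.isfinite(res.loc["g0", "log2FC"])

    def test_all_zero_feature_filtered(self):
        vals = np.vstack([np.zeros(6), np.full(6, 100.0), np.full(6, 30.0)])
        res = de.call_de(_mat(vals))
        assert res.loc["g0", "filtered"]
        assert np.isnan(res.loc["g0", "p_value"])

    def test_unknown_layer_rejected(self, small_counts):
        with pytest.raises(ValueError, match="layer"):
            de.call_de(small_counts, "piRNA")

    def test_planted_signal_power(self):
        # 4x planted fold changes at phi=0.1 with 5 replicates per
        # condition are nearly always recovered
        rng = np.random.default_rng(21)
        mu = 2.0 ** rng.uniform(4, 10, 800)
        m = np.tile(mu[:, None], (1, 10))
        m[:80, 5:] *= 4.0
        y = rng.negative_binomial(10.0, 10.0 / (10.0 + m))
        mat = _mat(y, reps=5)
        res = de.call_de(mat)
        assert res["is_de"].to_numpy()[:80].mean() >= 0.9
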