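import numpy as np
import pandas as pd
import pytest

from urbanfilter.synth import SyntheticScenario, generate_dataset
from urbanfilter.traitenv import (
    code_traits,
    fourth_corner,
    rlq,
    trait_counts_per_site,
    trait_direction_glm,
    trait_directions,
)


def brute_force_fourth_corner(r, l, q_coded):
    """Scalar-formula fourth-corner statistics with explicit loops."""
    lv = l.to_numpy(float)
    p = lv / lv.sum()
    rw = p.sum(axis=1)
    cw = p.sum(axis=0)
    out = np.zeros((r.shape[1], q_coded.shape[1]))
    for k, env_col in enumerate(r.columns):
        x = r[env_col].to_numpy(float)
        mx = np.sum(rw * x)
        sx = np.sqrt(np.sum(rw * (x - mx) ** 2))
        for t, tcol in enumerate(q_coded.columns):
            z = q_coded[tcol].to_numpy(float)
            mz = np.sum(cw * z)
            sz = np.sqrt(np.sum(cw * (z - mz) ** 2))
            s = 0.0
            for i in range(p.shape[0]):
                for j in range(p.shape[1]):
                    s += p[i, j] * (x[i] - mx) / sx * (z[j] - mz) / sz
            out[k, t] = s
    return out


@pytest.fixture
def tiny_tables():
    l = pd.DataFrame(
        [[3, 0, 1], [1, 2, 0], [0, 4, 2], [2, 1, 3]],
        index=["s1", "s2", "s3", "s4"],
        columns=["spA", "spB", "spC"],
    )
    r = pd.DataFrame(
        {"urb": [10.0, 40.0, 80.0, 25.0], "temp": [17.0, 20.0, 24.0, 19.0]},
        index=l.index,
    )
    q = pd.DataFrame(
        {"diet": ["poly", "oligo", "poly"], "size": [6.0, 11.0, 9.0]}, index=l.columns
    )
    return r, l, q


class TestCodeTraits:
    def test_one_hot_partition(self):
        q = pd.DataFrame({"sociality": ["solitary", "eusocial", "solitary"]})
        coded, meta = code_traits(q)
        assert list(coded.columns) == ["sociality:eusocial", "sociality:solitary"]
        assert np.allclose(coded.sum(axis=1), 1.0)
        assert set(meta["level"]) == {"eusocial", "solitary"}

    def test_constant_columns_dropped_with_warning(self):
        q = pd.DataFrame({"size": [5.0, 5.0, 5.0], "diet": ["a", "b", "a"]})
        with pytest.warns(UserWarning, match="constant"):
            coded, _ = code_traits(q)
        assert "size" not in coded.columns
        q2 = pd.DataFrame({"diet": ["a", "a", "a"], "size": [5.0, 6.0, 7.0]})
        with pytest.warns(UserWarning, match="single level"):
            coded2, _ = code_traits(q2)
        assert list(coded2.columns) == ["size"]

    def test_hand_written_expansion(self):
        q = pd.DataFrame(
            {"diet": ["poly", "oligo", "poly"], "size": [6.0, 11.0, 9.0]},
            index=["a", "b", "c"],
        )
        coded, _ = code_traits(q, standardize_quantitative=False)
        expected = pd.DataFrame(
            {
                "diet:oligo": [0.0, 1.0, 0.0],
                "diet:poly": [1.0, 0.0, 1.0],
                "size": [6.0, 11.0, 9.0],
            },
            index=["a", "b", "c"],
        )
        pd.testing.assert_frame_equal(coded, expected)

    def test_weighted_zscore_uses_species_weights(self):
        q = pd.DataFrame({"size": [2.0, 4.0]}, index=["a", "b"])
        w = pd.Series([0.75, 0.25], index=["a", "b"])
        coded, _ = code_traits(q, species_weights=w)
        mu = 0.75 * 2 + 0.25 * 4
        sd = np.sqrt(0.75 * (2 - mu) ** 2 + 0.25 * (4 - mu) ** 2)
        assert np.allclose(coded["size"], (np.array([2.0, 4.0]) - mu) / sd)

    def test_missing_values_raise(self):
        q = pd.DataFrame({"size": [1.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            code_traits(q)


class TestRLQ:
    def test_independent_structure_gives_zero_eigenvalues(self):
        # rank-1 P = r c^T: abundances proportional to site x species margins
        r_vec = np.array([0.1, 0.2, 0.3, 0.4])
        c_vec = np.array([0.5, 0.3, 0.2])
        l = pd.DataFrame(
            np.outer(r_vec, c_vec) * 1000,
            index=["s1", "s2", "s3", "s4"],
            columns=["a", "b", "c"],
        )
        r = pd.DataFrame({"urb": [1.0, 2.0, 4.0, 8.0]}, index=l.index)
        q = pd.DataFrame({"size": [3.0, 5.0, 9.0]}, index=l.columns)
        coded, _ = code_traits(q, standardize_quantitative=False)
        with pytest.raises(ValueError, match="rank 0"):
            rlq(r, l, coded)

    def test_first_eigenvalue_equals_squared_scalar_stat(self, tiny_tables):
        r, l, q = tiny_tables
        r1 = r[["urb"]]
        coded, _ = code_traits(q[["size"]], standardize_quantitative=False)
        res = rlq(r1, l, coded)
        stat = brute_force_fourth_corner(r1, l, coded)[0, 0]
        assert res.eigenvalues[0] == pytest.approx(stat**2, rel=1e-10)

    def test_eigenvalue_sum_is_frobenius_norm(self, tiny_tables):
        r, l, q = tiny_tables
        coded, _ = code_traits(q, standardize_quantitative=False)
        res = rlq(r, l, coded)
        m = brute_force_fourth_corner(r, l, coded)
        assert res.eigenvalues.sum() == pytest.approx((m**2).sum(), rel=1e-10)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_loadings_orthonormal(self, tiny_tables):
        r, l, q = tiny_tables
        coded, _ = code_traits(q, standardize_quantitative=False)
        res = rlq(r, l, coded)
        u = res.env_loadings.to_numpy()
        v = res.trait_loadings.to_numpy()
        assert np.allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-9)
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-9)


class TestFourthCorner:
    def test_matches_brute_force_oracle(self, tiny_tables):
        r, l, q = tiny_tables
        coded, _ = code_traits(q, standardize_quantitative=False)
        fc = fourth_corner(r, l, coded, n_perm=99, seed=0)
        oracle = brute_force_fourth_corner(r, l, coded)
        got = fc.table["stat"].unstack().loc[r.columns, coded.columns].to_numpy()
        assert np.allclose(got, oracle, atol=1e-10)
        assert (np.abs(got) <= 1.0 + 1e-12).all()

    def test_invariant_to_scaling_l(self, tiny_tables):
        r, l, q = tiny_tables
        coded, _ = code_traits(q, standardize_quantitative=False)
        a = fourth_corner(r, l, coded, n_perm=99, seed=5)
        b = fourth_corner(r, 10.0 * l, coded, n_perm=99, seed=5)
        assert np.allclose(a.table["stat"], b.table["stat"], atol=1e-12)
        assert np.allclose(a.table["p_perm"], b.table["p_perm"])

    def test_joint_site_permutation_equivariance(self, tiny_tables):
        r, l, q = tiny_tables
        coded, _ = code_traits(q, standardize_quantitative=False)
        a = fourth_corner(r, l, coded, n_perm=99, seed=1)
        order = ["s3", "s1", "s4", "s2"]
        b = fourth_corner(r.loc[order], l.loc[order], coded, n_perm=99, seed=1)
        assert np.allclose(a.table["stat"], b.table["stat"], atol=1e-12)

    def test_add_one_p_when_observed_exceeds_all(self):
        # deterministic strong association: one trait level dominates the
        # high-urbanisation sites
        rng = np.random.default_rng(0)
        n = 30
        urb = np.linspace(0, 100, n)
        l = pd.DataFrame(
            {
                "hi_sp": rng.poisson(np.exp(0.05 * (urb - 50) / 10 + 2)),
                "lo_sp": rng.poisson(np.exp(-0.05 * (urb - 50) / 10 + 2)),
            },
            index=[f"s{i}" for i in range(n)],
        )
        l["hi_sp"] = l["hi_sp"] + (urb > 50) * 40
        r = pd.DataFrame({"urb": urb}, index=l.index)
        q = pd.DataFrame({"g": ["hi", "lo"]}, index=l.columns)
        coded, _ = code_traits(q)
        fc = fourth_corner(r, l, coded, n_perm=99, seed=0)
        assert fc.table["p_perm"].min() == pytest.approx(0.01)

    def test_input_validation(self, tiny_tables):
        r, l, q = tiny_tables
        coded, _ = code_traits(q, standardize_quantitative=False)
        with pytest.raises(ValueError, match="n_perm"):
            fourth_corner(r, l, coded, n_perm=50)
        with pytest.raises(NotImplementedError):
            fourth_corner(r, l, coded, model=4)
        with pytest.raises(ValueError, match="site identifiers"):
            fourth_corner(r.iloc[::-1], l, coded)


class TestTraitCountsAndGLM:
    def test_hand_counted_presence(self):
        l = pd.DataFrame(
            [[2, 0, 1], [0, 0, 5]], index=["s1", "s2"], columns=["a", "b", "c"]
        )
        q = pd.DataFrame(
            {"sociality": ["eusocial", "eusocial", "solitary"], "size": [5.0, 6.0, 7.0]},
            index=l.columns,
        )
        counts = trait_counts_per_site(l, q)
        assert list(counts.columns) == ["sociality:eusocial", "sociality:solitary"]
        assert counts.loc["s1"].tolist() == [1.0, 1.0]
        assert counts.loc["s2"].tolist() == [0.0, 1.0]
        assert "size" not in counts.columns  # quantitative traits excluded

    def test_two_group_closed_form_slope(self):
        env = np.array([0.0] * 20 + [1.0] * 20)
        counts = np.array([2] * 20 + [6] * 20)
        res = trait_direction_glm(counts, env)
        assert res.beta == pytest.approx(np.log(6.0 / 2.0), abs=1e-8)
        assert res.sign == "+"

    def test_slope_recovery_on_generated_data(self):
        rng = np.random.default_rng(7)
        env = rng.uniform(-2, 2, 200)
        y = rng.poisson(np.exp(1.0 + 0.5 * env))
        res = trait_direction_glm(y, env)
        assert abs(res.beta - 0.5) < 2 * res.se

    def test_constant_counts_zero_slope(self):
        res = trait_direction_glm(np.full(30, 4), np.linspace(0, 1, 30))
        assert abs(res.beta) < 1e-8
        assert res.sign in {"+", "-", "0"}

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError, match="all-zero"):
            trait_direction_glm(np.zeros(10), np.arange(10.0))

    def test_direction_grid_on_synthetic_data(self, small_dataset):
        counts = trait_counts_per_site(small_dataset.community, small_dataset.traits)
        table = trait_directions(counts, small_dataset.env)
        assert {"beta", "se", "z", "p_wald", "sign"} <= set(table.columns)
        assert (table["se"].dropna() > 0).all()
        signs = np.sign(table["beta"]).map({1.0: "+", -1.0: "-", 0.0: "0"})
        assert (signs == table["sign"]).all()
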