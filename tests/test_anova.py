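"""Effect decomposition, df bookkeeping and Goodall's F for all designs."""

import numpy as np
import pytest
from scipy import stats

import morphosym as ms
from morphosym.anova import (
    DENOMINATORS,
    UnbalancedDesignError,
    a1_ss,
    a2_ss,
    a3_ss,
    design_dfs,
)


def _oracle_two_way(y):
    """Loop-based marginal-mean decomposition of an (I, J, R, D) array."""
    I, J, R, D = y.shape
    grand = y.mean(axis=(0, 1, 2))
    ss = dict.fromkeys(["individual", "part", "individual_x_part", "error"], 0.0)
    for i in range(I):
        mi = y[i].mean(axis=(0, 1))
        for j in range(J):
            mj = y[:, j].mean(axis=(0, 1))
            mij = y[i, j].mean(axis=0)
            for r in range(R):
                ss["individual"] += np.sum((mi - grand) ** 2)
                ss["part"] += np.sum((mj - grand) ** 2)
                ss["individual_x_part"] += np.sum((mij - mi - mj + grand) ** 2)
                ss["error"] += np.sum((y[i, j, r] - mij) ** 2)
    return ss


class TestDecomposition:
    def test_two_way_matches_explicit_averaging_oracle(self, rng):
        y = rng.standard_normal((3, 4, 2, 5))
        got = a1_ss(y)
        want = _oracle_two_way(y)
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-12)

    def test_nested_matches_explicit_averaging_oracle(self, rng):
        s = rng.standard_normal((3, 2, 2, 4))
        a = rng.standard_normal((3, 2, 2, 4))
        got = a3_ss(s, a)
        o2 = _oracle_two_way(s)
        I, J, R, D = a.shape
        rp = lrp = ea = 0.0
        for i in range(I):
            for j in range(J):
                aj = a[:, j].mean(axis=(0, 1))
                aij = a[i, j].mean(axis=0)
                for r in range(R):
                    rp += np.sum(aj**2)
                    lrp += np.sum((aij - aj) ** 2)
                    ea += np.sum((a[i, j, r] - aij) ** 2)
        assert got["individual"] == pytest.approx(o2["individual"], rel=1e-12)
        assert got["individual_x_part"] == pytest.approx(o2["individual_x_part"], rel=1e-12)
        assert got["symmetric_error"] == pytest.approx(o2["error"], rel=1e-12)
        assert got["reflection_in_part"] == pytest.approx(rp, rel=1e-12)
        assert got["individual_x_reflection_in_part"] == pytest.approx(lrp, rel=1e-12)
        assert got["asymmetric_error"] == pytest.approx(ea, rel=1e-12)

    def test_constant_dataset_all_zero(self):
        y = np.ones((4, 3, 2, 6))
        assert all(v == pytest.approx(0.0, abs=1e-20) for v in a1_ss(y).values())

    def test_a2_reflection_partition_of_nested_da(self, rng):
        """The bilateral-DA SS of the two-way object design splits the nested
        reflection-in-part SS into overall mean + per-part deviations."""
        s = rng.standard_normal((4, 3, 2, 6))
        a = rng.standard_normal((4, 3, 2, 6))
        two = a2_ss(s, a)
        nested = a3_ss(s, a)
        assert two["reflection"] + two["part_x_reflection"] == pytest.approx(
            nested["reflection_in_part"], rel=1e-12
        )

    def test_ss_additivity_all_designs(self, object_components, matching_components):
        co, cm = object_components, matching_components
        ss1 = a1_ss(cm.y)
        tot1 = np.sum((cm.y - cm.y.mean(axis=(0, 1, 2))) ** 2)
        assert sum(ss1.values()) == pytest.approx(tot1, rel=1e-10)
        # object designs: total variation about the symmetric reference
        sgrand = co.s.mean(axis=(0, 1, 2))
        tot3 = np.sum((co.s - sgrand) ** 2) + np.sum(co.a**2)
        ss3 = a3_ss(co.s, co.a)
        assert sum(v for k, v in ss3.items() if k != "total_error") == pytest.approx(
            tot3, rel=1e-10
        )

    def test_effects_confined_to_their_subspaces(self, object_components):
        from morphosym.anova import SUBSPACE, effect_arrays

        co = object_components
        arrs = effect_arrays("A3", co)
        P, Q = co.projectors.symmetric, co.projectors.asymmetric
        scale = max(np.abs(co.y).max(), 1e-12)
        for eff, x in arrs.items():
            other = Q if SUBSPACE["A3"][eff] == "sym" else P
            assert np.abs(x @ other).max() < 1e-10 * scale


class TestDfBookkeeping:
    def test_lantern_grid_reproduces_published_df(self):
        dims = (10, 10)
        a1 = design_dfs("A1", (10, 5, 2), dims)
        assert a1 == {
            "individual": (9, 90),
            "part": (4, 40),
            "individual_x_part": (36, 360),
            "error": (50, 500),
        }
        a2 = design_dfs("A2", (10, 5, 2), dims)
        assert a2 == {
            "part": (4, 40),
            "reflection": (1, 10),
            "part_x_reflection": (4, 40),
            "symmetric_error": (45, 450),
            "asymmetric_error": (45, 450),
            "total_error": (45, 900),
        }
        a3 = design_dfs("A3", (10, 5, 2), dims)
        assert a3 == {
            "individual": (9, 90),
            "part": (4, 40),
            "reflection_in_part": (5, 50),
            "individual_x_part": (36, 360),
            "individual_x_reflection_in_part": (45, 450),
            "symmetric_error": (45, 450),
            "asymmetric_error": (45, 450),
            "total_error": (45, 900),
        }
        size = design_dfs("size", (10, 5, 2), (1, 1))
        assert {k: v[0] for k, v in size.items()} == {
            "individual": 9,
            "part": 4,
            "individual_x_part": 36,
            "error": 50,
        }

    @pytest.mark.parametrize("grid", [(4, 3, 2), (6, 2, 3)])
    def test_df_sum_to_record_count_per_subspace(self, grid):
        i, j, r = grid
        a3 = design_dfs("A3", grid, (10, 10))
        sym = a3["individual"][0] + a3["part"][0] + a3["individual_x_part"][0] + 1
        asym = a3["reflection_in_part"][0] + a3["individual_x_reflection_in_part"][0]
        # per-subspace conventional df sum to the record count minus the
        # part-centred replicate contrasts removed by the mean correction
        assert sym + i * j * (r - 1) == i * j * r
        assert asym + i * j * (r - 1) == i * j * r
        assert a3["symmetric_error"][0] == j * (i - 1) * (r - 1)


class TestGoodallF:
    def test_equal_mean_squares_give_unity(self):
        f, p = ms.goodall_f(2.0, 10, 4.0, 20)
        assert f == pytest.approx(1.0)

    def test_zero_denominator_warns_nan(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            f, p = ms.goodall_f(1.0, 5, 0.0, 5)
        assert np.isnan(f) and np.isnan(p)

    def test_one_df_numerator_matches_normal_tail(self):
        f = 3.7
        _, p = ms.goodall_f(f, 1, 1.0 * 10**6, 10**6)
        assert p == pytest.approx(2 * stats.norm.sf(np.sqrt(f)), abs=1e-6)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ms.goodall_f(1.0, 0, 1.0, 5)
        with pytest.raises(ValueError):
            ms.goodall_f(-1.0, 2, 1.0, 5)


class TestDesignTables:
    def test_a1_individual_only_concentrates_ss(self):
        params = ms.VarianceComponents(
            seed=5, sigma_rot_fa=0.0, sigma_bil_fa=0.0, sigma_error=0.0, da_bilateral=0.0
        )
        ds, _ = ms.simulate_lanterns(params)
        cm = ms.prepare_matching(ds)
        ss = a1_ss(cm.y)
        total = sum(ss.values())
        assert ss["individual"] / total > 0.999
        assert ss["part"] / total < 1e-3

    def test_null_noise_f_near_unity(self, rng):
        """Under pure error (no individual, part or interaction effects) every
        F ratio is ~1 in expectation (Monte Carlo over direct draws)."""
        fs = []
        for _ in range(300):
            y = rng.standard_normal((5, 4, 2, 6))
            ss = a1_ss(y)
            dfs = design_dfs("A1", (5, 4, 2), (6, 6))
            fs.append(
                [
                    (ss[e] / dfs[e][1]) / (ss[DENOMINATORS["A1"][e]] / dfs[DENOMINATORS["A1"][e]][1])
                    for e in ("individual", "part", "individual_x_part")
                ]
            )
        fs = np.array(fs)
        for col in range(3):
            mean, se = fs[:, col].mean(), fs[:, col].std(ddof=1) / np.sqrt(len(fs))
            assert abs(mean - 1.0) < max(3 * se, 0.05 + 3 * se)

    def test_missing_replicates_rejected(self):
        params = ms.VarianceComponents(seed=6, n_replicates=1)
        ds, _ = ms.simulate_lanterns(params)
        cm = ms.prepare_matching(ds)
        with pytest.raises(ValueError, match="replicate"):
            ms.anova_rotational_matching(cm)

    def test_design_family_mismatch_rejected(self, matching_components, object_components):
        with pytest.raises(ValueError, match="object-symmetry pipeline"):
            ms.anova_nested(matching_components)
        with pytest.raises(ValueError, match="matching-symmetry pipeline"):
            ms.anova_rotational_matching(object_components)

    def test_unbalanced_grid_rejected(self, lantern_dataset):
        dataset, _ = lantern_dataset
        with pytest.raises(UnbalancedDesignError):
            ms.ShapeDataset(
                dataset.configs[:-1],
                dataset.individual[:-1],
                dataset.part[:-1],
                dataset.replicate[:-1],
                dataset.scheme,
            )


class TestCentroidSizeAnova:
    def test_constant_sizes_zero_ss(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            table = ms.anova_centroid_size(np.full((4, 3, 2), 7.5))
        assert np.allclose(table["SS"], 0.0, atol=1e-18)

    def test_object_only_data_rejected(self):
        with pytest.raises(ValueError, match="no size asymmetry"):
            ms.anova_centroid_size(np.ones((10, 2)))

    def test_sizes_recover_injected_structure(self, lantern_dataset, matching_components):
        _, truth = lantern_dataset
        table = ms.anova_centroid_size(matching_components.sizes).set_index("effect")
        # individual size variation dominates FA which dominates error
        assert table.loc["individual", "F"] > 5
        assert table.loc["individual_x_part", "F"] > 5

    def test_uses_conventional_df(self, matching_components):
        table = ms.anova_centroid_size(matching_components.sizes)
        assert (table["conv_df"] == table["shape_df"]).all()
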