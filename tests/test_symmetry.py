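"""Reflection-relabelling, symmetrization and subspace projectors."""

import numpy as np
import pytest

import morphosym as ms
from morphosym.geometry import _center_and_scale
from morphosym.symmetry import reflection_operator
from morphosym.simulate import lantern_template


class TestReflectAndRelabel:
    def test_involution_is_exact(self, rng, toy_scheme):
        cfg = rng.standard_normal((5, 2))
        twice = ms.reflect_and_relabel(ms.reflect_and_relabel(cfg, toy_scheme), toy_scheme)
        assert np.array_equal(twice, cfg)

    def test_hand_computed_toy(self, toy_scheme):
        cfg = np.array([[1.0, 2.0], [3.0, 4.0], [0.5, -1.0], [-2.0, 0.0], [5.0, 6.0]])
        # pairs (1,2) and (4,5) swap rows; x is negated everywhere
        expected = np.array([[-3.0, 4.0], [-1.0, 2.0], [-0.5, -1.0], [-5.0, 6.0], [2.0, 0.0]])
        assert np.array_equal(ms.reflect_and_relabel(cfg, toy_scheme), expected)

    def test_symmetric_config_is_fixed_point(self):
        scheme = ms.lantern_scheme()
        t = lantern_template(scheme)
        assert np.abs(ms.reflect_and_relabel(t, scheme) - t).max() < 1e-15

    def test_matching_scheme_rejected(self):
        scheme = ms.SymmetryScheme(mode="matching", n_landmarks=5, n_parts=5)
        with pytest.raises(ValueError, match="no bilateral pairing"):
            ms.reflect_and_relabel(np.zeros((5, 2)), scheme)

    def test_operator_matrix_agrees_with_row_operation(self, rng, toy_scheme):
        cfg = rng.standard_normal((5, 2))
        op = reflection_operator(toy_scheme)
        assert np.allclose(op @ cfg.reshape(-1), ms.reflect_and_relabel(cfg, toy_scheme).reshape(-1))


class TestSchemeValidation:
    def test_partition_must_be_exact(self):
        with pytest.raises(ValueError, match="partition"):
            ms.SymmetryScheme(mode="object", n_landmarks=5, pairing=((1, 2),), unpaired=(3,))

    def test_self_pairing_rejected(self):
        with pytest.raises(ValueError, match="paired with itself"):
            ms.SymmetryScheme(
                mode="object", n_landmarks=3, pairing=((1, 1),), unpaired=(2, 3)
            )


class TestSymmetrize:
    def test_symmetric_input_roundtrips(self):
        scheme = ms.lantern_scheme()
        t = lantern_template(scheme)
        out = ms.symmetrize(t, scheme)
        assert ms.procrustes_distance(out, t) < 1e-9

    def test_output_exactly_symmetric_and_idempotent(self, rng):
        scheme = ms.lantern_scheme()
        cfg = lantern_template(scheme) + 0.02 * rng.standard_normal((12, 2))
        out = ms.symmetrize(cfg, scheme)
        assert np.abs(ms.reflect_and_relabel(out, scheme) - out).max() < 1e-12
        again = ms.symmetrize(out, scheme)
        assert ms.procrustes_distance(again, out) < 1e-9

    def test_matches_two_config_superimposition_oracle(self, rng, toy_scheme):
        """The symmetric average equals the mean of the original and its
        aligned mirror copy from an explicit two-configuration fit."""
        cfg = np.array([[-1.0, 0.1], [1.1, 0.0], [0.05, 1.0], [-0.6, 0.55], [0.5, 0.6]])
        out = ms.symmetrize(cfg, toy_scheme)

        x, _ = _center_and_scale(cfg)
        m, _ = _center_and_scale(ms.reflect_and_relabel(cfg, toy_scheme))

        def rotate(z, t):
            c, s = np.cos(t), np.sin(t)
            return z @ np.array([[c, s], [-s, c]])

        best = None
        lo, hi = 0.0, 2 * np.pi
        for _ in range(10):
            grid = np.linspace(lo, hi, 100)
            errs = [np.sum((rotate(m, t) - x) ** 2) for t in grid]
            b = int(np.argmin(errs))
            step = grid[1] - grid[0]
            lo, hi = grid[b] - step, grid[b] + step
            best = grid[b]
        oracle = 0.5 * (x + rotate(m, best))
        assert ms.procrustes_distance(out, oracle) < 1e-5


class TestSubspaceProjectors:
    def test_lantern_dimensions(self):
        scheme = ms.lantern_scheme()
        proj = ms.subspace_projectors(scheme, lantern_template(scheme))
        assert (proj.dim_sym, proj.dim_asym) == (10, 10)

    def test_toy_dimension_formula(self, toy_scheme):
        # p=2 pairs, u=1 on-axis: each subspace has 2p+u-2 = 3 dims, sum 2k-4
        t = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-0.5, 0.5], [0.5, 0.5]])
        t, _ = _center_and_scale(t)
        proj = ms.subspace_projectors(toy_scheme, t)
        assert (proj.dim_sym, proj.dim_asym) == (3, 3)
        assert proj.dim_sym + proj.dim_asym == 2 * 5 - 4

    def test_projector_algebra(self):
        scheme = ms.lantern_scheme()
        proj = ms.subspace_projectors(scheme, lantern_template(scheme))
        P, Q = proj.symmetric, proj.asymmetric
        assert np.abs(P @ P - P).max() < 1e-12
        assert np.abs(Q @ Q - Q).max() < 1e-12
        assert np.abs(P @ Q).max() < 1e-12
        assert np.linalg.matrix_rank(P) == proj.dim_sym
        assert np.linalg.matrix_rank(Q) == proj.dim_asym

    def test_pythagoras_on_random_tangent_vectors(self, rng):
        scheme = ms.lantern_scheme()
        proj = ms.subspace_projectors(scheme, lantern_template(scheme))
        full = proj.symmetric + proj.asymmetric
        for _ in range(20):
            v = full @ rng.standard_normal(24)
            lhs = np.sum((proj.symmetric @ v) ** 2) + np.sum((proj.asymmetric @ v) ** 2)
            assert lhs == pytest.approx(np.sum(v**2), abs=1e-12)

    def test_asymmetric_consensus_rejected(self, rng):
        scheme = ms.lantern_scheme()
        bad = lantern_template(scheme) + 0.05 * rng.standard_normal((12, 2))
        with pytest.raises(ValueError, match="not symmetric"):
            ms.subspace_projectors(scheme, bad)

    def test_3d_unsupported(self):
        scheme = ms.lantern_scheme()
        with pytest.raises(NotImplementedError):
            ms.subspace_projectors(scheme, np.zeros((12, 3)), d=3)


class TestExpandedConsensus:
    def test_expansion_doubles_and_consensus_symmetric(self, lantern_dataset, object_components):
        dataset, _ = lantern_dataset
        comp = object_components
        scheme = dataset.scheme
        # joint GPA ran on originals + reflected copies: consensus invariant
        # under the group element to machine precision
        assert np.abs(ms.reflect_and_relabel(comp.consensus, scheme) - comp.consensus).max() < 1e-12

    def test_symmetric_plus_asymmetric_ss_equals_total(self, object_components):
        y, s, a = object_components.y, object_components.s, object_components.a
        assert np.abs(y - s - a).max() < 1e-12
        total = np.sum(y**2)
        assert np.sum(s**2) + np.sum(a**2) == pytest.approx(total, rel=1e-12)
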