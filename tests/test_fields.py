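"""Tensor field generators, DTI scaling and field diagnostics."""

import numpy as np
import pytest

import glioextent as ge
from glioextent.fields import (
    banded_anisotropic_field,
    butterfly_field,
    butterfly_profile,
    fractional_anisotropy,
    homogeneous_field,
    peclet_field,
    random_isotropic_field,
    scale_dti,
    tensor_divergence,
    DriftField,
    TensorField,
)


@pytest.fixture
def grid2d():
    return ge.build_grid((200.0, 200.0), (40, 40))


class TestRandomIsotropicField:
    def test_zero_amplitude_gives_identity(self, grid2d):
        f = random_isotropic_field(grid2d, 0.0, seed=1)
        assert np.allclose(f.tensors, np.eye(2))

    def test_cellwise_scalar_identity_with_determinant_equal_draw(self, grid2d):
        f = random_isotropic_field(grid2d, 0.8, seed=3)
        # off-diagonals vanish, diagonals equal
        assert np.allclose(f.tensors[..., 0, 1], 0.0)
        assert np.allclose(f.tensors[..., 0, 0], f.tensors[..., 1, 1])
        det = f.determinants()
        assert np.all(det >= 1.0 - 0.8 - 1e-12)
        assert np.all(det <= 1.0 + 0.8 + 1e-12)

    def test_reproducible_and_seed_sensitive(self, grid2d):
        a = random_isotropic_field(grid2d, 0.5, seed=7)
        b = random_isotropic_field(grid2d, 0.5, seed=7)
        c = random_isotropic_field(grid2d, 0.5, seed=8)
        assert np.array_equal(a.tensors, b.tensors)
        assert not np.array_equal(a.tensors, c.tensors)

    def test_mean_determinant_near_one(self):
        grid = ge.build_grid((100.0, 100.0), (100, 100))
        f = random_isotropic_field(grid, 0.8, seed=11)
        se = 0.8 / np.sqrt(3.0 * grid.n_cells)
        assert abs(f.determinants().mean() - 1.0) < 3.0 * se

    @pytest.mark.parametrize("beta", [1.0, 1.5, -0.1])
    def test_invalid_amplitude_rejected(self, grid2d, beta):
        with pytest.raises(ValueError):
            random_isotropic_field(grid2d, beta, seed=0)


class TestButterflyField:
    @pytest.mark.parametrize(
        "frac, expected", [(1.0 / 6.0, 1.9), (1.0 / 3.0, 1.0), (0.5, 0.1)]
    )
    def test_profile_band_values(self, frac, expected):
        assert butterfly_profile(frac * 200.0, 200.0) == pytest.approx(expected)

    def test_three_alternating_bands(self):
        grid = ge.build_grid((200.0, 200.0), (60, 60))
        f = butterfly_field(grid)
        col = f.tensors[:, 0, 0, 0]
        # fast left third, slow middle, fast right third
        assert col[:20].mean() > 1.3
        assert col[20:40].mean() < 0.7
        assert col[40:].mean() > 1.3

    def test_isotropic(self):
        grid = ge.build_grid((200.0, 200.0), (20, 20))
        f = butterfly_field(grid)
        assert np.allclose(fractional_anisotropy(f), 0.0, atol=1e-14)

    def test_amplitude_bound(self, grid2d):
        with pytest.raises(ValueError):
            butterfly_field(grid2d, amplitude=1.0)
        with pytest.raises(ValueError):
            butterfly_field(ge.build_grid((10.0,), (5,)))


class TestScaleDti:
    def _random_spd_field(self, grid, rng, dim=3):
        a = rng.normal(size=grid.cell_shape + (dim, dim))
        spd = np.einsum("...ik,...jk->...ij", a, a) + 0.5 * np.eye(dim)
        return TensorField(grid, spd)

    def test_identity_scaling(self, rng):
        grid = ge.build_grid((10.0, 10.0, 10.0), (3, 3, 3))
        f = self._random_spd_field(grid, rng)
        assert np.allclose(scale_dti(f, 1.0).tensors, f.tensors)

    def test_determinant_homogeneity(self, rng):
        grid = ge.build_grid((10.0, 10.0, 10.0), (3, 3, 3))
        f = self._random_spd_field(grid, rng)
        alpha = 5e-12
        scaled = scale_dti(f, alpha)
        assert np.allclose(
            scaled.determinants(), alpha**3 * f.determinants(), rtol=1e-10
        )

    def test_fa_invariant_under_scaling(self, rng):
        grid = ge.build_grid((10.0, 10.0, 10.0), (4, 4, 4))
        f = self._random_spd_field(grid, rng)
        assert np.allclose(
            fractional_anisotropy(scale_dti(f, 5e-12)),
            fractional_anisotropy(f),
            atol=1e-10,
        )

    def test_non_spd_rejected_with_cell_report_and_repair(self):
        grid = ge.build_grid((4.0, 4.0), (2, 2))
        tensors = np.broadcast_to(np.eye(2), (2, 2, 2, 2)).copy()
        tensors[1, 0] = np.diag([1.0, -0.5])
        f = TensorField(grid, tensors)
        with pytest.raises(ValueError, match=r"\(1, 0\)"):
            scale_dti(f, 1.0)
        repaired = scale_dti(f, 1.0, repair=True)
        assert np.all(repaired.eigenvalues() > 0.0)


class TestTensorDivergence:
    def test_constant_field_zero_drift(self, grid2d):
        f = homogeneous_field(grid2d, 2.5)
        b = tensor_divergence(f)
        assert np.allclose(b.vectors, 0.0)

    def test_linear_field_exact(self):
        # D = diag(c x1, c x2) -> b = (c, c) exactly under first-order FD
        grid = ge.build_grid((10.0, 10.0), (10, 10))
        c = 0.7
        x = grid.cell_centers(0)
        y = grid.cell_centers(1)
        tensors = np.zeros(grid.cell_shape + (2, 2))
        tensors[..., 0, 0] = c * x[:, None] + 5.0
        tensors[..., 1, 1] = c * y[None, :] + 5.0
        b = tensor_divergence(TensorField(grid, tensors))
        assert np.allclose(b.vectors[..., 0], c, atol=1e-12)
        assert np.allclose(b.vectors[..., 1], c, atol=1e-12)

    def test_butterfly_matches_symbolic_derivative(self):
        grid = ge.build_grid((200.0, 200.0), (200, 200))
        f = butterfly_field(grid)
        b = tensor_divergence(f)
        x = grid.cell_centers(0)
        exact = 0.9 * (3.0 * np.pi / 200.0) * np.cos(3.0 * np.pi * x / 200.0)
        h = grid.spacing[0]
        interior = slice(1, -1)
        err = np.abs(b.vectors[interior, :, 0] - exact[interior, None]).max()
        assert err < 0.5 * (3.0 * np.pi / 200.0 * h)  # first-order FD error
        assert np.allclose(b.vectors[..., 1], 0.0, atol=1e-14)

    def test_single_cell_axis_rejected(self):
        grid = ge.build_grid((10.0, 10.0), (1, 5))
        with pytest.raises(ValueError):
            tensor_divergence(homogeneous_field(grid))

    def test_first_order_convergence_against_dense_oracle(self):
        # smooth field: refining the grid shrinks the divergence error
        errs = []
        for n in (32, 64, 128):
            grid = ge.build_grid((10.0,), (n,))
            x = grid.cell_centers(0)
            tensors = (2.0 + np.sin(x))[:, None, None]
            b = tensor_divergence(TensorField(grid, tensors))
            errs.append(np.abs(b.vectors[1:-1, 0] - np.cos(x[1:-1])).max())
        assert errs[1] < errs[0] and errs[2] < errs[1]


class TestFractionalAnisotropy:
    def test_isotropic_zero(self):
        grid = ge.build_grid((5.0, 5.0, 5.0), (2, 2, 2))
        f = homogeneous_field(grid, 3.0)
        assert np.allclose(fractional_anisotropy(f), 0.0)

    def test_rank_deficient_limit(self):
        grid = ge.build_grid((2.0, 2.0, 2.0), (1, 1, 1))
        eps = 1e-9
        f = TensorField(grid, np.diag([1.0, eps, eps])[None, None, None])
        assert fractional_anisotropy(f)[0, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_two_one_one_value(self):
        grid = ge.build_grid((2.0, 2.0, 2.0), (1, 1, 1))
        f = TensorField(grid, np.diag([2.0, 1.0, 1.0])[None, None, None])
        assert fractional_anisotropy(f)[0, 0, 0] == pytest.approx(
            np.sqrt(1.5) / 3.0, rel=1e-12
        )

    def test_invariant_under_rotation_and_scaling(self, rng):
        grid = ge.build_grid((2.0, 2.0, 2.0), (2, 2, 2))
        lam = np.array([3.0, 1.5, 0.5])
        base = TensorField(
            grid, np.broadcast_to(np.diag(lam), grid.cell_shape + (3, 3)).copy()
        )
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = TensorField(
            grid, np.einsum("ik,...kl,jl->...ij", q, 7.0 * base.tensors, q)
        )
        assert np.allclose(
            fractional_anisotropy(rotated), fractional_anisotropy(base), atol=1e-12
        )

    def test_banded_3d_field_has_fa_bands(self):
        grid = ge.build_grid((40.0, 40.0, 40.0), (4, 4, 16))
        f = banded_anisotropic_field(grid, fa_amplitude=0.6, bands=2)
        f.check_spd()
        fa = fractional_anisotropy(f)
        assert fa.max() > 0.25 and fa.min() < 0.05
        # unit determinant everywhere by construction
        assert np.allclose(f.determinants(), 1.0, atol=1e-12)


class TestPecletField:
    def test_homogeneous_zero(self, grid2d):
        f = homogeneous_field(grid2d, 1.0)
        tau = peclet_field(f, tensor_divergence(f))
        assert np.allclose(tau, 0.0)

    def test_direct_formula(self):
        grid = ge.build_grid((2.0, 2.0), (2, 2))
        f = homogeneous_field(grid, 1.0 / np.sqrt(2.0))  # |D|_F = 1
        vec = np.zeros(grid.cell_shape + (2,))
        vec[..., 0] = 0.3
        tau = peclet_field(f, DriftField(grid, vec), spacing=1.0)
        assert np.allclose(tau, 0.3)

    def test_linear_in_spacing(self):
        grid = ge.build_grid((200.0, 200.0), (50, 50))
        f = butterfly_field(grid)
        b = tensor_divergence(f)
        tau1 = peclet_field(f, b, spacing=2.0)
        tau2 = peclet_field(f, b, spacing=4.0)
        assert np.allclose(tau2, 2.0 * tau1)
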