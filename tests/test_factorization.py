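"""Spectral range test, indicator maps, definiteness, monotonicity chain."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fmeit as fm
from fmeit.factorization import DegenerateOperatorError

from conftest import unit_currents


class TestSpectralAbs:
    def test_psd_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        B = rng.standard_normal((6, 6))
        A = B @ B.T
        dec = fm.spectral_abs(A)
        assert np.allclose(np.sort(dec.abs_eigenvalues),
                           np.sort(np.linalg.eigvalsh(A)), atol=1e-10)
        assert np.allclose(dec.reconstruct_abs(), A, atol=1e-10)

    def test_signed_diagonal(self):
        dec = fm.spectral_abs(np.diag([-2.0, 3.0]))
        assert np.allclose(dec.abs_eigenvalues, [3.0, 2.0])
        assert np.allclose(dec.signed_eigenvalues, [3.0, -2.0])

    def test_abs_squared_equals_squared(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((7, 7))
        A = 0.5 * (A + A.T)
        dec = fm.spectral_abs(A)
        absA = dec.reconstruct_abs()
        assert np.allclose(absA @ absA, A @ A, rtol=1e-12, atol=1e-12)

    def test_orthonormal_vectors(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((9, 9))
        dec = fm.spectral_abs(A + A.T)
        V = dec.vectors
        assert np.abs(V.T @ V - np.eye(9)).max() < 1e-10

    def test_asymmetric_input_rejected(self):
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            fm.spectral_abs(A)


class TestPicardRatio:
    def make_phi(self, vec, basis):
        return fm.BoundaryFunction(vec, basis)

    def test_top_eigenvector_gives_top_eigenvalue(self, basis8):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((8, 8))
        A = A + A.T
        dec = fm.spectral_abs(A)
        phi = self.make_phi(dec.vectors[:, 0], basis8)
        assert fm.picard_ratio(dec, phi) == pytest.approx(dec.abs_eigenvalues[0],
                                                          rel=1e-12)

    def test_scaling_linearity(self, basis8):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((8, 8))
        A = A + A.T
        phi = self.make_phi(rng.standard_normal(8), basis8)
        i1 = fm.picard_ratio(fm.spectral_abs(A), phi)
        i2 = fm.picard_ratio(fm.spectral_abs(2 * A), phi)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)

    def test_orthogonal_test_function_gives_infinity(self, basis8):
        A = np.diag([4.0, 2.0, 1.0] + [0.0] * 5)
        dec = fm.spectral_abs(A)
        opts = fm.FMOptions(eps_rel=1e-3, max_modes=3)
        phi = self.make_phi(np.eye(8)[:, 5], basis8)
        assert fm.picard_ratio(dec, phi, opts) == np.inf

    def test_degenerate_operator_raises(self, basis8):
        dec = fm.spectral_abs(np.zeros((8, 8)))
        with pytest.raises(DegenerateOperatorError):
            fm.picard_ratio(dec, self.make_phi(np.ones(8), basis8))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_series_on_random_matrices(self, seed):
        # independent oracle: direct truncated sum from numpy eigendecomposition
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((5, 5))
        A = A + A.T
        phi_vec = rng.standard_normal(5)
        basis = fm.make_boundary_basis(fm.BoundaryArc.full_circle(), 5)
        opts = fm.FMOptions(eps_rel=1e-12, max_modes=3)
        got = fm.picard_ratio(fm.spectral_abs(A), fm.BoundaryFunction(phi_vec, basis),
                              opts)
        lam, V = np.linalg.eigh(A)
        order = np.argsort(-np.abs(lam))[:3]
        u = phi_vec / np.linalg.norm(phi_vec)
        s = sum((V[:, k] @ u) ** 2 / abs(lam[k]) for k in order)
        assert got == pytest.approx(1.0 / s, rel=1e-10)


class TestDefinitenessCheck:
    def test_zero_matrix(self):
        assert fm.definiteness_check(np.zeros((4, 4))) == "zero"

    def test_matches_pointwise_ordering(self, mesh_coarse, bg, basis8, disk_phantom):
        L0 = fm.assemble_ntd(mesh_coarse, bg, basis8).matrix
        L1 = fm.assemble_ntd(mesh_coarse, disk_phantom.field, basis8).matrix
        assert fm.definiteness_check(L0 - L1) == "PSD"   # σ ≥ σ₀ shrinks the NtD
        assert fm.definiteness_check(L1 - L0) == "NSD"

    def test_mixed_contrast_phantom_is_indefinite(self, mesh_coarse, bg, basis8):
        phantom = fm.make_phantom(1.0, [
            fm.ShapeSpec(kind="disk", contrast=1.0, center=(0.35, 0.0), radius=0.2),
            fm.ShapeSpec(kind="disk", contrast=-0.5, center=(-0.35, 0.0), radius=0.2)])
        L0 = fm.assemble_ntd(mesh_coarse, bg, basis8).matrix
        L1 = fm.assemble_ntd(mesh_coarse, phantom.field, basis8).matrix
        assert fm.definiteness_check(L1 - L0) == "indefinite"


class TestMonotonicityVerify:
    def test_equal_conductivities_give_zero_chain(self, mesh_coarse, bg, basis8):
        triples, ok = fm.monotonicity_verify(mesh_coarse, bg, bg,
                                             unit_currents(basis8))
        assert ok
        assert np.abs(np.asarray(triples)).max() < 1e-12

    def test_inclusion_phantom_energy_ratio_bounds(self, mesh_coarse, bg, basis8,
                                                   disk_phantom, fem_bg_coarse):
        # for σ = 1 + χ_D: ∫_D|∇u₀|² ≥ g'(Λ(1)−Λ(σ))g ≥ ½∫_D|∇u₀|²
        L0 = fem_bg_coarse.ntd_matrix()
        L1 = fm.assemble_ntd(mesh_coarse, disk_phantom.field, basis8).matrix
        w = disk_phantom.region().on_mesh(mesh_coarse).astype(float)
        for g in unit_currents(basis8):
            u0 = fem_bg_coarse.solve_current(g)
            eD = fem_bg_coarse.region_energy(u0.values, weight=w)
            mid = float(g.coefficients @ ((L0 - L1) @ g.coefficients))
            assert 0.5 - 1e-10 <= mid / eD <= 1.0 + 1e-10

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 1_000))
    def test_chain_holds_for_random_ordered_phantoms(self, seed, mesh_coarse, basis8):
        # random piecewise-constant σ₁ ≥ σ₀: identities hold to round-off
        rng = np.random.default_rng(seed)
        sigma0 = np.full(mesh_coarse.n_triangles, 1.0)
        bump = rng.uniform(0.0, 2.0) * fm.ShapeSpec(
            kind="disk", contrast=1.0,
            center=tuple(rng.uniform(-0.4, 0.4, 2)),
            radius=rng.uniform(0.1, 0.3)).contains(mesh_coarse.centroids)
        sigma1 = sigma0 + bump
        currents = [fm.BoundaryFunction(rng.standard_normal(8), basis8)
                    for _ in range(4)]
        triples, ok = fm.monotonicity_verify(mesh_coarse, sigma0, sigma1, currents)
        assert ok
        for lo, mid, up in triples:
            assert lo <= mid + 1e-10 * max(abs(lo), abs(mid), abs(up))

    def test_mesh_mismatch_rejected(self, mesh_coarse, bg, basis8):
        other = fm.disk_mesh(0.1)
        sigma1 = np.full(other.n_triangles, 2.0)
        with pytest.raises(ValueError):
            fm.monotonicity_verify(mesh_coarse, bg, sigma1, unit_currents(basis8))


@pytest.fixture(scope="module")
def operators(mesh_mid, bg, basis16, disk_phantom):
    L0 = fm.assemble_ntd(mesh_mid, bg, basis16)
    L1 = fm.assemble_ntd(mesh_mid, disk_phantom.field, basis16)
    return L0, L1


class TestIndicatorMaps:
    def test_identical_operators_flagged_degenerate(self, operators, basis16):
        L0, _ = operators
        provider = fm.disk_dipole_provider(basis16)
        grid = np.array([[0.0, 0.0], [0.3, 0.0]])
        imap = fm.fm_indicator_map(L0, L0, provider, grid)
        assert imap.metadata["degenerate"]
        assert not imap.mask.any()

    def test_inside_point_beats_mirrored_outside_point(self, operators, basis16):
        L0, L1 = operators
        provider = fm.disk_dipole_provider(basis16)
        grid = np.array([[0.3, 0.0], [-0.6, 0.0]])
        imap = fm.fm_indicator_map(L1, L0, provider, grid)
        assert imap.values[0] > imap.values[1]

    def test_mask_threshold_semantics(self, operators, basis16):
        L0, L1 = operators
        provider = fm.disk_dipole_provider(basis16)
        grid = np.array([[0.3, 0.0], [0.35, 0.05], [-0.6, 0.0], [-0.7, 0.2]])
        opts = fm.FMOptions(threshold_c=0.25)
        imap = fm.fm_indicator_map(L1, L0, provider, grid, opts)
        finite = np.isfinite(imap.values)
        expect = finite & (imap.values >= 0.25 * imap.values[finite].max())
        assert np.array_equal(imap.mask, expect)

    def test_basis_mismatch_rejected(self, operators, mesh_mid, bg):
        _, L1 = operators
        other_basis = fm.make_boundary_basis(fm.BoundaryArc.full_circle(), 8)
        L0_small = fm.assemble_ntd(mesh_mid, bg, other_basis)
        provider = fm.disk_dipole_provider(other_basis)
        with pytest.raises(ValueError):
            fm.fm_indicator_map(L1, L0_small, provider, np.zeros((1, 2)))

    def test_indefinite_reduces_to_definite_with_empty_region(self, operators,
                                                              basis16):
        L0, L1 = operators
        provider = fm.disk_dipole_provider(basis16)
        grid = np.array([[0.3, 0.0], [0.0, 0.4], [-0.5, 0.0]])
        opts = fm.FMOptions(beta=1.5)
        a = fm.fm_indicator_map(L1, L0, provider, grid, opts)
        b = fm.fm_indefinite_map(L1, L0, fm.RegionMask.empty(), "b", provider,
                                 grid, opts)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.mask, b.mask)

    def test_indefinite_requires_shift_magnitude(self, operators, mesh_mid, bg,
                                                 basis16):
        L0, L1 = operators
        provider = fm.disk_dipole_provider(basis16)
        E = fm.RegionMask.from_shapes([fm.ShapeSpec(
            kind="disk", contrast=0.0, center=(-0.4, 0.0), radius=0.2)])
        with pytest.raises(ValueError, match="beta"):
            fm.fm_indefinite_map(L1, L0, E, "b", provider, np.zeros((1, 2)),
                                 mesh=mesh_mid, sigma0=bg)

    def test_shifted_operator_psd_when_assumption_holds(self, mesh_mid, bg, basis16):
        # σ = 1 + χ_{D+} − ½χ_{D−}, D− ⊆ E, case b: Λ(1)−Λ(σ)+2β M_E ⪰ 0
        Dp = fm.ShapeSpec(kind="disk", contrast=1.0, center=(0.35, 0.0), radius=0.25)
        Dm = fm.ShapeSpec(kind="disk", contrast=-0.5, center=(-0.4, 0.0), radius=0.15)
        phantom = fm.make_phantom(1.0, [Dp, Dm])
        E = fm.RegionMask.from_shapes([fm.ShapeSpec(
            kind="disk", contrast=0.0, center=(-0.4, 0.0), radius=0.2)])
        L0 = fm.assemble_ntd(mesh_mid, bg, basis16).matrix
        L1 = fm.assemble_ntd(mesh_mid, phantom.field, basis16).matrix
        M = fm.assemble_virtual_gram(mesh_mid, bg, E, basis16).matrix
        beta = 1.1   # > ‖(σ₀/σ)(σ₀−σ)‖_∞ = 1 for the −1/2 contrast
        shifted = (L0 - L1) + 2.0 * beta * M
        lam = np.linalg.eigvalsh(shifted)
        assert lam.min() >= -1e-8 * np.abs(lam).max()
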