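import numpy as np
import pytest
import scipy.linalg

from tnlm import (
    LBParams,
    SurfaceMesh,
    TimeSeriesField,
    TNLMParams,
    lb_eigenbasis,
    lb_filter,
    linked_neighborhoods,
    make_grid_mesh,
    standardize,
    tnlm_filter,
    tnlm_weight,
)
from tnlm.mesh import _cotangent_stiffness, _lumped_mass


def orthogonal_pair(T=64):
    """Two exactly zero-correlation standardized series."""
    t = np.arange(T)
    a = np.sqrt(2) * np.cos(2 * np.pi * t / T)
    b = np.sqrt(2) * np.sin(2 * np.pi * t / T)
    return a, b


class TestStandardize:
    def test_affine_series(self):
        fld = standardize(TimeSeriesField(data=np.array([[1.0, 2.0, 3.0]])))
        assert abs(fld.data[0].mean()) < 1e-12
        assert abs(fld.data[0].var() - 1.0) < 1e-12

    def test_constant_series_flagged_zero(self):
        fld = standardize(TimeSeriesField(data=np.array([[5.0, 5.0, 5.0]])))
        assert np.array_equal(fld.data[0], np.zeros(3))
        assert fld.zero_variance[0]

    def test_distance_correlation_identity(self, random_standardized):
        # (1/T) ||d(s) - d(r)||^2 = 2 - 2 corr for population-standardized
        fld = random_standardized(40, 80)
        d = fld.data
        T = fld.T
        for s, r in [(0, 1), (5, 30), (12, 12), (39, 2)]:
            dist2 = np.sum((d[s] - d[r]) ** 2) / T
            corr = d[s] @ d[r] / T
            assert abs(dist2 - (2 - 2 * corr)) < 1e-10

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            standardize(TimeSeriesField(data=np.ones((3, 1))))


class TestStandardizeProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 20),
        T=st.integers(3, 60),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariants_and_distance_identity(self, seed, n, T):
        rng = np.random.default_rng(seed)
        fld = standardize(TimeSeriesField(data=rng.standard_normal((n, T))))
        assert np.all(np.abs(fld.data.mean(axis=1)) < 1e-10)
        assert np.allclose(fld.data.var(axis=1), 1.0, atol=1e-8)
        d = fld.data
        s, r = 0, n - 1
        dist2 = np.sum((d[s] - d[r]) ** 2) / T
        corr = d[s] @ d[r] / T
        assert abs(dist2 - (2 - 2 * corr)) < 1e-10


class TestTNLMWeight:
    def test_identical_series_weight_one(self):
        a, _ = orthogonal_pair()
        assert tnlm_weight(a, a, h=0.72) == pytest.approx(1.0)

    def test_zero_correlation_value(self):
        a, b = orthogonal_pair()
        assert tnlm_weight(a, b, h=0.72) == pytest.approx(
            np.exp(-2 / 0.72**2), rel=1e-12
        )

    def test_anticorrelated_attains_minimum(self):
        a, _ = orthogonal_pair()
        for h in (0.5, 0.72, 1.73):
            assert tnlm_weight(a, -a, h=h) == pytest.approx(
                np.exp(-4 / h**2), rel=1e-12
            )

    def test_symmetric_and_decreasing_in_dissimilarity(self):
        a, b = orthogonal_pair()
        w_ab = tnlm_weight(a, b, h=0.72)
        assert w_ab == pytest.approx(tnlm_weight(b, a, h=0.72))
        # corr 1 > corr 0 > corr -1 ordering of weights
        assert tnlm_weight(a, a, 0.72) > w_ab > tnlm_weight(a, -a, 0.72)

    def test_unstandardized_input_rejected(self):
        with pytest.raises(ValueError):
            tnlm_weight(np.ones(10) * 3, np.ones(10) * 3, h=0.72)


class TestTNLMFilter:
    def make_field(self, rng, n=9, T=50):
        mesh = make_grid_mesh(3)
        fld = standardize(
            TimeSeriesField(data=rng.standard_normal((n, T)))
        )
        return mesh, fld

    def test_identical_series_everywhere_is_fixed_point(self):
        mesh = make_grid_mesh(3)
        a, _ = orthogonal_pair()
        fld = TimeSeriesField(
            data=np.tile(a, (9, 1)),
            standardized=True,
            zero_variance=np.zeros(9, bool),
        )
        out = tnlm_filter(fld, linked_neighborhoods(mesh, 2))
        assert np.allclose(out.data, fld.data)

    def test_self_only_neighborhood_is_identity(self, rng):
        mesh, fld = self.make_field(rng)
        out = tnlm_filter(fld, linked_neighborhoods(mesh, 0))
        assert np.allclose(out.data, fld.data)

    def test_hand_computed_three_vertex_average(self):
        # single triangle: every vertex neighbors both others
        mesh = SurfaceMesh(
            vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            triangles=np.array([[0, 1, 2]]),
        )
        a, b = orthogonal_pair(32)
        d = np.vstack([a, b, -a])
        fld = TimeSeriesField(
            data=d, standardized=True, zero_variance=np.zeros(3, bool)
        )
        h = 0.72
        out = tnlm_filter(
            fld, linked_neighborhoods(mesh, 1), TNLMParams(h=h, D=1)
        )
        w0 = np.exp(-2 / h**2)  # corr 0
        wm = np.exp(-4 / h**2)  # corr -1
        expected0 = (1 * a + w0 * b + wm * (-a)) / (1 + w0 + wm)
        assert np.allclose(out.data[0], expected0, atol=1e-12)
        expected1 = (w0 * a + 1 * b + w0 * (-a)) / (w0 + 1 + w0)
        assert np.allclose(out.data[1], expected1, atol=1e-12)

    def test_output_is_convex_combination(self, rng):
        mesh, fld = self.make_field(rng)
        nbrs = linked_neighborhoods(mesh, 1)
        out = tnlm_filter(fld, nbrs, TNLMParams(h=0.72, D=1))
        for s in range(9):
            lo = fld.data[nbrs[s]].min(axis=0) - 1e-12
            hi = fld.data[nbrs[s]].max(axis=0) + 1e-12
            assert np.all(out.data[s] >= lo) and np.all(out.data[s] <= hi)

    def test_h_limits(self, rng):
        mesh, fld = self.make_field(rng)
        nbrs = linked_neighborhoods(mesh, 1)
        wide = tnlm_filter(fld, nbrs, TNLMParams(h=1e6, D=1))
        for s in range(9):
            assert np.allclose(
                wide.data[s], fld.data[nbrs[s]].mean(axis=0), atol=1e-8
            )
        narrow = tnlm_filter(fld, nbrs, TNLMParams(h=1e-3, D=1))
        assert np.allclose(narrow.data, fld.data, atol=1e-10)

    def test_commutes_with_time_permutation(self, rng):
        mesh, fld = self.make_field(rng)
        nbrs = linked_neighborhoods(mesh, 1)
        perm = rng.permutation(fld.T)
        out_then_perm = tnlm_filter(fld, nbrs).data[:, perm]
        permuted = TimeSeriesField(
            data=fld.data[:, perm],
            standardized=True,
            zero_variance=fld.zero_variance,
        )
        perm_then_out = tnlm_filter(permuted, nbrs).data
        assert np.allclose(out_then_perm, perm_then_out)

    def test_nonlinearity_superposition_violated(self, rng):
        mesh, _ = self.make_field(rng)
        nbrs = linked_neighborhoods(mesh, 1)

        def run(d):
            return tnlm_filter(
                standardize(TimeSeriesField(data=d)), nbrs
            ).data

        d1 = rng.standard_normal((9, 50))
        d2 = rng.standard_normal((9, 50))
        assert not np.allclose(run(d1 + d2), run(d1) + run(d2))

    def test_zero_variance_vertex_passes_through_as_zeros(self, rng):
        mesh = make_grid_mesh(3)
        d = rng.standard_normal((9, 50))
        d[4] = 7.0  # constant -> zero variance
        fld = standardize(TimeSeriesField(data=d))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = tnlm_filter(fld, linked_neighborhoods(mesh, 1))
        assert np.array_equal(out.data[4], np.zeros(50))

    def test_requires_standardized_field(self, rng):
        mesh = make_grid_mesh(3)
        fld = TimeSeriesField(data=rng.standard_normal((9, 50)))
        with pytest.raises(ValueError, match="standardized"):
            tnlm_filter(fld, linked_neighborhoods(mesh, 1))


class TestLBFilter:
    def test_t_zero_identity_with_full_basis(self, rng):
        mesh = make_grid_mesh(5)
        basis = lb_eigenbasis(mesh, mesh.n_vertices)
        fld = TimeSeriesField(data=rng.standard_normal((25, 10)))
        out = lb_filter(fld, basis, LBParams(t=0.0))
        assert np.allclose(out.data, fld.data, atol=1e-8)

    def test_large_t_tends_to_surface_mean(self, rng):
        mesh = make_grid_mesh(5)
        basis = lb_eigenbasis(mesh, mesh.n_vertices)
        fld = TimeSeriesField(data=rng.standard_normal((25, 4)))
        out = lb_filter(fld, basis, LBParams(t=1e6))
        # constant-mode projection = mass-weighted surface mean per frame
        m = basis.mass
        mean = (m[:, None] * fld.data).sum(axis=0) / m.sum()
        assert np.allclose(out.data, np.tile(mean, (25, 1)), atol=1e-8)

    def test_matches_dense_heat_kernel_oracle(self, rng):
        mesh = make_grid_mesh(6)  # 36 vertices
        basis = lb_eigenbasis(mesh, mesh.n_vertices)
        fld = TimeSeriesField(data=rng.standard_normal((36, 7)))
        t = 1.7
        out = lb_filter(fld, basis, LBParams(t=t))
        S = _cotangent_stiffness(mesh).toarray()
        M = _lumped_mass(mesh)
        oracle = scipy.linalg.expm(-t * (S / M[:, None])) @ fld.data
        err = np.linalg.norm(out.data - oracle) / np.linalg.norm(oracle)
        assert err < 1e-6

    def test_linear_in_the_field(self, rng):
        mesh = make_grid_mesh(5)
        basis = lb_eigenbasis(mesh, 20)
        d1 = rng.standard_normal((25, 6))
        d2 = rng.standard_normal((25, 6))
        p = LBParams(t=2.0)
        lhs = lb_filter(TimeSeriesField(data=d1 + 3 * d2), basis, p).data
        rhs = (
            lb_filter(TimeSeriesField(data=d1), basis, p).data
            + 3 * lb_filter(TimeSeriesField(data=d2), basis, p).data
        )
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_vertex_count_mismatch_rejected(self, rng):
        mesh = make_grid_mesh(5)
        basis = lb_eigenbasis(mesh, 10)
        fld = TimeSeriesField(data=rng.standard_normal((24, 6)))
        with pytest.raises(Exception, match="vertices"):
            lb_filter(fld, basis)
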