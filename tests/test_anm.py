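import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from tetherscope.anm import (
    DisconnectedNetworkWarning,
    build_anm,
    coupling_fraction,
    cross_correlation,
    inverse_square_spring,
    normalize_fluctuations,
    rv_coefficient,
    select_modes_80,
    square_fluctuations,
)


def numeric_hessian_oracle(coords, cutoff, gamma, h=1e-5):
    """Central-difference second derivatives of the elastic-network energy
    E = 1/2 sum_contacts gamma(d0) (d - d0)^2, evaluated at the native
    coordinates. Independent of the analytic block construction."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    d0 = squareform(pdist(coords))
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if 0 < d0[i, j] <= cutoff
    ]

    def energy(flat):
        x = flat.reshape(n, 3)
        e = 0.0
        for i, j in pairs:
            d = np.linalg.norm(x[i] - x[j])
            e += 0.5 * float(gamma(d0[i, j])) * (d - d0[i, j]) ** 2
        return e

    x0 = coords.ravel()
    m = 3 * n
    hess = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            ea, eb = np.zeros(m), np.zeros(m)
            ea[a] = h
            eb[b] = h
            f = (
                energy(x0 + ea + eb)
                - energy(x0 + ea - eb)
                - energy(x0 - ea + eb)
                + energy(x0 - ea - eb)
            ) / (4 * h * h)
            hess[a, b] = hess[b, a] = f
    return hess


def compact_beads(n, rng, scale=4.0):
    return rng.normal(size=(n, 3)) * scale


class TestBuildAnm:
    def test_dimer_single_mode(self):
        coords = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                           [0.0, 10.0, 0.0]])
        # use only the first two beads via a large third-bead separation
        gamma = inverse_square_spring()
        with pytest.warns(DisconnectedNetworkWarning):
            m = build_anm(
                np.array([[0.0, 0, 0], [10.0, 0, 0], [500.0, 400, 0]]),
                cutoff=15.0,
            )
        nz = m.eigenvalues[m.eigenvalues > 0]
        assert nz.size == 1
        assert nz[0] == pytest.approx(2 * float(gamma(10.0)), rel=1e-8)

    def test_hessian_rows_sum_to_zero(self, rng):
        coords = compact_beads(8, rng)
        m = build_anm(coords)
        n = coords.shape[0]
        blocks = m.hessian.reshape(n, 3, n, 3)
        np.testing.assert_allclose(blocks.sum(axis=2), 0.0, atol=1e-10)

    def test_square_has_six_zero_and_six_positive_modes(self):
        square = np.array(
            [[0, 0, 0], [8, 0, 0], [8, 8, 0], [0, 8, 0]], float
        ) + np.array([0, 0, 0.0])
        square[3, 2] = 1.0  # break planarity so geometry is non-degenerate
        m = build_anm(square, cutoff=15.0)
        assert m.zero_modes == 6
        assert np.sum(m.eigenvalues > 0) == 6

    def test_matches_numeric_hessian_oracle(self, rng):
        for n in (5, 8, 10):
            coords = compact_beads(n, rng)
            gamma = inverse_square_spring()
            m = build_anm(coords, cutoff=15.0, spring=gamma)
            oracle = numeric_hessian_oracle(coords, 15.0, gamma)
            scale = np.abs(oracle).max()
            np.testing.assert_allclose(m.hessian, oracle, atol=1e-5 * scale)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0) * 3, np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            build_anm(line)


class TestModeSelection:
    def _model_with_eigenvalues(self, eigenvalues):
        class Fake:
            pass

        m = Fake()
        m.eigenvalues = np.concatenate([np.zeros(6), np.asarray(eigenvalues)])
        m.zero_modes = 6
        m.nonzero_modes = lambda: np.arange(6, m.eigenvalues.size)
        return m

    def test_single_mode(self):
        m = self._model_with_eigenvalues([2.0])
        assert select_modes_80(m) == [6]

    def test_two_of_three_modes(self):
        # variances 1, 1, 1/8 -> fractions .4706, .4706, .0588
        m = self._model_with_eigenvalues([1.0, 1.0, 8.0])
        assert select_modes_80(m) == [6, 7]

    def test_dominant_first_mode(self):
        m = self._model_with_eigenvalues([1.0, 100.0, 100.0, 100.0, 100.0])
        # 1/1 = 0.9615 of the total variance: first mode alone
        assert select_modes_80(m) == [6]


class TestFluctuations:
    def test_dimer_symmetry(self):
        with pytest.warns(DisconnectedNetworkWarning):
            m = build_anm(
                np.array([[0.0, 0, 0], [10.0, 0, 0], [500.0, 400, 0]]),
                cutoff=15.0,
            )
        mode = [int(np.flatnonzero(m.eigenvalues > 0)[0])]
        f = square_fluctuations(m, mode)
        assert f[0] == pytest.approx(f[1], rel=1e-9)

    def test_nonnegative_and_rigid_motion_invariant(self, rng):
        coords = compact_beads(12, rng)
        m1 = build_anm(coords)
        modes1 = select_modes_80(m1)
        f1 = square_fluctuations(m1, modes1)
        assert np.all(f1 >= 0)
        rot = Rotation.from_euler("xyz", [30, 100, 250], degrees=True).as_matrix()
        m2 = build_anm(coords @ rot.T + np.array([3.0, -8.0, 1.0]))
        f2 = square_fluctuations(m2, select_modes_80(m2))
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_uniform_ring_equal_fluctuations(self):
        # puckered ring: every bead equivalent under the ring's symmetry
        # (rotation by one position composed with z-reflection)
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pucker = 0.5 * (-1.0) ** np.arange(12)
        ring = np.column_stack([7 * np.cos(t), 7 * np.sin(t), pucker])
        m = build_anm(ring, cutoff=15.0)
        f = square_fluctuations(m, m.nonzero_modes())
        np.testing.assert_allclose(f, f[0], rtol=1e-6)

    def test_normalize_trims_and_standardizes(self, rng):
        f = rng.random(20) + 0.5
        prof = normalize_fluctuations(f, trim=5)
        assert prof.normalized.size == 10
        assert prof.normalized.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.normalized.std() == pytest.approx(1.0, rel=1e-12)

    def test_constant_profile_warns_zeros(self):
        with pytest.warns(UserWarning):
            prof = normalize_fluctuations(np.full(20, 3.0), trim=5)
        np.testing.assert_array_equal(prof.normalized, 0.0)

    def test_too_short_to_trim(self):
        with pytest.raises(ValueError):
            normalize_fluctuations(np.ones(10), trim=5)


class TestCrossCorrelation:
    def test_unit_diagonal_and_bounds(self, rng):
        m = build_anm(compact_beads(15, rng))
        c = cross_correlation(m, select_modes_80(m))
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert np.all(np.abs(c) <= 1.0 + 1e-12)
        np.testing.assert_allclose(c, c.T, atol=1e-12)

    def test_dimer_stretch_anticorrelated(self):
        # hand-built two-bead model: single stretch mode along the bond,
        # beads moving in anti-phase
        from tetherscope.anm import AnmModel, inverse_square_spring

        d = 10.0
        gamma = float(inverse_square_spring()(d))
        rij = np.array([d, 0.0, 0.0])
        k = (gamma / d**2) * np.outer(rij, rij)
        hess = np.block([[k, -k], [-k, k]])
        w, v = np.linalg.eigh(hess)
        w[np.abs(w) < 1e-10] = 0.0
        m = AnmModel(
            coords=np.array([[0.0, 0, 0], [d, 0, 0]]),
            cutoff=15.0,
            hessian=hess,
            eigenvalues=w,
            eigenvectors=v,
            zero_modes=int(np.sum(w == 0)),
        )
        mode = [int(np.flatnonzero(m.eigenvalues > 0)[0])]
        assert m.eigenvalues[mode[0]] == pytest.approx(2 * gamma)
        c = cross_correlation(m, mode)
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        coords = compact_beads(10, rng)
        m1 = build_anm(coords)
        c1 = cross_correlation(m1, select_modes_80(m1))
        rot = Rotation.from_euler("zyx", [75, 10, 190], degrees=True).as_matrix()
        m2 = build_anm(coords @ rot.T - 4.0)
        c2 = cross_correlation(m2, select_modes_80(m2))
        np.testing.assert_allclose(c1, c2, atol=1e-8)


class TestRvCoefficient:
    def test_self_is_one(self, rng):
        a = rng.normal(size=(6, 6))
        a = a + a.T
        assert rv_coefficient(a, a) == pytest.approx(1.0)

    def test_known_value(self):
        a = np.eye(2)
        b = np.ones((2, 2))
        assert rv_coefficient(a, b) == pytest.approx(2 / np.sqrt(8))

    @given(st.integers(0, 300))
    def test_scale_invariance_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 5))
        a = a @ a.T  # positive semidefinite
        b = rng.normal(size=(5, 5))
        b = b @ b.T
        c = float(rng.uniform(0.1, 10))
        assert rv_coefficient(a, c * a) == pytest.approx(1.0)
        assert rv_coefficient(a, b) == pytest.approx(rv_coefficient(b, a))
        assert 0.0 <= rv_coefficient(a, b) <= 1.0 + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError):
            rv_coefficient(np.eye(3), np.eye(4))
        with pytest.raises(ValueError):
            rv_coefficient(np.zeros((3, 3)), np.eye(3))


class TestCouplingFraction:
    def test_zero_offdiagonals(self):
        assert coupling_fraction(np.eye(5)) == 0.0

    def test_inclusive_threshold(self):
        c = np.full((4, 4), 0.7)
        np.fill_diagonal(c, 1.0)
        assert coupling_fraction(c) == 1.0
        c2 = np.full((4, 4), 0.699)
        np.fill_diagonal(c2, 1.0)
        assert coupling_fraction(c2) == 0.0

    def test_absolute_value(self):
        c = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert coupling_fraction(c) == 1.0
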