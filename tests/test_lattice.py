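"""Förster lattice simulator: geometry, rates, energy migration, portraits."""

import numpy as np
import pytest

from polim2d import (
    AngleGrid,
    FretNetwork,
    anisotropy,
    build_lattice,
    distance_sweep,
    emission_distribution,
    ensemble_portrait,
    fit_sfa,
    kappa_squared,
    modulation_emission,
    modulation_excitation,
    realization_portrait,
    substitute_dimers,
    transfer_rates,
)
from polim2d.lattice import DipoleSystem, random_orientations


def master_equation_emission(rates: np.ndarray, initial: int) -> np.ndarray:
    """Independent oracle: direct linear solve of the visit-count equations.

    v = e_initial + T^T v  =>  v = (I - T^T)^-1 e_initial, emission = v * p_emit.
    """
    n = rates.shape[0]
    total = rates.sum(axis=1)
    p_emit = 1.0 / (1.0 + total)
    hop = rates * p_emit[:, None]
    e0 = np.zeros(n)
    e0[initial] = 1.0
    visits = np.linalg.solve(np.eye(n) - hop.T, e0)
    return visits * p_emit


class TestBuildLattice:
    def test_single_site_lattice(self):
        sys_ = build_lattice(1, 5.0, seed=0)
        assert sys_.n_dipoles == 1
        assert sys_.central_index == 0

    def test_3x3x3_geometry(self):
        sys_ = build_lattice(3, 5.0, seed=0)
        assert sys_.n_dipoles == 27
        assert np.allclose(sys_.positions[sys_.central_index], 0.0)
        d = np.linalg.norm(sys_.positions - sys_.positions[sys_.central_index], axis=1)
        assert np.min(d[d > 0]) == pytest.approx(5.0)

    def test_even_n_side_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_lattice(4, 5.0)

    def test_orientations_are_isotropic_unit_vectors(self):
        mu = random_orientations(100_000, np.random.default_rng(1))
        assert np.allclose(np.linalg.norm(mu, axis=1), 1.0, atol=1e-12)
        # isotropy oracle: <mu_z^2> = 1/3
        assert np.mean(mu[:, 2] ** 2) == pytest.approx(1 / 3, abs=5e-3)

    def test_reproducible_under_seed(self):
        a = build_lattice(3, 5.0, seed=42)
        b = build_lattice(3, 5.0, seed=42)
        assert np.array_equal(a.orientations, b.orientations)


class TestSubstituteDimers:
    def test_fraction_zero_is_identity(self):
        sys_ = build_lattice(3, 13.0, seed=0)
        out = substitute_dimers(sys_, 0.0, seed=1)
        assert np.array_equal(out.positions, sys_.positions)
        assert np.array_equal(out.orientations, sys_.orientations)

    def test_fraction_one_doubles_count_with_fixed_separation(self):
        sys_ = build_lattice(3, 13.0, seed=0)
        out = substitute_dimers(sys_, 1.0, separation=3.5, seed=1)
        assert out.n_dipoles == 54
        # partners are consecutive; all intra-dimer distances 3.5 nm, centered
        # on the original lattice sites
        pairs = out.positions.reshape(27, 2, 3)
        gaps = np.linalg.norm(pairs[:, 0] - pairs[:, 1], axis=1)
        assert np.allclose(gaps, 3.5)
        assert np.allclose(pairs.mean(axis=1), sys_.positions)

    def test_partial_fraction_count_is_binomial(self):
        sys_ = build_lattice(7, 13.0, seed=0)
        out = substitute_dimers(sys_, 0.5, seed=2)
        n_sites = 343
        extra = out.n_dipoles - n_sites
        sd = np.sqrt(n_sites * 0.25)
        assert abs(extra - 0.5 * n_sites) < 4 * sd

    def test_central_dipole_still_at_center(self):
        sys_ = build_lattice(3, 13.0, seed=0)
        out = substitute_dimers(sys_, 1.0, seed=3)
        assert np.linalg.norm(out.positions[out.central_index]) <= 3.5 / 2 + 1e-12


class TestKappaSquared:
    def test_parallel_perpendicular_to_separation(self):
        assert kappa_squared([0, 0, 1], [0, 0, 1], [1, 0, 0]) == pytest.approx(1.0)

    def test_collinear_head_to_tail(self):
        assert kappa_squared([1, 0, 0], [1, 0, 0], [1, 0, 0]) == pytest.approx(4.0)

    def test_orthogonal_configuration_is_zero(self):
        assert kappa_squared([0, 0, 1], [0, 1, 0], [1, 0, 0]) == pytest.approx(0.0)

    def test_isotropic_average_is_two_thirds(self):
        rng = np.random.default_rng(5)
        mu = random_orientations(200_000, rng)
        nu = random_orientations(200_000, rng)
        vals = [kappa_squared(a, b, [1.0, 0, 0]) for a, b in zip(mu[:5000], nu[:5000])]
        assert np.mean(vals) == pytest.approx(2 / 3, abs=0.03)


class TestTransferRates:
    def _pair(self, mu_i, mu_j, r, r0=4.7):
        return DipoleSystem(
            positions=np.array([[0.0, 0, 0], [r, 0, 0]]),
            orientations=np.array([mu_i, mu_j], dtype=float),
            central_index=0,
            spacing=r,
            r0=r0,
        )

    def test_rate_is_radiative_rate_at_r0_for_isotropic_kappa(self):
        # mu_i.mu_j = sqrt(2/3) with both perpendicular to R gives kappa^2 = 2/3
        c = np.sqrt(2 / 3)
        s = np.sqrt(1 - 2 / 3)
        sys_ = self._pair([0, 0, 1], [0, s, c], r=4.7)
        k = transfer_rates(sys_).rates
        assert k[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_sixth_power_distance_scaling(self):
        near = transfer_rates(self._pair([0, 0, 1], [0, 0, 1], r=4.7)).rates[0, 1]
        far = transfer_rates(self._pair([0, 0, 1], [0, 0, 1], r=9.4)).rates[0, 1]
        assert far / near == pytest.approx(2.0**-6)

    def test_rates_symmetric_for_identical_spectra(self):
        sys_ = build_lattice(3, 5.0, seed=7)
        k = transfer_rates(sys_).rates
        assert np.allclose(k, k.T)
        assert np.all(k >= 0)
        assert np.all(np.diag(k) == 0)

    def test_cutoff_zeroes_distant_pairs_only(self):
        sys_ = build_lattice(3, 13.0, seed=7)
        k_cut = transfer_rates(sys_, cutoff=1.0).rates
        k_full = transfer_rates(sys_, cutoff=None).rates
        assert np.all(k_cut == 0)  # 13 nm > R0
        assert np.any(k_full > 0)

    def test_coincident_dipoles_rejected(self):
        sys_ = self._pair([0, 0, 1], [0, 0, 1], r=4.7)
        sys_.positions[1] = 0.0
        with pytest.raises(ValueError, match="coincident"):
            transfer_rates(sys_)


class TestEmissionDistribution:
    def test_uncoupled_dipole_keeps_the_excitation(self):
        net = FretNetwork(rates=np.zeros((5, 5)))
        probs = emission_distribution(net, initial=3)
        assert np.allclose(probs, np.eye(5)[3], atol=1e-9)

    def test_symmetric_pair_with_unit_rate(self):
        # geometric series: donor 2/3, acceptor 1/3
        net = FretNetwork(rates=np.array([[0.0, 1.0], [1.0, 0.0]]))
        probs = emission_distribution(net, initial=0)
        assert probs[0] == pytest.approx(2 / 3, abs=1e-9)
        assert probs[1] == pytest.approx(1 / 3, abs=1e-9)

    def test_strong_coupling_equilibrates(self):
        # k >> radiative rate: many back-and-forth hops before emission, so
        # the pair equilibrates; exact split is ((1+k)/(1+2k), k/(1+2k))
        net = FretNetwork(rates=np.array([[0.0, 1e3], [1e3, 0.0]]))
        probs = emission_distribution(net, initial=0)
        assert np.allclose(probs, 0.5, atol=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_master_equation_oracle(self, seed):
        # random small networks: probabilities conserve energy and agree with
        # the direct linear solve of the master equation
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 5)
        rates = rng.uniform(0, 3, size=(n, n))
        rates = (rates + rates.T) / 2
        np.fill_diagonal(rates, 0.0)
        probs = emission_distribution(FretNetwork(rates=rates), initial=0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        oracle = master_equation_emission(rates, initial=0)
        assert np.allclose(probs, oracle, atol=1e-8)

    def test_lattice_realization_conserves_energy(self):
        sys_ = build_lattice(5, 5.0, seed=3)
        probs = emission_distribution(
            transfer_rates(sys_), initial=sys_.central_index
        )
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestRealizationPortrait:
    def test_single_inplane_dipole_is_cos2_cos2(self):
        grid = AngleGrid.default()
        sys_ = DipoleSystem(
            positions=np.zeros((1, 3)),
            orientations=np.array([[1.0, 0.0, 0.0]]),
            central_index=0,
            spacing=1.0,
            r0=4.7,
        )
        vals = realization_portrait(sys_, np.array([1.0]), grid)
        expected = (
            np.cos(np.deg2rad(grid.ex)) ** 2 * np.cos(np.deg2rad(grid.em)) ** 2
        )
        assert np.allclose(vals, expected, atol=1e-12)

    def test_axial_dipole_contributes_nothing(self):
        grid = AngleGrid.default()
        sys_ = DipoleSystem(
            positions=np.zeros((1, 3)),
            orientations=np.array([[0.0, 0.0, 1.0]]),
            central_index=0,
            spacing=1.0,
            r0=4.7,
        )
        vals = realization_portrait(sys_, np.array([1.0]), grid)
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_rotation_average_preserves_the_mean(self):
        grid = AngleGrid.default()
        rng = np.random.default_rng(0)
        sys_ = build_lattice(3, 5.0, seed=rng)
        probs = emission_distribution(transfer_rates(sys_), initial=sys_.central_index)
        plain = realization_portrait(sys_, probs, grid)
        avg = realization_portrait(sys_, probs, grid, rotation_average=True)
        assert np.mean(avg) == pytest.approx(np.mean(plain), rel=1e-9)


class TestEnsemble:
    def test_ensemble_is_isotropic_within_mc_error(self):
        portrait, _ = ensemble_portrait(
            13.0, n_side=3, n_realizations=400, seed=9, rotation_average=False
        )
        m_ex, _ = modulation_excitation(portrait)
        m_em, _ = modulation_emission(portrait)
        assert m_ex < 0.1 and m_em < 0.1

    def test_anisotropy_independent_of_orientation(self):
        portrait, _ = ensemble_portrait(13.0, n_side=3, n_realizations=200, seed=9)
        rs = [anisotropy(portrait, phi) for phi in (0.0, 30.0, 45.0, 120.0)]
        assert np.ptp(rs) < 0.05

    def test_stderr_shrinks_with_realizations(self):
        _, se_small = ensemble_portrait(6.5, n_side=3, n_realizations=50, seed=1)
        _, se_big = ensemble_portrait(6.5, n_side=3, n_realizations=400, seed=1)
        assert np.mean(se_big) < np.mean(se_small)

    def test_sweep_monotone_trends_and_schema(self):
        table = distance_sweep(
            [3.5, 6.5, 13.0], n_side=5, n_realizations=60, repeats=3, seed=4
        )
        assert list(table.columns) == ["d_nm", "r_mean", "r_sd", "eps_mean", "eps_sd", "n"]
        r = table.r_mean.to_numpy()
        eps = table.eps_mean.to_numpy()
        slack = 0.03  # small-lattice MC error allowance
        assert all(b >= a - slack for a, b in zip(r, r[1:]))  # r grows with d
        assert all(b <= a + slack for a, b in zip(eps, eps[1:]))  # eps falls

    def test_dense_limit_depolarizes_and_funnels(self):
        portrait, _ = ensemble_portrait(3.5, n_side=3, n_realizations=300, seed=2)
        assert abs(anisotropy(portrait, 0.0)) < 0.08
        assert fit_sfa(portrait).eps > 0.85
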