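"""SLATM spectra: analytic values, oracle equivalence, invariances."""

import numpy as np
import pytest
from scipy.stats import norm, special_ortho_group

from cgslatm import (
    Configuration,
    CoincidentBeadsError,
    SlatmParams,
    atomic_slatm,
    gaussian_bin_profile,
    three_body_spectrum,
    two_body_spectrum,
)

from .oracles import brute_force_three_body, brute_force_two_body
from .conftest import random_configuration


def config(positions, types, n_solute=1):
    flags = np.zeros(len(positions), dtype=bool)
    flags[:n_solute] = True
    return Configuration(np.asarray(positions, float), np.array(types, dtype=object), flags)


class TestGaussianBinProfile:
    def test_interior_kernel_has_unit_mass(self, params):
        g = gaussian_bin_profile(4.0, 0.3, params.r_bin_centers, 0.2)
        # oracle: CDF differences of the normal over the bin edges
        edges = np.arange(params.n_bins_r + 1) * 0.2
        cdf_mass = np.diff(norm.cdf(edges, loc=4.0, scale=0.3)).sum()
        assert g.sum() == pytest.approx(1.0, abs=1e-6)
        assert g.sum() == pytest.approx(cdf_mass, abs=1e-6)

    def test_far_value_contributes_nothing(self, params):
        g = gaussian_bin_profile(20.0, 0.3, params.r_bin_centers, 0.2)
        assert (np.abs(g) < 1e-12).all()

    def test_narrow_sigma_concentrates_in_one_bin(self, params):
        # delta limit: every bin but the one containing the value vanishes
        g = gaussian_bin_profile(3.05, 1e-4, params.r_bin_centers, 0.2)
        assert (np.delete(g, 15) < 1e-12).all()  # bin 15 covers [3.0, 3.2)
        g = gaussian_bin_profile(3.1, 1e-4, params.r_bin_centers, 0.2)
        assert np.argmax(g) == 15
        assert g[15] / g.sum() == pytest.approx(1.0, rel=1e-12)

    def test_edge_value_keeps_mass_with_folding(self, params):
        g = gaussian_bin_profile(
            np.pi,
            params.sigma_theta,
            params.theta_bin_centers,
            params.bin_width_theta,
            reflect=(0.0, params.theta_support),
        )
        assert g.sum() == pytest.approx(1.0, abs=1e-3)


class TestTwoBodySpectrum:
    def test_single_pair_analytic_london_mass(self, registry3, params):
        reg = registry3  # Z: T1=1, Nda=2, POL=3
        cfg = config([[0, 0, 0], [4.0, 0, 0]], ["Nda", "POL"])
        hist = two_body_spectrum(cfg, 0, "POL", params, reg)
        expected = 0.5 * 2 * 3 * 4.0**-6  # = 7.3242e-4
        assert hist.sum() == pytest.approx(7.3242e-4, rel=0.01)
        assert hist.sum() == pytest.approx(expected, rel=0.01)

    def test_absent_neighbor_type_gives_zero_vector(self, registry3, params):
        cfg = config([[0, 0, 0], [4.0, 0, 0]], ["T1", "T1"])
        assert not two_body_spectrum(cfg, 0, "POL", params, registry3).any()

    def test_neighbor_beyond_cutoff_gives_zero_vector(self, registry3, params):
        cfg = config([[0, 0, 0], [9.0, 0, 0]], ["T1", "POL"])
        assert not two_body_spectrum(cfg, 0, "POL", params, registry3).any()

    def test_entries_nonnegative(self, registry3, params, rng):
        cfg = random_configuration(rng, registry3, 10)
        for t in registry3.names:
            assert (two_body_spectrum(cfg, 0, t, params, registry3) >= 0).all()

    def test_coincident_beads_raise(self, registry3, params):
        cfg = config([[0, 0, 0], [0, 0, 1e-8]], ["T1", "POL"])
        with pytest.raises(CoincidentBeadsError):
            two_body_spectrum(cfg, 0, "POL", params, registry3)

    def test_total_mass_decreases_with_distance(self, registry3, params):
        # R^-6 law: strictly monotone on a distance grid
        masses = []
        for r in np.linspace(2.0, 7.0, 12):
            cfg = config([[0, 0, 0], [r, 0, 0]], ["T1", "POL"])
            masses.append(
                two_body_spectrum(cfg, 0, "POL", params, registry3).sum()
            )
        assert all(a > b for a, b in zip(masses, masses[1:]))


class TestThreeBodySpectrum:
    def test_equilateral_triangle_analytic_atm_mass(self, registry3, params):
        s = 3.0
        cfg = config(
            [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]],
            ["T1", "T1", "T1"],
        )
        hist = three_body_spectrum(cfg, 0, ("T1", "T1"), params, registry3)
        # angular factor 1 + 3*(1/2)^3 = 1.375; weight (1/3)*1.375/3^9
        assert hist.sum() == pytest.approx(2.3283e-5, rel=0.01)

    def test_collinear_triplet_negative_atm_mass(self, registry3, params):
        cfg = config(
            [[0, 0, 0], [-2.0, 0, 0], [2.0, 0, 0]], ["T1", "T1", "T1"]
        )
        hist = three_body_spectrum(cfg, 0, ("T1", "T1"), params, registry3)
        # cosines (-1, 1, 1): factor -2; weight -2/(3*(2*2*4)^3)
        assert hist.sum() == pytest.approx(-1.6276e-4, rel=0.01)

    def test_fewer_than_two_in_cutoff_neighbors_zero(self, registry3, params):
        cfg = config(
            [[0, 0, 0], [3.0, 0, 0], [20.0, 0, 0]], ["T1", "POL", "POL"]
        )
        assert not three_body_spectrum(
            cfg, 0, ("POL", "POL"), params, registry3
        ).any()

    def test_cross_type_pair_matches_oracle(self, registry3, params, rng):
        cfg = random_configuration(rng, registry3, 8)
        zmap = {n: registry3.z_of(n) for n in registry3.names}
        got = three_body_spectrum(cfg, 0, ("Nda", "POL"), params, registry3)
        want = brute_force_three_body(
            cfg.positions, list(cfg.types), zmap, 0, ("Nda", "POL"), params
        )
        np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-16)


class TestAtomicSlatm:
    def test_isolated_bead_is_identity_only(self, registry3, index3, params):
        cfg = config([[0, 0, 0]], ["T1"])
        spec = atomic_slatm(cfg, 0, params, registry3, index3)
        assert spec.one_body == 1.0
        assert not any(v.any() for v in spec.two_body.values())
        assert not any(v.any() for v in spec.three_body.values())

    def test_channel_block_shapes(self, registry14, index14, params, rng):
        cfg = random_configuration(rng, registry14, 6)
        spec = atomic_slatm(cfg, 0, params, registry14, index14)
        # per center: N two-body maps and N(N+1)/2 three-body maps
        assert len(spec.two_body) == 14
        assert len(spec.three_body) == 105
        assert all(len(v) == params.n_bins_r for v in spec.two_body.values())
        assert all(
            len(v) == params.n_bins_theta for v in spec.three_body.values()
        )

    def test_composes_from_per_channel_calls(self, registry3, index3, params, rng):
        cfg = random_configuration(rng, registry3, 7)
        spec = atomic_slatm(cfg, 0, params, registry3, index3)
        for t in registry3.names:
            np.testing.assert_allclose(
                spec.two_body[t],
                two_body_spectrum(cfg, 0, t, params, registry3),
                rtol=1e-12,
                atol=1e-18,
            )
        for pair in index3.two_body:
            np.testing.assert_allclose(
                spec.three_body[pair],
                three_body_spectrum(cfg, 0, pair, params, registry3),
                rtol=1e-12,
                atol=1e-18,
            )


class TestOracleEquivalence:
    def test_fifty_random_configurations(self, registry3, index3, params, rng):
        zmap = {n: registry3.z_of(n) for n in registry3.names}
        for trial in range(50):
            n = int(rng.integers(2, 16))
            cfg = random_configuration(rng, registry3, n)
            center = int(rng.integers(n))
            spec = atomic_slatm(cfg, center, params, registry3, index3)
            types = list(cfg.types)
            for t in registry3.names:
                want = brute_force_two_body(
                    cfg.positions, types, zmap, center, t, params
                )
                np.testing.assert_allclose(
                    spec.two_body[t], want, rtol=1e-8, atol=1e-16
                )
            for pair in index3.two_body:
                want = brute_force_three_body(
                    cfg.positions, types, zmap, center, pair, params
                )
                np.testing.assert_allclose(
                    spec.three_body[pair], want, rtol=1e-8, atol=1e-16
                )


class TestInvariances:
    @staticmethod
    def flat(spec):
        parts = [np.atleast_1d(spec.one_body)]
        parts += [spec.two_body[k] for k in sorted(spec.two_body)]
        parts += [spec.three_body[k] for k in sorted(spec.three_body)]
        return np.concatenate(parts)

    def test_rigid_motion_and_relabeling(self, registry3, index3, params, rng):
        cfg = random_configuration(rng, registry3, 15)
        ref = self.flat(atomic_slatm(cfg, 0, params, registry3, index3))
        for _ in range(5):
            R = special_ortho_group.rvs(3, random_state=rng)
            t = rng.uniform(-50, 50, size=3)
            perm = rng.permutation(15)
            moved = Configuration(
                (cfg.positions @ R.T + t)[perm],
                cfg.types[perm],
                cfg.solute_flags[perm],
            )
            center = int(np.flatnonzero(perm == 0)[0])
            got = self.flat(
                atomic_slatm(moved, center, params, registry3, index3)
            )
            np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_locality_beyond_cutoff_plus_tails(self, registry3, index3, params, rng):
        cfg = random_configuration(rng, registry3, 10)
        ref = self.flat(atomic_slatm(cfg, 0, params, registry3, index3))
        far = cfg.positions[0] + np.array(
            [params.r_cutoff + 5 * params.sigma_r + 0.1, 0, 0]
        )
        extended = Configuration(
            np.vstack([cfg.positions, far]),
            np.append(cfg.types, "POL"),
            np.append(cfg.solute_flags, False),
        )
        got = self.flat(atomic_slatm(extended, 0, params, registry3, index3))
        np.testing.assert_allclose(got, ref, atol=1e-12)


class TestSlatmParams:
    def test_default_bin_counts(self, params):
        assert params.n_bins_r == 40  # ceil(8.0 / 0.2)
        assert params.n_bins_theta == 16  # ceil(pi / 0.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SlatmParams(sigma_r=0.0)
        with pytest.raises(ValueError):
            SlatmParams(r_cutoff=0.1, bin_width_r=0.2)
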