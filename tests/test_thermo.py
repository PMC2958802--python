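"""PMF, rotational entropy and dipole fluctuation tensor estimators."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import solvmap as sm
from solvmap.thermo import (
    N_ROTATIONAL_STATES,
    OVERFLOW_STATE,
    molecular_dipoles,
    pair_state_index,
    rotational_states,
)
from conftest import harmonic_expected_counts, make_ensemble, water_at


class TestOctants:
    @pytest.mark.parametrize("v,expected", [
        ((1, 1, 1), 7),
        ((-1, -1, -1), 0),
        ((0, 1, -1), 6),   # zero component ties to the non-negative side
        ((1, -1, 1), 5),
        ((-1, 1, -1), 2),
    ])
    def test_octant_convention(self, v, expected):
        assert sm.octant_index(np.array(v, float)) == expected

    def test_zero_vector_degenerate(self):
        with pytest.raises(sm.GeometryError):
            sm.octant_index(np.zeros(3))


class TestRotationalState:
    def test_28_states_enumerate_unordered_pairs(self):
        """The canonical encoding is a bijection with {i<j} octant pairs."""
        seen = {int(pair_state_index(i, j))
                for i, j in itertools.combinations(range(8), 2)}
        assert seen == set(range(N_ROTATIONAL_STATES))

    def test_pair_example_and_swap_symmetry(self):
        o = np.zeros(3)
        s1 = sm.rotational_state(o, [1, 1, 1], [-1, -1, -1])
        s2 = sm.rotational_state(o, [-1, -1, -1], [1, 1, 1])
        assert s1 == s2
        assert s1.octant_pair == (0, 7)

    def test_same_octant_maps_to_overflow(self):
        assert int(pair_state_index(3, 3)) == OVERFLOW_STATE

    def test_coincident_hydrogen_degenerate(self):
        with pytest.raises(sm.GeometryError):
            sm.rotational_state(np.zeros(3), np.zeros(3), [1, 0, 0])

    def test_overflow_impossible_for_rigid_water(self):
        """Two H-O vectors in one sign-octant subtend <= 90 deg, below 104.52."""
        spec = sm.SyntheticSpec(n_trajectories=1, n_frames=1, n_waters=100_000,
                                d_t=0.0, d_rot=0.0, orientation_mode="frozen", seed=9)
        ens = sm.gen_ensemble(spec)
        states = rotational_states(ens.coords[0].reshape(-1, 3, 3))
        assert np.all(states < OVERFLOW_STATE)
        # ... and all 28 states are reachable
        assert len(np.unique(states)) == N_ROTATIONAL_STATES


class TestCountField:
    def test_fixed_water_counts_frames(self, one_cell_grid):
        traj = np.repeat(water_at([5, 5, 5])[None, None], 100, axis=0)
        ens = make_ensemble([traj])
        c = sm.count_field(ens, one_cell_grid)
        assert c.values[0, 0, 0] == 100

    def test_conservation_with_out_of_grid(self, free_ensemble):
        grid = sm.GridSpec(origin=(0, 0, 0), spacing=5.0, dims=(4, 4, 4))
        c = sm.count_field(free_ensemble, grid)
        assert c.n_samples.sum() + c.meta["out_of_grid"] == free_ensemble.total_observations

    def test_uniform_gas_poisson_spread(self):
        """10^5 uniform points over 10^3 cells: ~100 per cell, Poisson spread."""
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 10, size=(100_000, 3))
        traj = np.zeros((1, 100_000, 3, 3))
        traj[..., :] = pts[None, :, None, :]
        ens = make_ensemble([traj], box=(10, 10, 10))
        grid = sm.GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(10, 10, 10))
        c = sm.count_field(ens, grid)
        assert c.values.mean() == pytest.approx(100.0)
        assert c.values.std() == pytest.approx(10.0, rel=0.15)

    def test_empty_ensemble_errors(self, one_cell_grid, tip3p):
        ens = sm.TrajectoryEnsemble(tip3p, [], 1.0, np.array([10.0, 10.0, 10.0]))
        with pytest.raises(sm.SolvmapError):
            sm.count_field(ens, one_cell_grid)


class TestBulkReference:
    def _field(self, values):
        grid = sm.GridSpec(origin=(0, 0, 0), spacing=1.0, dims=values.shape)
        ns = np.full(values.shape, 1000, dtype=int)
        return sm.ScalarField(grid, values, ns, np.ones(values.shape, bool), "counts")

    def test_constant_field(self):
        f = self._field(np.full((4, 4, 8), 7.0))
        ref = sm.bulk_reference(f, sm.Slab("z", 2.0, 6.0))
        assert ref.mean == 7.0 and ref.sd == 0.0 and ref.n_cells == 4 * 4 * 4

    def test_two_layer_z_index_mean(self):
        vals = np.fromfunction(lambda i, j, k: k, (3, 3, 8))
        ref = sm.bulk_reference(self._field(vals), sm.Slab("z", 4.0, 6.0))
        assert ref.mean == pytest.approx(4.5)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(5, 5, 10))
        f = self._field(vals)
        slab = sm.Slab("z", 3.0, 7.0)
        ref = sm.bulk_reference(f, slab)
        sub = vals[:, :, 3:7]
        assert ref.mean == pytest.approx(sub.mean())
        assert ref.sd == pytest.approx(sub.std(ddof=1))

    def test_partially_covered_cells_excluded(self):
        vals = np.fromfunction(lambda i, j, k: k, (3, 3, 8))
        # slab [3.5, 6) covers layer 3 only partially: layers 4, 5 qualify
        ref = sm.bulk_reference(self._field(vals), sm.Slab("z", 3.5, 6.0))
        assert ref.mean == pytest.approx(4.5) and ref.n_cells == 18

    def test_empty_region_errors(self):
        f = self._field(np.ones((3, 3, 3)))
        f.mask[...] = False
        f = sm.ScalarField(f.grid, np.ones((3, 3, 3)), f.n_samples,
                           np.zeros((3, 3, 3), bool), "counts")
        with pytest.raises(sm.SolvmapError):
            sm.bulk_reference(f, sm.Slab("z", 0.0, 3.0))


class TestPmfField:
    def _counts(self, values):
        grid = sm.GridSpec(origin=(0, 0, 0), spacing=1.0, dims=values.shape)
        return sm.ScalarField(grid, values.astype(float),
                              values.astype(int), np.ones(values.shape, bool), "counts")

    def test_uniform_density_gives_zero(self):
        c = self._counts(np.full((4, 4, 4), 500))
        ref = sm.bulk_reference(c, sm.Slab("z", 0.0, 4.0))
        w = sm.pmf_field(c, ref)
        np.testing.assert_allclose(w.values, 0.0, atol=1e-12)

    def test_one_kBT_depletion(self):
        vals = np.full((4, 4, 4), 500.0)
        vals[0, 0, 0] = 500.0 / np.e
        c = self._counts(vals)
        ref = sm.bulk_reference(c, sm.Slab("z", 1.0, 4.0))
        w = sm.pmf_field(c, ref)
        assert w.values[0, 0, 0] == pytest.approx(1.0)
        assert w.units == "k_BT"

    def test_zero_and_undersampled_cells_masked(self):
        vals = np.full((4, 4, 4), 500.0)
        vals[0, 0, 0] = 0.0
        vals[1, 1, 1] = 50.0
        c = self._counts(vals)
        ref = sm.bulk_reference(c, sm.Slab("z", 1.0, 4.0))
        w = sm.pmf_field(c, ref, min_samples=100)
        assert not w.mask[0, 0, 0] and not w.mask[1, 1, 1]
        assert w.mask[2, 2, 2]

    def test_boltzmann_inversion_recovers_harmonic_well(self):
        """-ln(density/bulk) reproduces a known U(r) from equilibrium draws."""
        k = 0.5
        pot = sm.HarmonicWell(center=(8.0, 8.0, 8.0), k=(k, k, k))
        pos = sm.gen_boltzmann_positions(pot, 60_000, (16.0, 16.0, 16.0), seed=0)
        traj = np.zeros((1, len(pos), 3, 3))
        traj[..., :] = pos[None, :, None, :]
        ens = make_ensemble([traj], box=(16, 16, 16))
        grid = sm.GridSpec(origin=(0, 0, 0), spacing=2.0, dims=(8, 8, 8))
        c = sm.count_field(ens, grid)
        slab = sm.Slab("z", 6.0, 10.0)
        w = sm.pmf_field(c, sm.bulk_reference(c, slab), min_samples=100)
        # exact oracle: expected counts from Gaussian cell integrals give the
        # predicted PMF; multinomial noise gives the per-cell standard error
        E, p = harmonic_expected_counts((k, k, k), (8.0, 8.0, 8.0),
                                        (16.0, 16.0, 16.0), grid, 60_000)
        w_pred = -np.log(E / E[slab.cell_selector(grid)].mean())
        resid = (w.values - w_pred)[w.mask]
        se = np.sqrt((1.0 - p[w.mask]) / E[w.mask])
        assert np.all(np.abs(resid) < 3 * se)


class TestMolecularDipole:
    def test_tip3p_magnitude(self, tip3p):
        sites = water_at([3.0, 4.0, 5.0], topology=tip3p)
        mu = sm.molecular_dipole(sites[0], sites[1], sites[2], tip3p)
        # 2 * 0.417 * 0.9572 * cos(52.26 deg) * 4.803 e*A->D
        assert np.linalg.norm(mu) == pytest.approx(2.347, abs=2e-3)

    def test_zero_charges_zero_dipole(self):
        topo = sm.WaterTopology(1, charges=(0.0, 0.0, 0.0))
        sites = water_at([0, 0, 0], topology=topo)
        mu = sm.molecular_dipole(sites[0], sites[1], sites[2], topo)
        np.testing.assert_array_equal(mu, 0.0)

    def test_translation_invariance(self, tip3p):
        sites = water_at([0, 0, 0], topology=tip3p)
        mu1 = sm.molecular_dipole(sites[0], sites[1], sites[2], tip3p)
        shifted = sites + np.array([17.0, -4.0, 2.5])
        mu2 = sm.molecular_dipole(shifted[0], shifted[1], shifted[2], tip3p)
        np.testing.assert_allclose(mu1, mu2, atol=1e-12)


class TestRotationalEntropy:
    def _entropy_of_k_states(self, k, seed=0):
        spec = sm.SyntheticSpec(n_trajectories=2, n_frames=14 * k, n_waters=30,
                                d_t=0.0, orientation_mode="uniform_states",
                                n_states=k, seed=seed)
        ens = sm.gen_ensemble(spec)
        grid = sm.GridSpec(origin=(-100.0, -100.0, -100.0), spacing=300.0, dims=(1, 1, 1))
        s = sm.rotational_entropy_field(ens, grid)
        return float(s.values[0, 0, 0])

    def test_single_state_zero_entropy(self):
        assert self._entropy_of_k_states(1) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 20, 28])
    def test_uniform_k_states_gives_ln_k(self, k):
        assert self._entropy_of_k_states(k) == pytest.approx(np.log(k), abs=1e-9)

    def test_two_states_below_bound_cutoff_twenty_above_bulk(self):
        assert self._entropy_of_k_states(2) < 0.7
        assert self._entropy_of_k_states(20) > 2.9

    def test_bounded_by_ln_28(self, free_ensemble, one_cell_grid):
        s = sm.rotational_entropy_field(free_ensemble, one_cell_grid)
        v = s.values[0, 0, 0]
        assert 0.0 <= v <= np.log(28) + 1e-12

    def test_axis_permutation_invariance(self, free_ensemble, one_cell_grid):
        """Cyclic relabeling of lab axes permutes octant states, leaving S fixed."""
        s1 = sm.rotational_entropy_field(free_ensemble, one_cell_grid)
        permuted = [c[..., [1, 2, 0]] for c in free_ensemble.coords]
        ens2 = make_ensemble(permuted, box=np.asarray(free_ensemble.box)[[1, 2, 0]],
                             topology=free_ensemble.topology)
        s2 = sm.rotational_entropy_field(ens2, one_cell_grid)
        assert s1.values[0, 0, 0] == pytest.approx(s2.values[0, 0, 0], abs=1e-12)

    def test_h_swap_invariance(self, free_ensemble, one_cell_grid):
        s1 = sm.rotational_entropy_field(free_ensemble, one_cell_grid)
        swapped = [c[:, :, [0, 2, 1], :] for c in free_ensemble.coords]
        ens2 = make_ensemble(swapped, topology=free_ensemble.topology)
        s2 = sm.rotational_entropy_field(ens2, one_cell_grid)
        assert s1.values[0, 0, 0] == s2.values[0, 0, 0]


class TestDipoleTensor:
    def test_frozen_orientation_zero_tensor(self, one_cell_grid):
        traj = np.repeat(water_at([5, 5, 5])[None, None], 150, axis=0)
        ens = make_ensemble([traj])
        t = sm.dipole_fluctuation_tensor_field(ens, one_cell_grid)
        np.testing.assert_allclose(t.values[0, 0, 0], 0.0, atol=1e-10)

    def test_isotropic_closed_form(self, one_cell_grid):
        """Uniform orientations: C -> diag(mu0^2/3), off-diagonals -> 0."""
        spec = sm.SyntheticSpec(n_trajectories=1, n_frames=1, n_waters=100_000,
                                d_t=0.0, orientation_mode="frozen", seed=21)
        ens = sm.gen_ensemble(spec)
        mu0_sq = np.sum(molecular_dipoles(
            ens.coords[0][0, 0][None], ens.topology)[0] ** 2)
        t = sm.dipole_fluctuation_tensor_field(ens, one_cell_grid)
        cov = t.values[0, 0, 0]
        np.testing.assert_allclose(np.diag(cov), mu0_sq / 3, rtol=0.02)
        trace = sm.tensor_trace_field(t).values[0, 0, 0]
        offdiag = sm.offdiagonal_sum_field(t).values[0, 0, 0]
        assert trace == pytest.approx(mu0_sq, rel=0.02)
        assert abs(offdiag) < 0.02 * mu0_sq

    def test_two_state_flip_cxx(self, one_cell_grid):
        """180-degree dipole flips along x: C_xx = mu0^2, all else 0."""
        spec = sm.SyntheticSpec(n_trajectories=1, n_frames=400, n_waters=20,
                                d_t=0.0, orientation_mode="two_state_flip", seed=2)
        ens = sm.gen_ensemble(spec)
        mu0 = np.linalg.norm(molecular_dipoles(ens.coords[0][0, 0][None], ens.topology)[0])
        t = sm.dipole_fluctuation_tensor_field(ens, one_cell_grid)
        cov = t.values[0, 0, 0]
        assert cov[0, 0] == pytest.approx(mu0 ** 2, rel=1e-9)
        np.testing.assert_allclose(cov - np.diag([mu0 ** 2, 0, 0]), 0.0, atol=1e-9)

    def test_symmetric_psd_and_oracle_equivalence(self, free_ensemble, one_cell_grid):
        """Accumulated covariance matches np.cov over the pooled dipole samples."""
        t = sm.dipole_fluctuation_tensor_field(free_ensemble, one_cell_grid)
        cov = t.values[0, 0, 0]
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)
        mus = np.concatenate([
            molecular_dipoles(c.reshape(-1, 3, 3), free_ensemble.topology)
            for c in free_ensemble.coords
        ])
        direct = np.cov(mus.T, ddof=0)
        np.testing.assert_allclose(cov, direct, rtol=1e-9, atol=1e-12)

    def test_trace_and_offdiag_summaries(self):
        grid = sm.GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(1, 1, 1))
        mat = np.array([[1.0, 0.5, 0.25], [0.5, 2.0, -0.5], [0.25, -0.5, 3.0]])
        t = sm.TensorField(grid, mat[None, None, None], np.full((1, 1, 1), 200),
                           np.ones((1, 1, 1), bool))
        assert sm.tensor_trace_field(t).values[0, 0, 0] == pytest.approx(6.0)
        assert sm.offdiagonal_sum_field(t).values[0, 0, 0] == pytest.approx(0.5)
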