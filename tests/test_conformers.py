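import numpy as np
import pytest

import torfes
from torfes import synthetic as syn
from torfes.conformers import (
    DISCARDED,
    ClusterSet,
    assign_memberships,
    cluster_conformers,
    filter_small_clusters,
    find_density_peaks,
    merge_shallow_clusters,
    saddle_free_energies,
)
from torfes.constants import KB
from torfes.geometry import ConfigurationSet, nearest_neighbors, pairwise_sq_dists
from torfes.reweight import PerPointFES


def _fes_from_rho(rho, temperature=300.0):
    rho = np.asarray(rho, dtype=float)
    f = -KB * temperature * np.log(rho)
    f -= f.min()
    return PerPointFES(rho_star=rho, rho_bar=rho, F=f, temperature=temperature)


def _pipeline_parts(cs, **kwargs):
    density, fes, nb = torfes.compute_per_point_fes(cs, **kwargs)
    return density, fes, nb


class TestFindDensityPeaks:
    def test_unimodal_single_center(self):
        mix = syn.TorusMixture([1.0], [[0.0, 0.0]], [[8.0, 8.0]])
        cs = syn.sample_unbiased(mix, 2000, seed=9)
        density, fes, nb = _pipeline_parts(cs)
        centers = find_density_peaks(fes, nb, density.k_selected)
        assert len(centers) >= 1
        # the global density argmax must be one of them
        assert int(np.argmax(fes.rho_bar)) in centers

    def test_two_separated_modes(self):
        mix = syn.TorusMixture(
            [0.5, 0.5], [[0.0, 0.0], [np.pi, np.pi]], [[10.0, 10.0], [10.0, 10.0]]
        )
        cs = syn.sample_unbiased(mix, 4000, seed=10)
        density, fes, nb = _pipeline_parts(cs)
        centers = find_density_peaks(fes, nb, density.k_selected)
        d2 = pairwise_sq_dists(cs.angles[centers], mix.means)
        # each true mode has a provisional center within 0.2 rad
        assert np.sqrt(d2.min(axis=0)).max() < 0.2


class TestAssignMemberships:
    def _simple(self, rho, angles, centers):
        cs = ConfigurationSet(np.asarray(angles, dtype=float))
        nb = nearest_neighbors(cs, cs.n - 1)
        fes = _fes_from_rho(rho)
        return assign_memberships(cs, fes, nb, np.asarray(centers))

    def test_chain_inheritance(self):
        labels = self._simple([3.0, 2.0, 1.0], [[0.0], [0.1], [0.2]], [0])
        assert labels.tolist() == [0, 0, 0]

    def test_equidistant_tie_smaller_index(self):
        # point 2 sits exactly between points 0 and 1, both denser
        labels = self._simple(
            [3.0, 3.0, 1.0], [[0.0], [1.0], [0.5]], [0, 1]
        )
        assert labels[2] == labels[0]

    def test_no_centers_raises(self):
        cs = ConfigurationSet(np.zeros((3, 1)))
        nb = nearest_neighbors(cs, 2)
        with pytest.raises(ValueError):
            assign_memberships(cs, _fes_from_rho([1.0, 2.0, 3.0]), nb, np.array([]))

    def test_all_points_reachable(self, small_ala2_sample):
        density, fes, nb = _pipeline_parts(small_ala2_sample)
        centers = find_density_peaks(fes, nb, density.k_selected)
        labels = assign_memberships(small_ala2_sample, fes, nb, centers)
        assert np.all(labels >= 0)


class TestSaddles:
    def test_no_contact_no_entry(self):
        # two tight, far-apart pairs; k neighbourhoods never cross
        angles = np.array([[0.0], [0.01], [3.0], [3.01]])
        cs = ConfigurationSet(angles)
        nb = nearest_neighbors(cs, 1)
        fes = _fes_from_rho([2.0, 1.0, 2.0, 1.0])
        saddles = saddle_free_energies(
            fes, nb, np.ones(4, dtype=int), np.array([0, 0, 1, 1])
        )
        assert saddles == {}

    def test_saddle_above_centers(self, small_ala2_sample):
        density, fes, nb = _pipeline_parts(small_ala2_sample)
        centers = find_density_peaks(fes, nb, density.k_selected)
        labels = assign_memberships(small_ala2_sample, fes, nb, centers)
        saddles = saddle_free_energies(fes, nb, density.k_selected, labels)
        center_f = {cid: fes.F[c] for cid, c in enumerate(centers)}
        for (a, b), sf in saddles.items():
            assert sf >= max(center_f[a], center_f[b]) - 1e-9

    def test_symmetric_double_well_barrier(self):
        kappa = syn.barrier_kappa(4.0)
        mix = syn.two_mode_mixture(kappa)
        cs = syn.sample_unbiased(mix, 6000, seed=33)
        density, fes, nb = _pipeline_parts(cs)
        centers = find_density_peaks(fes, nb, density.k_selected)
        labels = assign_memberships(cs, fes, nb, centers)
        saddles = saddle_free_energies(fes, nb, density.k_selected, labels)
        # the dominant pair's saddle approximates the analytic 4 kT barrier
        clusters = cluster_conformers(cs, fes, nb, density.k_selected)
        assert clusters.n_clusters == 2
        sf = clusters.saddle_F[(0, 1)]
        barrier_kt = (sf - clusters.center_F.max()) / (KB * 300.0)
        assert barrier_kt == pytest.approx(4.0, abs=1.2)


def _toy_clusterset(center_f, saddle, populations=None):
    k = len(center_f)
    assignment = np.repeat(np.arange(k), 10)
    pops = np.full(k, 10) if populations is None else np.asarray(populations)
    return ClusterSet(
        center_indices=np.arange(k),
        center_coords=np.zeros((k, 1)),
        center_F=np.asarray(center_f, dtype=float),
        assignment=assignment,
        populations=pops,
        saddle_F=saddle,
    )


class TestMerging:
    def test_zero_threshold_no_merges(self):
        cl = _toy_clusterset([0.0, 0.5], {(0, 1): 0.6})
        merged = merge_shallow_clusters(cl, 300.0, threshold_kt=0.0)
        assert merged.n_clusters == 2

    def test_shallow_pair_merges(self):
        kt = KB * 300.0
        cl = _toy_clusterset([0.0, 0.5], {(0, 1): 0.5 + 0.5 * kt})
        merged = merge_shallow_clusters(cl, 300.0, threshold_kt=1.0)
        assert merged.n_clusters == 1
        assert np.all(merged.assignment == 0)

    def test_deep_pair_survives(self):
        kt = KB * 300.0
        cl = _toy_clusterset([0.0, 0.5], {(0, 1): 0.5 + 3.0 * kt})
        merged = merge_shallow_clusters(cl, 300.0, threshold_kt=1.0)
        assert merged.n_clusters == 2

    def test_monotone_in_threshold(self):
        kt = KB * 300.0
        saddle = {(0, 1): 0.4 + 0.8 * kt, (1, 2): 0.4 + 2.0 * kt}
        counts = []
        for thr in (0.0, 1.0, 3.0, 10.0):
            cl = _toy_clusterset([0.0, 0.2, 0.4], dict(saddle))
            counts.append(merge_shallow_clusters(cl, 300.0, thr).n_clusters)
        assert counts == sorted(counts, reverse=True)

    def test_merged_keeps_lower_center(self):
        kt = KB * 300.0
        cl = _toy_clusterset([0.3, 0.0], {(0, 1): 0.3 + 0.1 * kt})
        merged = merge_shallow_clusters(cl, 300.0, 1.0)
        assert merged.center_F[0] == 0.0
        assert merged.center_indices[0] == 1


class TestFiltering:
    def test_strict_cutoff(self):
        assignment = np.concatenate([np.zeros(991, dtype=int), np.ones(9, dtype=int)])
        cl = ClusterSet(
            center_indices=np.array([0, 991]),
            center_coords=np.zeros((2, 1)),
            center_F=np.array([0.0, 1.0]),
            assignment=assignment,
            populations=np.array([991, 9]),
            saddle_F={},
        )
        out = filter_small_clusters(cl, 0.01)
        assert out.n_clusters == 1
        assert (out.assignment == DISCARDED).sum() == 9

    def test_exact_boundary_retained(self):
        assignment = np.concatenate([np.zeros(990, dtype=int), np.ones(10, dtype=int)])
        cl = ClusterSet(
            center_indices=np.array([0, 990]),
            center_coords=np.zeros((2, 1)),
            center_F=np.array([0.0, 1.0]),
            assignment=assignment,
            populations=np.array([990, 10]),
            saddle_F={},
        )
        out = filter_small_clusters(cl, 0.01)
        assert out.n_clusters == 2

    def test_zero_fraction_keeps_all(self):
        cl = _toy_clusterset([0.0, 1.0], {}, populations=[10, 10])
        assert filter_small_clusters(cl, 0.0).n_clusters == 2

    def test_all_removed_raises(self):
        assignment = np.concatenate([np.zeros(6, dtype=int), np.ones(4, dtype=int)])
        cl = ClusterSet(
            center_indices=np.array([0, 6]),
            center_coords=np.zeros((2, 1)),
            center_F=np.array([0.0, 1.0]),
            assignment=assignment,
            populations=np.array([6, 4]),
            saddle_F={},
        )
        with pytest.raises(ValueError):
            filter_small_clusters(cl, 0.7)


class TestClusterConformers:
    def test_three_mode_recovery(self, small_ala2_sample, ala2_mixture):
        _, _, _, clusters = torfes.run_pipeline(small_ala2_sample)
        assert clusters.n_clusters == 3
        d2 = pairwise_sq_dists(clusters.center_coords, ala2_mixture.means)
        assert np.sqrt(d2.min(axis=1)).max() < 0.25

    def test_center_f_zeroed_at_global_min(self, small_ala2_sample):
        _, _, _, clusters = torfes.run_pipeline(small_ala2_sample)
        assert clusters.center_F.min() == 0.0
        assert np.all(np.diff(clusters.center_F) >= 0)  # labels sorted by F

    def test_centers_are_local_minima(self, small_ala2_sample):
        density, fes, nb, clusters = torfes.run_pipeline(small_ala2_sample)
        for c in clusters.center_indices:
            ball = nb.indices[c][nb.distances[c] <= 0.1]
            assert np.all(fes.F[ball] >= fes.F[c])

    def test_uniform_single_cluster(self):
        rng = np.random.default_rng(77)
        cs = ConfigurationSet(rng.uniform(-np.pi, np.pi, size=(3000, 2)))
        _, _, _, clusters = torfes.run_pipeline(cs)
        assert clusters.n_clusters == 1

    def test_deterministic(self, small_ala2_sample):
        r1 = torfes.run_pipeline(small_ala2_sample)[3]
        r2 = torfes.run_pipeline(small_ala2_sample)[3]
        np.testing.assert_array_equal(r1.assignment, r2.assignment)
        np.testing.assert_array_equal(r1.center_indices, r2.center_indices)
        np.testing.assert_array_equal(r1.center_F, r2.center_F)

    def test_populations_sum(self, small_ala2_sample):
        _, _, _, clusters = torfes.run_pipeline(small_ala2_sample)
        n_assigned = (clusters.assignment != DISCARDED).sum()
        assert clusters.populations.sum() == n_assigned <= small_ala2_sample.n
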