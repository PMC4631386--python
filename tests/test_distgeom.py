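import numpy as np
import pytest

from shiftfold.distgeom import (BoundsMatrix, InconsistentBoundsError,
                                bounds_penalty, build_bounds,
                                chirality_volumes, embed, metrize_sample,
                                minimize, refine, select_lowest,
                                smooth_bounds, ConformerEnsemble)
from shiftfold.geom import rmsd, superpose
from shiftfold.io import (AtomRef, PeptideSequence, RestraintRow,
                          RestraintTable)
from shiftfold.peptide import Conformer, PeptideTopology, build_peptide


def toy_topology(n):
    """Bare n-point topology for matrix-level operations."""
    seq = PeptideSequence(["G"])
    return PeptideTopology(sequence=seq,
                           atoms=[AtomRef(1, f"X{i}") for i in range(n)],
                           elements=["C"] * n, bonds=[])


def toy_bounds(lower, upper):
    lower = np.asarray(lower, dtype=float)
    return BoundsMatrix(toy_topology(lower.shape[0]), lower,
                        np.asarray(upper, dtype=float))


def brute_force_smooth(lower, upper, passes=50):
    """Independent oracle: Floyd-Warshall uppers + iterated inverse
    triangle lowers, in pure python."""
    n = len(upper)
    u = [row[:] for row in upper]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                u[i][j] = min(u[i][j], u[i][k] + u[k][j])
    l = [row[:] for row in lower]
    for _ in range(passes):
        changed = False
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    cand = max(l[i][k] - u[k][j], l[j][k] - u[k][i])
                    if cand > l[i][j] + 1e-12:
                        l[i][j] = cand
                        changed = True
        if not changed:
            break
    return np.array(l), np.array(u)


class TestBuildBounds:
    def test_covalent_n_ca_distance_fixed(self):
        bm = build_bounds(PeptideSequence(list("GG")))
        topo = bm.topology
        i = topo.index_of(AtomRef(1, "N"))
        j = topo.index_of(AtomRef(1, "CA"))
        assert bm.lower[i, j] == bm.upper[i, j]
        assert bm.lower[i, j] == pytest.approx(1.458, abs=1e-6)

    def test_restraint_intersects_defaults(self, r4_sequence):
        # the steric default lower (here CA-CA, 2.72 A) beats a looser
        # experimental lower; the experimental upper tightens the ceiling
        table = RestraintTable(rows=[RestraintRow(
            AtomRef(62, "CA"), AtomRef(73, "CA"), 1.8, 3.5)])
        bm = build_bounds(r4_sequence, table)
        plain = build_bounds(r4_sequence)
        topo = bm.topology
        i = topo.index_of(AtomRef(62, "CA"))
        j = topo.index_of(AtomRef(73, "CA"))
        assert bm.upper[i, j] == 3.5
        assert bm.lower[i, j] == plain.lower[i, j] > 1.8

    def test_contradictory_restraint_on_bonded_pair(self, r4_sequence):
        table = RestraintTable(rows=[RestraintRow(
            AtomRef(65, "HB2"), AtomRef(65, "HB3"), 0.5, 1.0)])
        with pytest.raises(InconsistentBoundsError):
            build_bounds(r4_sequence, table)

    def test_one_four_bounds_bracket_rotation(self):
        bm = build_bounds(PeptideSequence(list("AA")))
        topo = bm.topology
        # HA(1)-HB* are 1-4 through CA-CB: cis < trans, strictly ordered
        i = topo.index_of(AtomRef(1, "HA"))
        j = topo.index_of(AtomRef(1, "HB1"))
        assert 0 < bm.lower[i, j] < bm.upper[i, j] < 3.5


class TestSmoothing:
    def test_three_node_shortest_path(self):
        u = [[0, 2, 10], [2, 0, 2], [10, 2, 0]]
        l = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
        out = smooth_bounds(toy_bounds(l, u))
        assert out.upper[0, 2] == pytest.approx(4.0)

    def test_idempotent_on_consistent_metric(self):
        u = np.array([[0, 2, 3.0], [2, 0, 2], [3.0, 2, 0]])
        l = np.array([[0, 1, 1.5], [1, 0, 1], [1.5, 1, 0]])
        once = smooth_bounds(toy_bounds(l, u))
        twice = smooth_bounds(once)
        assert np.allclose(once.upper, twice.upper)
        assert np.allclose(once.lower, twice.lower)

    def test_inverse_triangle_raises_lower(self):
        # l(A,B)=5 and u(B,C)=1 force l(A,C) >= 4
        u = np.array([[0, 9, 9.0], [9, 0, 1], [9, 1, 0]])
        l = np.array([[0, 5, 0.0], [5, 0, 0], [0, 0, 0]])
        out = smooth_bounds(toy_bounds(l, u))
        assert out.lower[0, 2] >= 4.0 - 1e-9

    def test_crossing_is_reported_with_pair(self):
        u = np.array([[0, 1, 1.0], [1, 0, 1], [1, 1, 0]])
        l = np.array([[0, 5, 0.0], [5, 0, 0], [0, 0, 0]])
        with pytest.raises(InconsistentBoundsError, match="X"):
            smooth_bounds(toy_bounds(l, u))

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(25):
            n = 8
            base = rng.uniform(1.0, 6.0, size=(n, n))
            u = np.triu(base, 1)
            u = u + u.T
            l = np.triu(rng.uniform(0.5, 1.0, size=(n, n)), 1)
            l = l + l.T
            bm = toy_bounds(l, u)
            got = smooth_bounds(bm)
            exp_l, exp_u = brute_force_smooth(l.tolist(), u.tolist())
            assert np.allclose(got.upper, exp_u, atol=1e-9)
            assert np.allclose(got.lower, exp_l, atol=1e-9)


class TestMetrization:
    def test_tight_bounds_reproduced_exactly(self):
        pts = np.array([[0, 0, 0.0], [1.5, 0, 0], [0.7, 1.2, 0], [0.2, 0.5, 1.1]])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        bm = toy_bounds(d, d)
        for seed in (0, 1, 99):
            assert np.allclose(metrize_sample(bm, seed), d)

    def test_samples_respect_bounds_three_atoms(self):
        l = np.array([[0, 1, 1.0], [1, 0, 1], [1, 1, 0]])
        u = np.array([[0, 2, 3.0], [2, 0, 2], [3, 2, 0]])
        bm = toy_bounds(l, u)
        sm = smooth_bounds(bm)
        for seed in range(300):
            d = metrize_sample(bm, seed, full=True)
            assert np.all(d >= sm.lower - 1e-9)
            assert np.all(d <= sm.upper + 1e-9)

    def test_same_seed_same_matrix(self):
        l = np.full((5, 5), 1.0)
        u = np.full((5, 5), 4.0)
        np.fill_diagonal(l, 0)
        np.fill_diagonal(u, 0)
        bm = toy_bounds(l, u)
        assert np.array_equal(metrize_sample(bm, 7), metrize_sample(bm, 7))
        assert not np.array_equal(metrize_sample(bm, 7), metrize_sample(bm, 8))


class TestEmbedding:
    def test_equilateral_triangle(self):
        d = np.array([[0, 1, 1.0], [1, 0, 1], [1, 1, 0]])
        with pytest.warns(UserWarning, match="degenerate"):  # planar input
            x = embed(d, dimensions=3)
        got = np.linalg.norm(x[:, None] - x[None], axis=-1)
        assert np.allclose(got, d, atol=1e-8)

    def test_known_conformer_reproduced(self, ideal_helix):
        d = ideal_helix.distances()
        x = embed(d, dimensions=3)
        aligned = superpose(x, ideal_helix.coords)
        err = rmsd(aligned, ideal_helix.coords, superposed=True)
        if err > 1e-6:  # embedding may return the mirror image
            x[:, 0] *= -1
            err = rmsd(superpose(x, ideal_helix.coords), ideal_helix.coords,
                       superposed=True)
        assert err < 1e-6

    def test_colinear_points_flagged_degenerate(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        d = np.abs(pts - pts.T)
        with pytest.warns(UserWarning, match="degenerate"):
            x = embed(d, dimensions=3)
        got = np.linalg.norm(x[:, None] - x[None], axis=-1)
        assert np.allclose(got, d, atol=1e-8)


class TestRefineAndMinimize:
    def test_feasible_3d_conformer_is_fixed_point(self, ideal_helix,
                                                  helix_bounds):
        conf = refine(ideal_helix, helix_bounds)
        assert conf.energy < 0.01
        assert np.allclose(conf.coords, ideal_helix.coords, atol=0.05)

    def test_planted_distances_recovered(self, ideal_helix, helix_bounds,
                                         backbone_indices):
        d = ideal_helix.distances()
        with pytest.warns(UserWarning, match="degenerate"):  # exact 3D input
            conf4 = embed(d, dimensions=4, topology=ideal_helix.topology)
        out = refine(conf4, helix_bounds)
        assert rmsd(out.coords[backbone_indices],
                    ideal_helix.coords[backbone_indices]) < 0.5

    def test_mirror_image_detected_and_reflected(self, ideal_helix,
                                                 helix_bounds):
        mirrored = ideal_helix.coords * np.array([-1.0, 1.0, 1.0])
        conf4 = Conformer(ideal_helix.topology,
                          np.hstack([mirrored, np.zeros((len(mirrored), 1))]))
        out = refine(conf4, helix_bounds)
        vols = chirality_volumes(out.topology, out.coords)
        assert np.all(vols > 0)

    def test_minimize_fixed_point_at_zero_energy(self, ideal_helix,
                                                 helix_bounds):
        start = refine(ideal_helix, helix_bounds)
        if start.energy < 1e-12:
            out = minimize(start, helix_bounds)
            assert np.array_equal(out.coords, start.coords)

    def test_minimize_descends_on_perturbed_helix(self, ideal_helix,
                                                  helix_bounds, rng):
        noisy = Conformer(ideal_helix.topology,
                          ideal_helix.coords + rng.normal(0, 0.3,
                                                          ideal_helix.coords.shape))
        e0 = bounds_penalty(noisy.coords, helix_bounds)
        out = minimize(noisy, helix_bounds)
        assert out.energy <= e0
        assert out.energy < e0  # 0.3 A noise always leaves room to descend


class TestSelection:
    def make_ensemble(self, energies):
        topo = toy_topology(2)
        confs = [Conformer(topo, np.zeros((2, 3)), energy=e,
                           metadata={"seed": i})
                 for i, e in enumerate(energies)]
        return ConformerEnsemble(conformers=confs,
                                 selection_rule=(len(confs), len(confs)))

    def test_keeps_k_smallest_sorted(self):
        ens = self.make_ensemble([5.0, 1.0, 3.0])
        kept = select_lowest(ens, 2)
        assert [c.energy for c in kept.conformers] == [1.0, 3.0]
        assert kept.selection_rule == (3, 2)

    def test_single_run_single_keep(self):
        ens = self.make_ensemble([2.0])
        kept = select_lowest(ens, 1)
        assert len(kept) == 1

    def test_ties_broken_by_generation_order(self):
        ens = self.make_ensemble([1.0, 1.0, 0.5])
        kept = select_lowest(ens, 2)
        assert [c.metadata["seed"] for c in kept.conformers] == [2, 0]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            select_lowest(self.make_ensemble([1.0]), 2)
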