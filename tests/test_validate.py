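import numpy as np
import pytest

from shiftfold.csp import classify_epitope
from shiftfold.distgeom import ConformerEnsemble
from shiftfold.io import AtomRef, RestraintRow, RestraintTable
from shiftfold.peptide import Conformer
from shiftfold.validate import (csp_contact_consistency, ensemble_rmsd,
                                violation_report)


def ensemble_of(conformers):
    return ConformerEnsemble(conformers=list(conformers))


class TestViolationReport:
    def test_upper_violation_measured(self, ideal_helix):
        topo = ideal_helix.topology
        d = ideal_helix.distances()
        i = topo.index_of(AtomRef(63, "H"))
        j = topo.index_of(AtomRef(70, "H"))
        table = RestraintTable(rows=[RestraintRow(
            topo.atoms[i], topo.atoms[j], 1.8, d[i, j] - 0.5)])
        rep = violation_report(ensemble_of([ideal_helix]), table)
        assert rep.per_restraint[0].max_violation == pytest.approx(0.5)
        assert rep.count_over_01 == 1
        assert rep.largest == pytest.approx(0.5)

    def test_within_bounds_is_zero(self, ideal_helix):
        topo = ideal_helix.topology
        d = ideal_helix.distances()
        i = topo.index_of(AtomRef(63, "HA"))
        j = topo.index_of(AtomRef(64, "H"))
        table = RestraintTable(rows=[RestraintRow(
            topo.atoms[i], topo.atoms[j], max(0.5, d[i, j] - 1), d[i, j] + 1)])
        rep = violation_report(ensemble_of([ideal_helix]), table)
        assert rep.largest == 0.0
        assert rep.count_over_01 == rep.count_over_05 == 0

    def test_truth_satisfies_its_own_restraints(self, ideal_helix,
                                                helix_restraints):
        # all uppers hold exactly; a handful of geminal pairs sit slightly
        # inside the conventional 1.8 A lower floor
        rep = violation_report(ensemble_of([ideal_helix]), helix_restraints)
        assert rep.count_over_05 == 0
        assert rep.largest < 0.2

    def test_exactly_satisfied_restraints_give_zero_counts(self, ideal_helix):
        topo = ideal_helix.topology
        d = ideal_helix.distances()
        protons = topo.proton_indices()[:40]
        rows = [RestraintRow(topo.atoms[i], topo.atoms[j],
                             max(0.5, d[i, j] - 0.5), d[i, j] + 0.5)
                for i in protons[:20] for j in protons[20:40]]
        rep = violation_report(ensemble_of([ideal_helix] * 3),
                               RestraintTable(rows=rows))
        assert rep.count_over_01 == 0
        assert rep.count_over_05 == 0
        assert rep.largest == 0.0

    def test_pseudoatom_evaluated_at_group_mean(self, ideal_helix):
        topo = ideal_helix.topology
        group = topo.resolve(AtomRef(71, "QD1"))
        centre = ideal_helix.coords[group].mean(axis=0)
        ref = ideal_helix.coords[topo.index_of(AtomRef(65, "H"))]
        true_d = np.linalg.norm(centre - ref)
        table = RestraintTable(rows=[RestraintRow(
            AtomRef(71, "QD1"), AtomRef(65, "H"), 1.8, true_d - 0.25)])
        rep = violation_report(ensemble_of([ideal_helix]), table)
        assert rep.largest == pytest.approx(0.25, abs=1e-9)

    def test_missing_atom_names_restraint(self, ideal_helix):
        table = RestraintTable(rows=[RestraintRow(
            AtomRef(99, "HZ"), AtomRef(65, "H"), 1.8, 5.0)])
        with pytest.raises(KeyError, match="99.HZ"):
            violation_report(ensemble_of([ideal_helix]), table)


class TestEnsembleRMSD:
    def test_duplicated_conformer_gives_zero(self, ideal_helix):
        mean, to_medoid = ensemble_rmsd(ensemble_of([ideal_helix,
                                                     ideal_helix]))
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(to_medoid, 0.0)

    def test_rigid_translation_is_invisible(self, ideal_helix):
        moved = Conformer(ideal_helix.topology, ideal_helix.coords + 25.0)
        mean, _ = ensemble_rmsd(ensemble_of([ideal_helix, moved]))
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_ordered_region_tighter_than_disordered(self, ideal_helix, rng):
        # emulate an ensemble ordered over 65-72 but frayed over 62-64
        topo = ideal_helix.topology
        nterm = [i for i, a in enumerate(topo.atoms)
                 if a.residue_index <= 64]
        confs = []
        for _ in range(6):
            xyz = ideal_helix.coords.copy()
            xyz[nterm] += rng.normal(0, 1.2, (len(nterm), 3))
            confs.append(Conformer(topo, xyz))
        ens = ensemble_of(confs)
        rmsd_core, _ = ensemble_rmsd(ens, region=(65, 72))
        rmsd_nterm, _ = ensemble_rmsd(ens, region=(62, 64))
        assert rmsd_core < rmsd_nterm

    def test_single_conformer_rejected(self, ideal_helix):
        with pytest.raises(ValueError):
            ensemble_rmsd(ensemble_of([ideal_helix]))

    def test_empty_selection_rejected(self, ideal_helix):
        with pytest.raises(ValueError, match="selection"):
            ensemble_rmsd(ensemble_of([ideal_helix, ideal_helix]),
                          region=(1, 2))


class TestPoseConsistency:
    def make_pose(self, n_partner=12, close=(), rng=None):
        """Partner residues on a 6 A grid; residues in `close` get an atom
        near the peptide, the rest sit far away."""
        peptide = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]])
        partner = {}
        for r in range(1, n_partner + 1):
            base = np.array([[40.0 + 6 * r, 5.0, 0.0]])
            if r in close:
                base = np.array([[0.0, 2.0 + 0.1 * r, 0.0]])
            partner[r] = base
        return partner, peptide

    def test_high_csp_close_contact_correlates(self):
        close = set(range(1, 9))
        partner, peptide = self.make_pose(close=close)
        # CSP ordering mirrors proximity ordering throughout
        vals = {r: ((0.5 + 0.01 * (9 - r)) if r in close
                    else 0.05 - 0.002 * r) for r in partner}
        profile = classify_epitope(vals)
        score = csp_contact_consistency(partner, peptide, profile)
        assert score.rank_correlation > 0.8

    def test_uniform_profile_is_degenerate(self):
        partner, peptide = self.make_pose()
        profile = classify_epitope({r: 0.05 for r in partner})
        with pytest.raises(ValueError, match="constant"):
            csp_contact_consistency(partner, peptide, profile)

    def test_far_away_pose_uncorrelated_with_random_profile(self, rng):
        partner, peptide = self.make_pose()
        peptide = peptide + 100.0
        vals = {r: float(rng.uniform(0.01, 0.2)) for r in partner}
        profile = classify_epitope(vals)
        score = csp_contact_consistency(partner, peptide, profile)
        # permutation baseline: distances carry no epitope signal
        null = []
        dists = [np.linalg.norm(partner[r][0] - peptide[0]) for r in partner]
        from scipy.stats import spearmanr
        for _ in range(200):
            perm = rng.permutation(list(vals.values()))
            null.append(abs(spearmanr(perm, [-d for d in dists]).statistic))
        assert abs(score.rank_correlation) <= np.quantile(null, 0.99) + 1e-9

    def test_rigid_motion_invariance(self):
        close = {1, 2, 3, 4}
        partner, peptide = self.make_pose(close=close)
        vals = {r: (0.5 if r in close else 0.01) + 0.001 * r for r in partner}
        profile = classify_epitope(vals)
        s1 = csp_contact_consistency(partner, peptide, profile)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([5.0, -3.0, 8.0])
        partner2 = {r: v @ rot.T + shift for r, v in partner.items()}
        s2 = csp_contact_consistency(partner2, peptide @ rot.T + shift,
                                     profile)
        assert s1.rank_correlation == pytest.approx(s2.rank_correlation,
                                                    abs=1e-9)

    def test_too_few_residues_rejected(self):
        partner, peptide = self.make_pose(n_partner=2)
        profile = classify_epitope({1: 0.1, 2: 0.5})
        with pytest.raises(ValueError, match=">= 3"):
            csp_contact_consistency(partner, peptide, profile)
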