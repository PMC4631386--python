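"""Ensemble validation: restraint-violation statistics, pairwise/medoid
RMSD, and CSP-contact consistency scoring of a docked peptide pose."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .csp import CSPProfile
from .distgeom import ConformerEnsemble
from .geom import rmsd as _rmsd
from .io import AtomRef, RestraintTable

#: AQUA-style reporting thresholds (Angstrom)
VIOLATION_THRESHOLDS = (0.1, 0.5)


@dataclass
class RestraintViolation:
    atom_i: AtomRef
    atom_j: AtomRef
    max_violation: float
    mean_violation: float
    n_violated_conformers: int


@dataclass
class ViolationReport:
    per_restraint: list[RestraintViolation]
    count_over_01: int
    count_over_05: int
    largest: float

    def summary(self) -> str:
        return (f"{len(self.per_restraint)} restraints: "
                f"{self.count_over_01} with violation > 0.1 A, "
                f"{self.count_over_05} > 0.5 A, "
                f"largest {self.largest:.3f} A")


def violation_report(ensemble: ConformerEnsemble,
                     restraints: RestraintTable) -> ViolationReport:
    """Per-restraint violation statistics over an ensemble.

    violation = max(0, d - upper) + max(0, lower - d) per conformer;
    pseudoatom references are evaluated at the mean position of their
    proton group. Raises KeyError naming the restraint if an atom is
    missing from the conformers.
    """
    if not ensemble.conformers:
        raise ValueError("empty ensemble")
    topo = ensemble.conformers[0].topology
    coords = np.stack([c.coords3d() for c in ensemble.conformers])
    per = []
    for row in restraints.rows:
        try:
            gi = topo.resolve(row.atom_i)
            gj = topo.resolve(row.atom_j)
        except KeyError:
            raise KeyError(f"restraint {row.atom_i}-{row.atom_j}: atom "
                           f"missing from ensemble") from None
        pi = coords[:, gi, :].mean(axis=1)
        pj = coords[:, gj, :].mean(axis=1)
        d = np.linalg.norm(pi - pj, axis=1)
        viol = np.maximum(0.0, d - row.upper) + np.maximum(0.0, row.lower - d)
        per.append(RestraintViolation(
            row.atom_i, row.atom_j, float(viol.max()), float(viol.mean()),
            int((viol > 0).sum())))
    maxima = np.array([v.max_violation for v in per]) if per else np.zeros(0)
    return ViolationReport(
        per_restraint=per,
        count_over_01=int((maxima > VIOLATION_THRESHOLDS[0]).sum()),
        count_over_05=int((maxima > VIOLATION_THRESHOLDS[1]).sum()),
        largest=float(maxima.max()) if len(maxima) else 0.0)


def _selection_indices(topology, atom_selection, region) -> list[int]:
    names = set(atom_selection) if atom_selection else None
    lo, hi = (region if region is not None
              else (min(topology.sequence.indices),
                    max(topology.sequence.indices)))
    idx = [i for i, a in enumerate(topology.atoms)
           if lo <= a.residue_index <= hi
           and (names is None or a.atom_name in names)]
    if not idx:
        raise ValueError("empty atom selection")
    return idx


def ensemble_rmsd(ensemble: ConformerEnsemble,
                  atom_selection=("N", "CA", "C"),
                  region: tuple[int, int] | None = None):
    """Ensemble precision over a selection.

    Returns (mean pairwise RMSD, per-conformer RMSD to the medoid); each
    pair is optimally superposed on the selection first. The medoid is the
    conformer with the smallest summed RMSD to the others.
    """
    if len(ensemble.conformers) < 2:
        raise ValueError("need >= 2 conformers")
    topo = ensemble.conformers[0].topology
    idx = _selection_indices(topo, atom_selection, region)
    xs = [c.coords3d()[idx] for c in ensemble.conformers]
    m = len(xs)
    mat = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            mat[a, b] = mat[b, a] = _rmsd(xs[a], xs[b])
    mean_pairwise = float(mat[np.triu_indices(m, k=1)].mean())
    medoid = int(np.argmin(mat.sum(axis=1)))
    return mean_pairwise, mat[medoid]


@dataclass
class PoseConsistencyScore:
    """Agreement between a docked pose and the CSP epitope: Spearman rank
    correlation between per-residue CSP and proximity to the peptide."""

    rank_correlation: float
    per_residue: dict[int, tuple[float, float]]  # residue -> (csp d, min dist)

    def summary(self) -> str:
        return (f"CSP-contact rank correlation {self.rank_correlation:+.3f} "
                f"over {len(self.per_residue)} residues")


def csp_contact_consistency(partner_coords: dict[int, np.ndarray],
                            peptide_coords: np.ndarray,
                            profile: CSPProfile) -> PoseConsistencyScore:
    """Score a two-chain pose against a CSP profile.

    `partner_coords` maps each partner residue index to its heavy-atom
    coordinates (k, 3); `peptide_coords` holds all peptide atoms (m, 3).
    For every profiled residue present in the pose the minimal heavy-atom
    distance to the peptide is computed, and the score is the rank
    correlation between the CSP and the negated distance (higher CSP <->
    closer contact). Invariant under rigid motion of the whole pose.
    """
    peptide_coords = np.asarray(peptide_coords, dtype=float)
    csps, dists, per = [], [], {}
    for res, d in profile.assigned.items():
        if res not in partner_coords:
            continue
        xyz = np.asarray(partner_coords[res], dtype=float)
        mind = float(np.sqrt(
            ((xyz[:, None, :] - peptide_coords[None, :, :]) ** 2)
            .sum(-1)).min())
        csps.append(d)
        dists.append(mind)
        per[res] = (d, mind)
    if len(csps) < 3:
        raise ValueError("need >= 3 residues with both CSP and coordinates")
    if np.ptp(csps) == 0 or np.ptp(dists) == 0:
        raise ValueError("rank correlation undefined: constant input")
    rho = spearmanr(csps, [-x for x in dists]).statistic
    return PoseConsistencyScore(rank_correlation=float(rho), per_residue=per)


def score_pose_pdb(path, profile: CSPProfile,
                   peptide_chain: str) -> PoseConsistencyScore:
    """CSP-contact consistency for a two-chain pose in a PDB file; the
    chain named `peptide_chain` is the peptide, everything else the
    CSP-mapped partner."""
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    heavy = arr[arr.element != "H"]
    pep = heavy[heavy.chain_id == peptide_chain]
    part = heavy[heavy.chain_id != peptide_chain]
    if pep.array_length() == 0:
        raise ValueError(f"no atoms in peptide chain {peptide_chain!r}")
    partner: dict[int, np.ndarray] = {}
    for res in np.unique(part.res_id):
        partner[int(res)] = part.coord[part.res_id == res]
    return csp_contact_consistency(partner, pep.coord, profile)


def pose_from_structure(atoms, kinds, coords, peptide_chain_residues):
    """Split a structure into (partner residue -> heavy atoms, peptide
    heavy atoms) given the set of peptide residue indices. Helper for
    scoring poses read from multi-chain PDB files."""
    partner: dict[int, list] = {}
    peptide = []
    for (res, name), k, xyz in zip(
            [(a.residue_index, a.atom_name) for a in atoms], kinds, coords):
        if name.startswith(("H", "1H", "2H", "3H")):
            continue
        if res in peptide_chain_residues:
            peptide.append(xyz)
        else:
            partner.setdefault(res, []).append(xyz)
    return ({r: np.array(v) for r, v in partner.items()},
            np.array(peptide))
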