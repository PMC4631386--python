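"""All-atom peptide topology and ideal-geometry construction.

The topology (atom roster, covalent bonds, rigid planar groups, van der
Waals radii, pseudoatom resolution) is derived from the Chemical Component
Dictionary residue templates shipped with biotite; backbone atoms are
placed by internal-coordinate chain extension at user-chosen (phi, psi),
and side chains are grafted from the templates in their default rotamer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import networkx as nx
import biotite.structure.info as struc_info

from .geom import place_atom, kabsch_rotation
from .io import AtomRef, PeptideSequence, ONE_TO_THREE

# backbone internal coordinates (Angstrom / degrees), standard values
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8
OMEGA = 180.0

# atoms of the template never transferred to the built peptide
_TEMPLATE_SKIP = {"OXT", "HXT", "H2", "H3"}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}
POLAR_H_RADIUS = 0.50  # H bonded to N/O: shrunk so H-bonded geometry is feasible

# planar side-chain groups fixed as rigid bodies (beyond rings, which are
# detected from the bond graph)
_PLANAR_SIDECHAIN = {
    "R": [["CD", "NE", "HE", "CZ", "NH1", "NH2", "HH11", "HH12", "HH21", "HH22"]],
    "N": [["CB", "CG", "OD1", "ND2", "HD21", "HD22"]],
    "Q": [["CG", "CD", "OE1", "NE2", "HE21", "HE22"]],
    "D": [["CB", "CG", "OD1", "OD2"]],
    "E": [["CG", "CD", "OE1", "OE2"]],
}


@dataclass
class PeptideTopology:
    """Atom roster + covalent structure of one peptide chain."""

    sequence: PeptideSequence
    atoms: list[AtomRef]
    elements: list[str]
    bonds: list[tuple[int, int]]
    rigid_groups: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.atoms)}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residue_kinds(self) -> list[str]:
        """One-letter residue code per atom."""
        return [self.sequence.kind(a.residue_index) for a in self.atoms]

    def index_of(self, ref: AtomRef) -> int:
        name = ref.atom_name.upper()
        if name == "HN":
            name = "H"  # alternative amide-proton naming
        try:
            return self._index[AtomRef(ref.residue_index, name)]
        except KeyError:
            raise KeyError(f"atom {ref} not in topology") from None

    def resolve(self, ref: AtomRef) -> list[int]:
        """Resolve an atom reference to atom indices.

        Pseudoatom names (``QB``, ``QD1`` ...) expand to their proton
        group (``HB2``/``HB3``, ``HD11``/``HD12``/``HD13`` ...).
        """
        name = ref.atom_name.upper()
        if name.startswith("Q"):
            suffix = name[1:]
            hits = [
                i for i, a in enumerate(self.atoms)
                if a.residue_index == ref.residue_index
                and a.atom_name.startswith("H" + suffix)
                and a.atom_name[1 + len(suffix):].isdigit()
            ]
            if not hits:
                raise KeyError(f"pseudoatom {ref} matches no protons")
            return hits
        return [self.index_of(ref)]

    def vdw_radii(self) -> np.ndarray:
        """Per-atom van der Waals radii; polar hydrogens (bonded to N/O)
        get a reduced radius."""
        adj = self.adjacency()
        radii = np.array([VDW_RADII[e] for e in self.elements])
        for i, e in enumerate(self.elements):
            if e == "H" and any(self.elements[j] in ("N", "O") for j in adj[i]):
                radii[i] = POLAR_H_RADIUS
        return radii

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from(self.bonds)
        return g

    def methyl_groups(self) -> list[tuple[int, list[int]]]:
        """(carbon index, [three H indices]) for every methyl group."""
        adj = self.adjacency()
        out = []
        for i, e in enumerate(self.elements):
            if e != "C":
                continue
            hs = [j for j in adj[i] if self.elements[j] == "H"]
            if len(hs) == 3:
                out.append((i, hs))
        return out

    def proton_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.elements) if e == "H"]


@dataclass
class Conformer:
    """One coordinate set over a peptide topology.

    Coordinates are (n, 3) in Angstrom, or (n, 4) transiently during
    four-dimensional refinement. `energy` is the restraint-penalty score
    in squared-Angstrom units.
    """

    topology: PeptideTopology
    coords: np.ndarray
    energy: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.energy < 0:
            raise ValueError("energy must be >= 0")

    @property
    def atoms(self) -> list[AtomRef]:
        return self.topology.atoms

    @property
    def residue_kinds(self) -> list[str]:
        return self.topology.residue_kinds

    def coords3d(self) -> np.ndarray:
        return self.coords[:, :3]

    def distances(self) -> np.ndarray:
        x = self.coords3d()
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))


def _template(kind: str):
    return struc_info.residue(ONE_TO_THREE[kind])


@lru_cache(maxsize=None)
def _template_atoms(kind: str):
    """Names, elements, coords and bonds of the template atoms we keep."""
    res = _template(kind)
    names = list(res.atom_name)
    elements = list(res.element)
    bonds = [(names[i], names[j]) for i, j, _ in res.bonds.as_array()]
    neighbours: dict[str, list[str]] = {n: [] for n in names}
    for a, b in bonds:
        neighbours[a].append(b)
        neighbours[b].append(a)
    keep = []
    for n, e in zip(names, elements):
        if n in _TEMPLATE_SKIP:
            continue
        if e == "H" and any(
            elements[names.index(nb)] in ("O", "S") for nb in neighbours[n]
        ):
            continue  # hydroxyl/thiol protons: not observed, not built
        keep.append(n)
    coords = {n: res.coord[names.index(n)] for n in keep}
    el = {n: elements[names.index(n)] for n in keep}
    kept_bonds = [(a, b) for a, b in bonds if a in coords and b in coords]
    return keep, el, coords, kept_bonds


def helix_backbone(n_res: int, phi: float = -57.0, psi: float = -47.0) -> np.ndarray:
    """(n_res, 3, 3) array of N/CA/C positions for a regular (phi, psi)
    conformation with trans peptide bonds."""
    bb = np.zeros((n_res, 3, 3))
    bb[0, 0] = [0.0, 0.0, 0.0]
    bb[0, 1] = [BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(ANG_N_CA_C)
    bb[0, 2] = bb[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        if i > 0:
            bb[i, 1] = place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0],
                                  BOND_N_CA, ANG_C_N_CA, OMEGA)
            bb[i, 2] = place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1],
                                  BOND_CA_C, ANG_N_CA_C, phi)
        if i < n_res - 1:
            bb[i + 1, 0] = place_atom(bb[i, 0], bb[i, 1], bb[i, 2],
                                      BOND_C_N, ANG_CA_C_N, psi)
    return bb


def build_peptide(sequence: PeptideSequence, phi: float = -57.0,
                  psi: float = -47.0) -> Conformer:
    """Build an all-atom conformer (heavy atoms + amide/aliphatic H) of
    `sequence` with every residue at (`phi`, `psi`) and trans peptide
    bonds; side-chain rotamers are chosen deterministically among the
    canonical staggered values to avoid steric clashes.

    The defaults give an ideal alpha-helix.
    """
    conf = assemble_on_backbone(sequence, helix_backbone(len(sequence), phi, psi))
    conf.metadata.update({"builder": "ideal", "phi": phi, "psi": psi})
    return conf


def assemble_on_backbone(sequence: PeptideSequence, bb: np.ndarray,
                         psi_last: float = -47.0) -> Conformer:
    """Assemble a full peptide (carbonyl O, amide H, side chains in
    clash-minimizing staggered rotamers) onto given backbone N/CA/C
    coordinates of shape (n_res, 3, 3). Deterministic."""
    n_res = len(sequence)

    atoms: list[AtomRef] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    index: dict[AtomRef, int] = {}

    def add(res_idx: int, name: str, element: str, xyz: np.ndarray) -> int:
        ref = AtomRef(res_idx, name)
        index[ref] = len(atoms)
        atoms.append(ref)
        elements.append(element)
        coords.append(np.asarray(xyz, dtype=float))
        return index[ref]

    for i, (kind, res_idx) in enumerate(zip(sequence.residues, sequence.indices)):
        n_xyz, ca_xyz, c_xyz = bb[i]
        add(res_idx, "N", "N", n_xyz)
        add(res_idx, "CA", "C", ca_xyz)
        add(res_idx, "C", "C", c_xyz)
        # carbonyl O: in the sp2 plane, opposite the bisector of CA->C and N'->C
        if i < n_res - 1:
            u1 = (ca_xyz - c_xyz) / np.linalg.norm(ca_xyz - c_xyz)
            nn = bb[i + 1, 0]
            u2 = (nn - c_xyz) / np.linalg.norm(nn - c_xyz)
            o_dir = -(u1 + u2)
            o_xyz = c_xyz + BOND_C_O * o_dir / np.linalg.norm(o_dir)
        else:
            o_xyz = place_atom(n_xyz, ca_xyz, c_xyz, BOND_C_O, ANG_CA_C_O,
                               psi_last + 180.0)
        add(res_idx, "O", "O", o_xyz)
        # amide H: trans to the carbonyl O across the peptide bond
        if kind != "P":
            if i > 0:
                cp = bb[i - 1, 2]
                u1 = (cp - n_xyz) / np.linalg.norm(cp - n_xyz)
                u2 = (ca_xyz - n_xyz) / np.linalg.norm(ca_xyz - n_xyz)
                h_dir = -(u1 + u2)
                h_xyz = n_xyz + BOND_N_H * h_dir / np.linalg.norm(h_dir)
            else:
                h_xyz = place_atom(c_xyz, ca_xyz, n_xyz, BOND_N_H, 109.5, 180.0)
            add(res_idx, "H", "H", h_xyz)
        # graft the template side chain (+ HA) onto the built backbone
        keep, el, t_coords, t_bonds = _template_atoms(kind)
        t_frame = np.stack([t_coords["N"], t_coords["CA"], t_coords["C"]])
        b_frame = np.stack([n_xyz, ca_xyz, c_xyz])
        tc = t_frame.mean(axis=0)
        bc = b_frame.mean(axis=0)
        rot = kabsch_rotation(t_frame - tc, b_frame - bc)
        for name in keep:
            if name in ("N", "CA", "C", "O", "H"):
                continue
            xyz = (t_coords[name] - tc) @ rot + bc
            add(res_idx, name, el[name], xyz)
        for a, b in t_bonds:
            ra, rb = AtomRef(res_idx, a), AtomRef(res_idx, b)
            if ra in index and rb in index:
                bonds.append((index[ra], index[rb]))
        if i > 0:
            bonds.append((index[AtomRef(sequence.indices[i - 1], "C")],
                          index[AtomRef(res_idx, "N")]))

    topo = PeptideTopology(sequence=sequence, atoms=atoms, elements=elements,
                           bonds=sorted(set(tuple(sorted(b)) for b in bonds)))
    topo.rigid_groups = _find_rigid_groups(topo)
    xyz = np.array(coords)
    _select_rotamers(topo, xyz)
    return Conformer(topology=topo, coords=xyz, metadata={"builder": "assembled"})


_CHI_CHOICES = (-60.0, 180.0, 60.0)  # canonical staggered rotamers, by frequency


def _rotate_about_axis(points, origin, axis, angle_deg):
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    p = points - origin
    return (p * np.cos(a)
            + np.cross(axis, p) * np.sin(a)
            + axis * np.outer(p @ axis, 1.0) * (1 - np.cos(a))) + origin


def _select_rotamers(topo: PeptideTopology, xyz: np.ndarray, sweeps: int = 2) -> None:
    """Deterministically set side-chain chi1 (and chi2) to the canonical
    staggered value that maximises the worst steric contact with the rest
    of the chain. The template default rotamer can clash badly in a helix;
    this keeps the built conformer sterically plausible."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    from .geom import dihedral_angle

    adj = topo.adjacency()
    seq = topo.sequence
    n = len(topo)
    adj_mat = csr_matrix(
        (np.ones(len(topo.bonds)), tuple(np.array(topo.bonds).T)), shape=(n, n))
    gdist = shortest_path(adj_mat, directed=False, unweighted=True)
    radii = np.array([VDW_RADII[e] for e in topo.elements])
    vdw_sum = radii[:, None] + radii[None, :]
    for _ in range(sweeps):
        for kind, res in zip(seq.residues, seq.indices):
            if kind in ("G", "A", "P"):
                continue
            for chi_atoms in (("N", "CA", "CB"), ("CA", "CB", "CG")):
                try:
                    a, b, c = (topo.index_of(AtomRef(res, nm)) for nm in chi_atoms)
                except KeyError:
                    continue
                heavy_next = [j for j in adj[c]
                              if j != b and topo.elements[j] != "H"]
                if not heavy_next:
                    continue
                d = min(heavy_next)  # deterministic reference atom
                moving = _atoms_beyond(topo, b, c)
                if not moving:
                    continue
                rest = np.array([i for i in range(n) if i not in set(moving)])
                # only pairs separated by >= 4 bonds count as steric contacts
                contact = gdist[np.ix_(moving, rest)] >= 4
                if not contact.any():
                    continue
                cur = dihedral_angle(xyz[a], xyz[b], xyz[c], xyz[d])
                best = None
                for target in _CHI_CHOICES:
                    trial = xyz.copy()
                    trial[moving] = _rotate_about_axis(
                        xyz[moving], xyz[c], xyz[c] - xyz[b], target - cur)
                    dist = np.linalg.norm(
                        trial[moving][:, None, :] - trial[rest][None, :, :],
                        axis=-1)
                    ratio = dist / vdw_sum[np.ix_(moving, rest)]
                    score = ratio[contact].min()
                    if best is None or score > best[0] + 1e-12:
                        best = (score, trial)
                xyz[:] = best[1]


def _atoms_beyond(topo: PeptideTopology, frm: int, pivot: int) -> list[int]:
    """Atoms on the far side of the bond frm->pivot (excluding both)."""
    adj = topo.adjacency()
    seen = {frm, pivot}
    stack = [j for j in adj[pivot] if j != frm]
    out = []
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        out.append(i)
        stack.extend(adj[i])
    return out


def _find_rigid_groups(topo: PeptideTopology) -> list[list[int]]:
    """Rigid planar groups: peptide planes, rings (+ their substituents)
    and planar side-chain termini. Distances within a group are fixed."""
    groups: list[list[int]] = []
    seq = topo.sequence
    # peptide planes
    for prev, nxt in zip(seq.indices[:-1], seq.indices[1:]):
        grp = []
        for ref in (AtomRef(prev, "CA"), AtomRef(prev, "C"), AtomRef(prev, "O"),
                    AtomRef(nxt, "N"), AtomRef(nxt, "H"), AtomRef(nxt, "CA")):
            try:
                grp.append(topo.index_of(ref))
            except KeyError:
                pass
        groups.append(grp)
    # rings + substituents
    g = topo.graph()
    adj = topo.adjacency()
    for cycle in nx.cycle_basis(g):
        grp = set(cycle)
        for i in cycle:
            grp.update(adj[i])
        groups.append(sorted(grp))
    # planar side-chain groups
    for kind, res_idx in zip(seq.residues, seq.indices):
        for names in _PLANAR_SIDECHAIN.get(kind, []):
            grp = []
            for nm in names:
                try:
                    grp.append(topo.index_of(AtomRef(res_idx, nm)))
                except KeyError:
                    pass
            if len(grp) >= 3:
                groups.append(grp)
    return groups
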