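"""Transferred-NOE distance calibration and restraint construction.

Cross-peak intensities are converted to distances through the isolated
spin-pair approximation I ~ r^-6, calibrated against a geminal CH2
proton pair of known separation (1.78 A for idealized sp3 geometry).
Calibrated distances are binned into standard restraint classes
(strong/medium/weak upper bounds of 2.7/3.5/5.0 A over a universal 1.8 A
lower bound), with pseudoatom corrections for unresolvable proton groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AtomRef, PeptideSequence, RestraintRow, RestraintTable

#: (upper bin edge of calibrated distance, upper bound assigned)
DISTANCE_CLASSES = ((2.7, 2.7), (3.5, 3.5), (np.inf, 5.0))
LOWER_BOUND = 1.8              # Angstrom, universal NOE lower bound
METHYL_CORRECTION = 1.0        # Angstrom added to upper for methyl pseudoatoms
PAIR_CORRECTION = 0.7          # Angstrom for unresolved CH2/aromatic pairs


def geminal_reference_distance(ch_bond: float = 1.09,
                               hch_angle: float = 109.47) -> float:
    """H-H separation of an idealized sp3 methylene: 2 b sin(theta/2).

    With the standard C-H bond (1.09 A) and tetrahedral angle this gives
    the 1.78 A internal calibration reference.
    """
    if ch_bond <= 0:
        raise ValueError("bond length must be > 0")
    if not 0 < hch_angle < 180:
        raise ValueError("H-C-H angle must be in (0, 180) degrees")
    return 2.0 * ch_bond * np.sin(np.deg2rad(hch_angle) / 2.0)


@dataclass
class CalibrationConstant:
    """Reference pair: known separation `r_ref` and its intensity `i_ref`."""

    r_ref: float  # Angstrom
    i_ref: float  # intensity units

    def __post_init__(self):
        if self.r_ref <= 0 or self.i_ref <= 0:
            raise ValueError("r_ref and i_ref must be > 0")


def calibrate(peaks) -> CalibrationConstant:
    """Calibration from the flagged reference row of a NOE peak table,
    using the idealized geminal separation."""
    return CalibrationConstant(r_ref=geminal_reference_distance(),
                               i_ref=peaks.reference.intensity)


def intensity_to_distance(intensity: float, cal: CalibrationConstant) -> float:
    """Isolated-spin-pair distance: r = r_ref (i_ref / I)^(1/6)."""
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    return float(cal.r_ref * (cal.i_ref / intensity) ** (1.0 / 6.0))


def upper_bound_for(distance: float) -> float:
    """Class upper bound for a calibrated distance."""
    for edge, upper in DISTANCE_CLASSES:
        if distance <= edge:
            return upper
    raise AssertionError("unreachable")


def _is_methyl(topology, ref: AtomRef) -> bool:
    methyl_h = {h for _, hs in topology.methyl_groups() for h in hs}
    try:
        return all(i in methyl_h for i in topology.resolve(ref))
    except KeyError:
        return False


def build_restraints(peaks, cal: CalibrationConstant,
                     sequence: PeptideSequence,
                     collapse_pseudoatoms: bool = False) -> RestraintTable:
    """Restraint table from calibrated NOE intensities.

    Each cross peak gets lower = 1.8 A and the class upper bound of its
    calibrated distance; pseudoatom corrections (+1.0 A methyl, +0.7 A
    unresolved methylene/aromatic pair) are added to the upper bound when
    `collapse_pseudoatoms` replaces proton groups by their Q pseudoatom.
    Duplicate atom pairs are merged keeping the tighter upper bound.
    Raises KeyError naming the row on an unresolvable atom.
    """
    from .peptide import build_peptide

    topo = build_peptide(sequence).topology
    merged: dict[tuple[AtomRef, AtomRef], float] = {}
    for row in peaks.rows:
        for ref in (row.atom_i, row.atom_j):
            try:
                topo.resolve(ref)
            except KeyError:
                raise KeyError(
                    f"restraint row {row.atom_i}-{row.atom_j}: atom {ref} "
                    f"not resolvable in sequence") from None
        r = intensity_to_distance(row.intensity, cal)
        upper = upper_bound_for(r)
        ai, aj = row.atom_i, row.atom_j
        if collapse_pseudoatoms:
            ai, _ = _pseudo(topo, ai)
            aj, _ = _pseudo(topo, aj)
        upper += _pseudo_correction(topo, ai) + _pseudo_correction(topo, aj)
        if ai == aj:
            continue  # protons collapsed onto the same pseudoatom
        key = tuple(sorted((ai, aj)))
        if key not in merged or upper < merged[key]:
            merged[key] = upper
    rows = [RestraintRow(a, b, LOWER_BOUND, u)
            for (a, b), u in sorted(merged.items())]
    return RestraintTable(rows=rows)


def _pseudo_correction(topology, ref: AtomRef) -> float:
    """Upper-bound correction for a pseudoatom reference: +1.0 A for a
    methyl group (three protons), +0.7 A for an unresolved pair."""
    if not ref.atom_name.startswith("Q"):
        return 0.0
    group = topology.resolve(ref)
    return METHYL_CORRECTION if len(group) >= 3 else PAIR_CORRECTION


def _pseudo(topology, ref: AtomRef) -> tuple[AtomRef, float]:
    """Replace a proton of an unresolvable group by its Q pseudoatom and
    return the upper-bound correction."""
    name = ref.atom_name
    if not name.startswith("H"):
        return ref, 0.0
    if _is_methyl(topology, ref):
        # HD11 -> QD1 etc.: strip the trailing proton counter
        return AtomRef(ref.residue_index, "Q" + name[1:-1]), METHYL_CORRECTION
    if name[-1] in "23" and len(name) > 2:
        qname = "Q" + name[1:-1]
        try:
            if len(topology.resolve(AtomRef(ref.residue_index, qname))) == 2:
                return AtomRef(ref.residue_index, qname), PAIR_CORRECTION
        except KeyError:
            pass
    return ref, 0.0
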