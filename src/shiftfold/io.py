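"""Readers and writers for the pipeline's external formats.

Formats handled here:

* assigned 2D peak tables (TSV; one file per titration point, the
  ligand:protein molar ratio in a ``# ratio=`` header directive),
* distance-restraint tables in an X-PLOR-style ``assign`` dialect,
* plate-reader dose-response tables (TSV),
* single-record FASTA peptide sequences with an optional ``start=N``
  numbering token,
* multi-MODEL PDB ensembles (via biotite).

All parse errors carry file and line context; no reader silently drops
data rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class ParseError(ValueError):
    """Raised on malformed input; message carries file and line number."""


class PeakEntry(NamedTuple):
    residue_index: int
    residue_kind: str  # one-letter code
    h_shift: float     # ppm
    n_shift: float     # ppm


@dataclass
class PeakTable:
    """Assigned amide peak positions at one titration point.

    Parameters
    ----------
    entries : list of PeakEntry
        One entry per assigned residue (residue indices unique).
    ratio_label : float
        Ligand:protein molar ratio of this titration point.
    """

    entries: list[PeakEntry]
    ratio_label: float

    def __post_init__(self):
        idx = [e.residue_index for e in self.entries]
        if len(set(idx)) != len(idx):
            dup = sorted({i for i in idx if idx.count(i) > 1})
            raise ValueError(f"duplicate residue indices in peak table: {dup}")
        if self.ratio_label < 0:
            raise ValueError("ratio_label must be >= 0")
        for e in self.entries:
            if not (np.isfinite(e.h_shift) and np.isfinite(e.n_shift)):
                raise ValueError(f"non-finite shift for residue {e.residue_index}")

    def by_residue(self) -> dict[int, PeakEntry]:
        return {e.residue_index: e for e in self.entries}


class AtomRef(NamedTuple):
    """An atom addressed by residue index + PDB v3.3 atom name."""

    residue_index: int
    atom_name: str

    def __str__(self) -> str:  # e.g. "65.HB2"
        return f"{self.residue_index}.{self.atom_name}"


class RestraintRow(NamedTuple):
    atom_i: AtomRef
    atom_j: AtomRef
    lower: float  # Angstrom
    upper: float  # Angstrom


@dataclass
class RestraintTable:
    """A set of interproton distance restraints with lower/upper bounds."""

    rows: list[RestraintRow] = field(default_factory=list)

    def __post_init__(self):
        for r in self.rows:
            if not 0 < r.lower <= r.upper:
                raise ValueError(
                    f"restraint {r.atom_i}-{r.atom_j}: need 0 < lower <= upper, "
                    f"got ({r.lower}, {r.upper})"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, RestraintTable) and self.rows == other.rows


class PlateRow(NamedTuple):
    concentration: float  # molar
    signal: float         # arbitrary fluorescence units
    replicate: int


@dataclass
class PlateTable:
    """Plate-reader dose-response observations."""

    rows: list[PlateRow]

    def __post_init__(self):
        if any(r.concentration < 0 for r in self.rows):
            raise ValueError("concentrations must be >= 0")
        if len({r.concentration for r in self.rows}) < 2:
            raise ValueError("need >= 2 distinct concentrations")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([r.concentration for r in self.rows])

    @property
    def signals(self) -> np.ndarray:
        return np.array([r.signal for r in self.rows])


@dataclass
class PeptideSequence:
    """A peptide as one-letter codes with an explicit numbering offset.

    Residue numbering is preserved from the input (e.g. cFLIP numbering
    62-73 for the R4 peptide) and never renumbered internally.
    """

    residues: list[str]
    first_index: int = 1

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        bad = [r for r in self.residues if r not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"non-canonical residue codes: {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> list[int]:
        return list(range(self.first_index, self.first_index + len(self.residues)))

    def kind(self, residue_index: int) -> str:
        i = residue_index - self.first_index
        if not 0 <= i < len(self.residues):
            raise KeyError(f"residue {residue_index} outside sequence "
                           f"{self.first_index}-{self.first_index + len(self.residues) - 1}")
        return self.residues[i]

    def __str__(self) -> str:
        return "".join(self.residues)


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

def read_peak_table(path, ratio: float | None = None) -> PeakTable:
    """Read a TSV peak table (columns: residue, kind, 1H ppm, 15N ppm).

    ``#`` lines are comments; a ``# ratio=X`` directive sets the titration
    ratio unless `ratio` is given explicitly.
    """
    path = Path(path)
    entries: list[PeakEntry] = []
    header_ratio = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"ratio\s*=\s*([0-9.eE+-]+)", line)
                if m:
                    header_ratio = float(m.group(1))
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 columns "
                                 f"(residue kind H N), got {len(parts)}")
            try:
                idx = int(parts[0])
                kind = parts[1].upper()
                h, n = float(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
            if kind not in AMINO_ACIDS:
                raise ParseError(f"{path}:{ln}: unknown residue kind {kind!r}")
            if any(e.residue_index == idx for e in entries):
                raise ParseError(f"{path}:{ln}: duplicate residue {idx}")
            entries.append(PeakEntry(idx, kind, h, n))
    if not entries:
        raise ParseError(f"{path}: no peaks")
    if ratio is None:
        ratio = header_ratio
    if ratio is None:
        raise ParseError(f"{path}: no '# ratio=' directive and no ratio given")
    return PeakTable(entries=entries, ratio_label=float(ratio))


def write_peak_table(table: PeakTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ratio={float(table.ratio_label)!r}\n")
        fh.write("# residue kind H N\n")
        for e in table.entries:
            # repr gives the shortest exactly round-tripping decimal form
            fh.write(f"{e.residue_index}\t{e.residue_kind}\t"
                     f"{float(e.h_shift)!r}\t{float(e.n_shift)!r}\n")


# ---------------------------------------------------------------------------
# restraint tables (X-PLOR-style "assign" dialect)
# ---------------------------------------------------------------------------

_ASSIGN_RE = re.compile(
    r"assign\s*"
    r"\(\s*resid\s+(\d+)\s+and\s+name\s+(\S+?)\s*\)\s*"
    r"\(\s*resid\s+(\d+)\s+and\s+name\s+(\S+?)\s*\)\s*"
    r"([0-9.eE+-]+)\s+([0-9.eE+-]+)(?:\s+([0-9.eE+-]+))?\s*$",
    re.IGNORECASE,
)


def read_restraint_table(path) -> RestraintTable:
    """Read restraints in the ``assign`` dialect.

    Two trailing numbers are read as explicit (lower, upper) in Angstrom.
    Three trailing numbers are read X-PLOR-style as (d, dminus, dplus),
    i.e. lower = d - dminus, upper = d + dplus -- the convention of
    deposited NMR restraint files, so this doubles as the importer for
    deposition-format tables.
    """
    path = Path(path)
    rows: list[RestraintRow] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "!")):
                continue
            m = _ASSIGN_RE.match(line)
            if m is None:
                raise ParseError(f"{path}:{ln}: unparseable assign line: {line!r}")
            ri, ni, rj, nj = int(m.group(1)), m.group(2).upper(), int(m.group(3)), m.group(4).upper()
            if m.group(7) is None:
                lower, upper = float(m.group(5)), float(m.group(6))
            else:
                d, dminus, dplus = (float(m.group(k)) for k in (5, 6, 7))
                lower, upper = d - dminus, d + dplus
            if lower > upper:
                raise ParseError(f"{path}:{ln}: lower {lower} > upper {upper}")
            rows.append(RestraintRow(AtomRef(ri, ni), AtomRef(rj, nj),
                                     lower, upper))
    return RestraintTable(rows=rows)


def write_restraint_table(table: RestraintTable, path) -> None:
    with open(path, "w") as fh:
        for r in table.rows:
            fh.write(
                f"assign (resid {r.atom_i.residue_index} and name "
                f"{r.atom_i.atom_name})(resid {r.atom_j.residue_index} and "
                f"name {r.atom_j.atom_name}) {float(r.lower)!r} "
                f"{float(r.upper)!r}\n"
            )


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------

def read_plate_table(path) -> PlateTable:
    """Read a TSV plate table (columns: concentration [M], signal, replicate)."""
    path = Path(path)
    rows: list[PlateRow] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{ln}: expected 2-3 columns, got {len(parts)}")
            try:
                conc, sig = float(parts[0]), float(parts[1])
                rep = int(parts[2]) if len(parts) == 3 else 1
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
            rows.append(PlateRow(conc, sig, rep))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return PlateTable(rows=rows)


def write_plate_table(table: PlateTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# concentration signal replicate\n")
        for r in table.rows:
            fh.write(f"{float(r.concentration)!r}\t{float(r.signal)!r}\t"
                     f"{r.replicate}\n")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_sequence(path) -> PeptideSequence:
    """Read a single-record FASTA; an optional header token ``start=N``
    sets the numbering offset (default 1)."""
    path = Path(path)
    header = None
    seq_chunks: list[str] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    raise ParseError(f"{path}:{ln}: multi-record FASTA not supported")
                header = line[1:]
            else:
                if header is None:
                    raise ParseError(f"{path}:{ln}: sequence before FASTA header")
                seq_chunks.append(line)
    if header is None or not seq_chunks:
        raise ParseError(f"{path}: no FASTA record")
    seq = "".join(seq_chunks).upper()
    bad = sorted({c for c in seq if c not in AMINO_ACIDS})
    if bad:
        raise ParseError(f"{path}: illegal residue codes {bad}")
    m = re.search(r"start\s*=\s*(-?\d+)", header)
    first = int(m.group(1)) if m else 1
    return PeptideSequence(residues=list(seq), first_index=first)


def write_sequence(seq: PeptideSequence, path, name: str = "peptide") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} start={seq.first_index}\n{seq}\n")


# ---------------------------------------------------------------------------
# PDB ensembles
# ---------------------------------------------------------------------------

def _ensemble_to_stack(ensemble) -> struc.AtomArrayStack:
    from .distgeom import ConformerEnsemble  # local import: avoid cycle

    if isinstance(ensemble, ConformerEnsemble):
        conformers = ensemble.conformers
    else:
        conformers = list(ensemble)
    if not conformers:
        raise ValueError("empty ensemble")
    roster = conformers[0].atoms
    for c in conformers[1:]:
        if c.atoms != roster:
            raise ValueError("conformers have inconsistent atom rosters")
    n = len(roster)
    arr = struc.AtomArray(n)
    arr.atom_name = np.array([a.atom_name for a in roster])
    arr.res_id = np.array([a.residue_index for a in roster])
    arr.res_name = np.array([ONE_TO_THREE[k] for k in conformers[0].residue_kinds])
    arr.chain_id = np.array(["A"] * n)
    arr.element = np.array([_guess_element(a.atom_name) for a in roster])
    arr.hetero = np.zeros(n, dtype=bool)
    coords = np.stack([np.asarray(c.coords3d(), dtype=float) for c in conformers])
    stack = struc.stack([arr] * len(conformers))
    stack.coord = coords
    return stack


def _guess_element(atom_name: str) -> str:
    # PDB v3.3 peptide atom names start with the element letter,
    # except numeric-prefixed hydrogens like "1HB"
    stripped = atom_name.lstrip("0123456789")
    return stripped[0]


def write_ensemble(ensemble, path) -> None:
    """Write conformers as a multi-MODEL PDB file (coordinates in Angstrom,
    three decimals). All conformers must share one atom roster."""
    stack = _ensemble_to_stack(ensemble)
    f = _pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_ensemble_coords(path):
    """Read a multi-MODEL PDB back as (atom refs, residue kinds, coords).

    Returns
    -------
    atoms : list of AtomRef
    kinds : list of str (one-letter, per atom)
    coords : ndarray, shape (n_models, n_atoms, 3)
    """
    f = _pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    atoms = [AtomRef(int(r), str(a)) for r, a in zip(stack.res_id, stack.atom_name)]
    kinds = [THREE_TO_ONE[rn] for rn in stack.res_name]
    return atoms, kinds, np.asarray(stack.coord, dtype=float)
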