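"""Synthetic-data generators.

Every generator is a pure function of its inputs and a seed, and its
noiseless output matches the closed form of the corresponding physical
model: fast-exchange population-weighted chemical shifts under single-site
binding with ligand depletion, NOESY cross-peak intensities proportional
to r^-6 on a known conformer, and four-parameter-logistic plate signals
with additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .binding import fraction_bound, four_pl
from .io import (AMINO_ACIDS, AtomRef, PeakEntry, PeakTable, PeptideSequence,
                 PlateRow, PlateTable)
from .peptide import Conformer, build_peptide

#: H-H distance of the geminal methylene calibration reference (Angstrom)
R_REFERENCE = 1.78


class NOERow(NamedTuple):
    atom_i: AtomRef
    atom_j: AtomRef
    intensity: float
    is_reference: bool


@dataclass
class NOEPeakTable:
    """Cross-peak intensities of a (simulated or measured) NOESY."""

    rows: list[NOERow]

    def __post_init__(self):
        if any(r.intensity <= 0 for r in self.rows):
            raise ValueError("intensities must be > 0")
        if sum(r.is_reference for r in self.rows) != 1:
            raise ValueError("exactly one reference row required")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def reference(self) -> NOERow:
        return next(r for r in self.rows if r.is_reference)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults reproduce the NMR titration conditions of the study this
    package models: 55 uM protein, a six-point titration from 0:1 to 5:1
    ligand:protein, a true dissociation constant of 60 uM, and a 5 A NOE
    observability cutoff calibrated against a 1.78 A geminal reference.
    """

    true_kd: float = 60e-6          # molar
    protein_conc: float = 55e-6     # molar
    ratios: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 5.0)
    shift_noise: float = 0.002      # ppm std dev on each observed shift
    noe_cutoff: float = 5.0         # Angstrom
    noe_noise: float = 0.02         # relative std dev on intensities
    plate_params: tuple = (1000.0, 100.0, 2e-6, 1.5)      # (m1, m2, m3, m4)
    competition_params: tuple = (100.0, 1000.0, 63e-6, 1.5)
    plate_noise: float = 9.0        # additive signal std dev (~1% of range)
    seed: int = 0

    def __post_init__(self):
        if self.true_kd <= 0 or self.protein_conc <= 0:
            raise ValueError("true_kd and protein_conc must be > 0")
        r = list(self.ratios)
        if r != sorted(r) or r[0] != 0:
            raise ValueError("ratios must be sorted ascending starting at 0")
        if min(self.shift_noise, self.noe_noise) < 0 or self.plate_noise < 0:
            raise ValueError("noise levels must be >= 0")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed + 7919 * salt) % (2**31))


def make_ideal_helix(sequence: PeptideSequence, phi: float = -57.0,
                     psi: float = -47.0) -> Conformer:
    """All-atom ideal-geometry conformer at uniform (phi, psi); the default
    is the alpha-helical conformation the bound peptide adopts. Deterministic."""
    return build_peptide(sequence, phi=phi, psi=psi)


def _reference_pair(conformer: Conformer) -> tuple[int, int]:
    """The geminal CH2 proton pair used as intensity reference: the
    HB2/HB3 pair of the first Phe if present, else the first geminal
    methylene in the chain."""
    topo = conformer.topology
    for kind_wanted in ("F", None):
        for kind, res in zip(topo.sequence.residues, topo.sequence.indices):
            if kind_wanted is not None and kind != kind_wanted:
                continue
            try:
                return (topo.index_of(AtomRef(res, "HB2")),
                        topo.index_of(AtomRef(res, "HB3")))
            except KeyError:
                continue
    raise ValueError("conformer has no geminal CH2 pair to use as reference")


def simulate_noesy(conformer: Conformer, config: SimulationConfig) -> NOEPeakTable:
    """NOESY cross peaks for every proton pair closer than the cutoff.

    Intensity = (r_ref / r)^6 * (1 + eps), eps ~ Normal(0, noe_noise),
    with r_ref = 1.78 A; the geminal CH2 reference pair is flagged.
    """
    if config.noe_cutoff <= 0:
        raise ValueError("noe_cutoff must be > 0")
    topo = conformer.topology
    protons = topo.proton_indices()
    if not protons:
        raise ValueError("conformer has no protons")
    ref_pair = _reference_pair(conformer)
    d = conformer.distances()
    rng = config.rng(salt=1)
    rows: list[NOERow] = []
    for a in range(len(protons)):
        for b in range(a + 1, len(protons)):
            i, j = protons[a], protons[b]
            r = d[i, j]
            if r > config.noe_cutoff:
                continue
            noise = rng.normal(0.0, config.noe_noise) if config.noe_noise else 0.0
            rows.append(NOERow(
                topo.atoms[i], topo.atoms[j],
                (R_REFERENCE / r) ** 6 * (1.0 + noise),
                {i, j} == set(ref_pair)))
    return NOEPeakTable(rows=rows)


@dataclass
class EpitopeProfile:
    """Ground truth for a simulated titration: free-state peaks plus the
    per-residue fully-bound chemical-shift displacement."""

    free_table: PeakTable
    bound_shifts: dict[int, tuple[float, float]]  # residue -> (dH, dN) ppm
    epitope: frozenset[int] = field(default_factory=frozenset)


def make_epitope_profile(n_residues: int = 118, epitope_size: int = 8,
                         background_shift: float = 0.02,
                         epitope_factor: float = 10.0,
                         seed: int = 0) -> EpitopeProfile:
    """Random free-state amide peaks plus a planted binding epitope.

    Background residues get bound-state displacements of magnitude about
    `background_shift` ppm (in the combined 1H/15N metric); a random
    `epitope_size`-residue subset gets `epitope_factor` times that.
    """
    rng = np.random.default_rng(seed % (2**31))
    kinds = rng.choice(sorted(AMINO_ACIDS), size=n_residues)
    entries = [PeakEntry(i + 1, str(kinds[i]),
                         float(rng.normal(8.3, 0.45)),
                         float(rng.normal(119.0, 4.0)))
               for i in range(n_residues)]
    residues = [e.residue_index for e in entries]
    epitope = frozenset(rng.choice(residues, size=epitope_size, replace=False).tolist())
    bound: dict[int, tuple[float, float]] = {}
    for res in residues:
        scale = background_shift * rng.uniform(0.5, 1.5)
        if res in epitope:
            scale = background_shift * epitope_factor
        theta = rng.uniform(0.0, 2.0 * np.pi)
        # split the displacement between 1H and (alpha-scaled) 15N axes
        bound[res] = (scale * np.cos(theta), scale * np.sin(theta) / 0.14)
    return EpitopeProfile(free_table=PeakTable(entries=entries, ratio_label=0.0),
                          bound_shifts=bound, epitope=epitope)


def simulate_titration(config: SimulationConfig, profile: EpitopeProfile
                       ) -> list[PeakTable]:
    """Observed peak tables across the titration.

    At ligand:protein ratio rho the observed shift of each residue is
    free + f_bound(P, rho P, K_D) * bound_shift + Normal(0, shift_noise),
    with f_bound from the single-site ligand-depletion mass balance.
    """
    if 0.0 not in config.ratios:
        raise ValueError("titration must include the zero-ratio free state")
    rng = config.rng(salt=2)
    p = config.protein_conc
    out: list[PeakTable] = []
    for ratio in config.ratios:
        fb = fraction_bound(p, ratio * p, config.true_kd)
        entries = []
        for e in profile.free_table.entries:
            dh, dn = profile.bound_shifts[e.residue_index]
            h = e.h_shift + fb * dh
            n = e.n_shift + fb * dn
            if config.shift_noise:
                h += rng.normal(0.0, config.shift_noise)
                n += rng.normal(0.0, config.shift_noise)
            entries.append(PeakEntry(e.residue_index, e.residue_kind, h, n))
        out.append(PeakTable(entries=entries, ratio_label=ratio))
    return out


def default_plate_concentrations(m3: float, n: int = 12,
                                 replicates: int = 3) -> np.ndarray:
    """Two-fold serial dilution spanning ~5 doublings below to ~6 above
    the inflection concentration, the usual plate layout."""
    conc = m3 * 2.0 ** np.arange(-5, n - 5)
    return np.repeat(conc, replicates)


def simulate_plate(config: SimulationConfig, descending: bool = False,
                   concentrations: np.ndarray | None = None) -> PlateTable:
    """Plate-reader signals from the four-parameter logistic.

    `descending` emulates the competition format (signal falls as the
    competing peptide displaces the tracer); the default emulates direct
    binding. Replicates get independent additive Gaussian noise.
    """
    params = config.competition_params if descending else config.plate_params
    m1, m2, m3, m4 = params
    if concentrations is None:
        concentrations = default_plate_concentrations(m3)
    concentrations = np.asarray(concentrations, dtype=float)
    if np.all(concentrations == 0):
        raise ValueError("all-zero concentrations")
    if len(np.unique(concentrations)) < 5:
        raise ValueError("need >= 5 distinct concentrations")
    rng = config.rng(salt=3)
    rows = []
    rep_counter: dict[float, int] = {}
    for x in concentrations:
        y = four_pl(x, m1, m2, m3, m4)
        if config.plate_noise:
            y += rng.normal(0.0, config.plate_noise)
        rep = rep_counter.get(x, 0) + 1
        rep_counter[x] = rep
        rows.append(PlateRow(float(x), float(y), rep))
    return PlateTable(rows=rows)


def restraints_from_conformer(conformer: Conformer, config: SimulationConfig):
    """Ground-truth restraint table: all proton pairs within the NOE
    cutoff, with standard class bounds. Convenience wrapper used by the
    planted-helix recovery protocol (noise-free by construction)."""
    from .restraints import CalibrationConstant, build_restraints

    noiseless = SimulationConfig(
        true_kd=config.true_kd, protein_conc=config.protein_conc,
        ratios=config.ratios, shift_noise=0.0,
        noe_cutoff=config.noe_cutoff, noe_noise=0.0,
        plate_params=config.plate_params, seed=config.seed)
    peaks = simulate_noesy(conformer, noiseless)
    ref = peaks.reference
    cal = CalibrationConstant(r_ref=R_REFERENCE, i_ref=ref.intensity)
    return build_restraints(peaks, cal, conformer.topology.sequence)
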