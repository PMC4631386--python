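import numpy as np
import pytest
from hypothesis import settings

from shiftfold.io import PeptideSequence, RestraintRow, RestraintTable
from shiftfold.peptide import build_peptide

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

R4 = "VRRFDLLKRILK"  # cFLIP DED1 region 4, residues 62-73


@pytest.fixture(scope="session")
def r4_sequence():
    return PeptideSequence(list(R4), first_index=62)


@pytest.fixture(scope="session")
def ideal_helix(r4_sequence):
    return build_peptide(r4_sequence)


@pytest.fixture(scope="session")
def helix_restraints(ideal_helix):
    """Ground-truth restraint set: every proton pair closer than 5 A,
    binned into the standard 2.7/3.5/5.0 A classes."""
    topo = ideal_helix.topology
    d = ideal_helix.distances()
    protons = topo.proton_indices()
    rows = []
    for a in range(len(protons)):
        for b in range(a + 1, len(protons)):
            i, j = protons[a], protons[b]
            r = d[i, j]
            if r > 5.0:
                continue
            upper = 2.7 if r <= 2.7 else (3.5 if r <= 3.5 else 5.0)
            rows.append(RestraintRow(topo.atoms[i], topo.atoms[j], 1.8, upper))
    return RestraintTable(rows=rows)


@pytest.fixture(scope="session")
def helix_bounds(r4_sequence, helix_restraints):
    from shiftfold.distgeom import build_bounds

    return build_bounds(r4_sequence, helix_restraints)


@pytest.fixture(scope="session")
def backbone_indices(ideal_helix):
    """Backbone atom indices over the ordered core (residues 63-72)."""
    from shiftfold.io import AtomRef

    topo = ideal_helix.topology
    return [topo.index_of(AtomRef(res, nm))
            for res in range(63, 73) for nm in ("N", "CA", "C")]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
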