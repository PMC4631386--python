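"""Distance-geometry structure engine.

Pipeline: holonomic + experimental distance bounds -> triangle-inequality
smoothing -> random (partial) metrization -> metric-matrix embedding in
four dimensions -> penalty refinement that anneals the fourth coordinate
away and enforces L-amino-acid chirality -> fixed-schedule steepest-descent
/ conjugate-gradient minimization -> ensemble generation and lowest-energy
selection.

All energies are restraint-penalty scores in squared Angstrom: the sum of
squared violations of the lower/upper bounds (holonomic covalent geometry,
soft-sphere lower bounds and experimental restraints enter on the same
footing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.sparse.csgraph import floyd_warshall, shortest_path
from scipy.sparse import csr_matrix

from .geom import place_atom
from .io import AtomRef, PeptideSequence, RestraintTable
from .peptide import Conformer, PeptideTopology, build_peptide

VDW_LOWER_SCALE = 0.8     # default lower bound = scale * sum of vdW radii
CHIRALITY_TARGET = 2.5    # signed CA volume (A^3) of an L residue, ideal geometry
CHIRALITY_MARGIN = 0.5    # penalty turns on below this volume
_EPS = 1e-9


class InconsistentBoundsError(ValueError):
    """Lower bound exceeds upper bound for some atom pair."""


@dataclass
class BoundsMatrix:
    """Symmetric lower/upper interatomic distance bounds over a topology."""

    topology: PeptideTopology
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        n = len(self.topology)
        assert self.lower.shape == self.upper.shape == (n, n)

    def copy(self) -> "BoundsMatrix":
        return BoundsMatrix(self.topology, self.lower.copy(), self.upper.copy())

    def check(self) -> None:
        gap = self.lower - self.upper
        i, j = np.unravel_index(np.argmax(gap), gap.shape)
        if gap[i, j] > _EPS:
            a, b = self.topology.atoms[i], self.topology.atoms[j]
            raise InconsistentBoundsError(
                f"lower {self.lower[i, j]:.3f} > upper {self.upper[i, j]:.3f} "
                f"for pair {a}-{b}")

    @property
    def fixed(self) -> np.ndarray:
        return self.upper - self.lower < 1e-6


def _dihedral_distance_range(b1, b2, b3, theta1, theta2):
    """(cis, trans) distance between atoms 1 and 4 of a rotatable
    four-atom chain with the given bond lengths / bond angles."""
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([b1, 0.0, 0.0])
    ang = np.deg2rad(theta1)
    c = b + b2 * np.array([-np.cos(ang), np.sin(ang), 0.0])
    d_cis = np.linalg.norm(place_atom(a, b, c, b3, theta2, 0.0) - a)
    d_trans = np.linalg.norm(place_atom(a, b, c, b3, theta2, 180.0) - a)
    return min(d_cis, d_trans), max(d_cis, d_trans)


def build_bounds(sequence: PeptideSequence,
                 restraints: RestraintTable | None = None,
                 vdw_scale: float = VDW_LOWER_SCALE,
                 ceiling: float | None = None) -> BoundsMatrix:
    """Construct the initial bounds matrix for a peptide.

    1-2 and 1-3 distances (and all pairs inside rigid planar groups) are
    fixed at ideal covalent geometry; 1-4 distances are bounded by their
    cis/trans rotation extremes; every other pair defaults to a scaled
    sum of van der Waals radii below and a chain-length ceiling above.
    Experimental restraints then intersect the defaults where they are
    tighter. A restraint whose upper bound undercuts a holonomically fixed
    distance is a contradiction and raises ``InconsistentBoundsError``.
    """
    ref = build_peptide(sequence)
    topo = ref.topology
    n = len(topo)
    dref = ref.distances()
    if ceiling is None:
        ceiling = 10.0 + 3.8 * len(sequence)

    radii = topo.vdw_radii()
    lower = vdw_scale * (radii[:, None] + radii[None, :])
    upper = np.full((n, n), float(ceiling))
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)

    adj_mat = csr_matrix(
        (np.ones(len(topo.bonds)), tuple(np.array(topo.bonds).T)), shape=(n, n))
    gdist = shortest_path(adj_mat, directed=False, unweighted=True)

    # holonomic 1-2 / 1-3
    near = (gdist == 1) | (gdist == 2)
    lower[near] = dref[near]
    upper[near] = dref[near]

    # 1-4: cis/trans rotation extremes (intersection over all 3-bond paths)
    adj = topo.adjacency()
    ii, jj = np.where(np.triu(gdist == 3))
    for i, l in zip(ii, jj):
        lo, hi = 0.0, np.inf
        for j in adj[i]:
            for k in adj[j]:
                if k != i and l in adj[k] and gdist[i, k] == 2:
                    c, t = _dihedral_distance_range(
                        dref[i, j], dref[j, k], dref[k, l],
                        _angle(dref, i, j, k), _angle(dref, j, k, l))
                    lo, hi = max(lo, c), min(hi, t)
        if hi < np.inf:
            lower[i, l] = lower[l, i] = lo
            upper[i, l] = upper[l, i] = hi

    # rigid planar groups: all internal distances fixed
    for grp in topo.rigid_groups:
        g = np.array(grp)
        lower[np.ix_(g, g)] = dref[np.ix_(g, g)]
        upper[np.ix_(g, g)] = dref[np.ix_(g, g)]
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)

    bm = BoundsMatrix(topo, lower, upper)
    if restraints is not None:
        _apply_restraints(bm, restraints)
    bm.check()
    return bm


def _angle(dref, i, j, k) -> float:
    """Bond angle i-j-k (degrees) from the three pair distances."""
    a, b, c = dref[i, j], dref[j, k], dref[i, k]
    cosang = (a * a + b * b - c * c) / (2 * a * b)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _apply_restraints(bm: BoundsMatrix, restraints: RestraintTable) -> None:
    topo = bm.topology
    for row in restraints.rows:
        for a in topo.resolve(row.atom_i):
            for b in topo.resolve(row.atom_j):
                if a == b:
                    continue
                if bm.fixed[a, b]:
                    if row.upper < bm.lower[a, b] - 1e-6:
                        raise InconsistentBoundsError(
                            f"restraint {row.atom_i}-{row.atom_j} upper "
                            f"{row.upper:.2f} A below the holonomic distance "
                            f"{bm.lower[a, b]:.2f} A")
                    continue  # holonomic geometry wins; restraint redundant
                lo = max(bm.lower[a, b], row.lower)
                hi = min(bm.upper[a, b], row.upper)
                if lo > hi + _EPS:
                    # NOE lower bounds are soft conventions; the steric /
                    # rotational lower bound takes precedence
                    lo = min(lo, hi)
                bm.lower[a, b] = bm.lower[b, a] = lo
                bm.upper[a, b] = bm.upper[b, a] = hi


# ---------------------------------------------------------------------------
# triangle smoothing
# ---------------------------------------------------------------------------

def smooth_bounds(bounds: BoundsMatrix, max_passes: int = 10) -> BoundsMatrix:
    """Triangle-inequality smoothing.

    Upper bounds are replaced by all-pairs shortest paths over the upper
    matrix; lower bounds are raised by the inverse triangle inequality
    (l_ik >= max_j l_ij - u_jk), iterated to a fixed point. The operation
    is idempotent. Raises ``InconsistentBoundsError`` if smoothing crosses
    the bounds anywhere.
    """
    u_fw = floyd_warshall(bounds.upper, directed=False)
    # keep original entries unless the path bound is a real improvement;
    # this makes the operation exactly idempotent in floating point
    u = np.where(u_fw < bounds.upper - 1e-12, u_fw, bounds.upper)
    l = bounds.lower.copy()
    n = l.shape[0]
    for _ in range(max_passes):
        changed = False
        for k in range(n):
            cand = l[:, k][:, None] - u[k, :][None, :]
            cand = np.maximum(cand, cand.T)
            mask = cand > l + 1e-12
            if mask.any():
                l[mask] = cand[mask]
                changed = True
        if not changed:
            break
    np.fill_diagonal(l, 0.0)
    out = BoundsMatrix(bounds.topology, l, u)
    out.check()
    return out


# ---------------------------------------------------------------------------
# metrization
# ---------------------------------------------------------------------------

def _fix_pair(l, u, i, j, v):
    """Fix d(i,j) = v and propagate the consequence to all other pairs."""
    l[i, j] = l[j, i] = v
    u[i, j] = u[j, i] = v
    ui = u[:, i][:, None]
    uj = u[:, j][:, None]
    np.minimum(u, ui + v + u[j, :][None, :], out=u)
    np.minimum(u, uj + v + u[i, :][None, :], out=u)
    cand = np.maximum(v - ui - u[j, :][None, :], v - uj - u[i, :][None, :])
    cand = np.maximum(cand, cand.T)
    np.maximum(l, cand, out=l)
    np.fill_diagonal(l, 0.0)
    np.fill_diagonal(u, 0.0)


def metrize_sample(bounds: BoundsMatrix, seed: int,
                   fraction: float = 0.1, full: bool = False,
                   max_retries: int = 8) -> np.ndarray:
    """Sample a full distance matrix consistent with smoothed bounds.

    Random metrization: pair distances are fixed one at a time in a seeded
    random order, each drawn uniformly within its current bounds, with the
    consequences propagated to the remaining bounds after each fix. By
    default only a random `fraction` of pairs is metrized this way
    (partial metrization), followed by one final full smooth and
    independent uniform sampling of the remaining pairs; ``full=True``
    metrizes every pair. On an inconsistency the whole procedure retries
    with a fresh order, up to `max_retries` times.
    """
    base = smooth_bounds(bounds)
    n = len(bounds.topology)
    iu, ju = np.triu_indices(n, k=1)
    free = ~base.fixed[iu, ju]
    order_pool = np.flatnonzero(free)
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed + 1000003 * attempt) % (2**31))
        l, u = base.lower.copy(), base.upper.copy()
        k = len(order_pool) if full else max(1, int(round(fraction * len(order_pool))))
        chosen = rng.permutation(order_pool)[:k]
        ok = True
        for p in chosen:
            i, j = int(iu[p]), int(ju[p])
            lo, hi = l[i, j], u[i, j]
            if lo > hi + 1e-6:
                ok = False
                break
            _fix_pair(l, u, i, j, rng.uniform(lo, hi))
        if not ok:
            last_err = InconsistentBoundsError("metrization crossed bounds")
            continue
        try:
            sm = smooth_bounds(BoundsMatrix(bounds.topology, l, u))
        except InconsistentBoundsError as exc:
            last_err = exc
            continue
        d = rng.uniform(sm.lower[iu, ju], sm.upper[iu, ju])
        out = np.zeros((n, n))
        out[iu, ju] = d
        out += out.T
        return out
    raise InconsistentBoundsError(
        f"metrization failed after {max_retries} attempts: {last_err}")


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def embed(distances: np.ndarray, dimensions: int = 3,
          topology: PeptideTopology | None = None):
    """Metric-matrix (classical MDS) embedding of a distance matrix.

    Coordinates come from the top eigenpairs of the Gram matrix obtained
    by double-centering the squared distances. Exact Euclidean inputs are
    reproduced up to rigid motion and reflection. If fewer than
    `dimensions` eigenvalues are positive, a degenerate-geometry warning
    is issued and the missing coordinates are zero.

    Returns raw coordinates, or a `Conformer` when a topology is given.
    """
    d2 = np.asarray(distances, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:dimensions]
    lam = evals[order]
    pos = lam > 1e-10 * max(1.0, abs(evals).max())
    if pos.sum() < dimensions:
        warnings.warn(
            f"degenerate geometry: only {int(pos.sum())} positive eigenvalues "
            f"for a {dimensions}-dimensional embedding", stacklevel=2)
    coords = np.zeros((n, dimensions))
    coords[:, pos] = evecs[:, order[pos]] * np.sqrt(lam[pos])
    if topology is None:
        return coords
    return Conformer(topology=topology, coords=coords,
                     metadata={"stage": "embedded", "rank": int(pos.sum())})


# ---------------------------------------------------------------------------
# penalty energy
# ---------------------------------------------------------------------------

def _pair_penalty(x, lower, upper, grad=True):
    """Penalty core on explicit bound matrices (any coordinate dimension).

    The gradient is assembled from matrix products rather than an
    (n, n, dim) displacement tensor:
    g_i = 2 [ (sum_j w_ij) x_i - sum_j w_ij x_j ].
    """
    d2 = np.einsum("ik,ik->i", x, x)
    d = d2[:, None] + d2[None, :] - 2.0 * (x @ x.T)
    np.maximum(d, 0.0, out=d)
    np.sqrt(d, out=d)
    np.fill_diagonal(d, 1.0)  # avoid 0/0; diagonal bounds are (0, 0)
    over = np.maximum(0.0, d - upper)
    under = np.maximum(0.0, lower - d)
    np.fill_diagonal(over, 0.0)
    np.fill_diagonal(under, 0.0)
    e = 0.5 * float((over ** 2 + under ** 2).sum())  # each pair counted once
    if not grad:
        return e
    w = over - under
    w /= d
    g = 2.0 * (w.sum(axis=1)[:, None] * x - w @ x)
    return e, g


def bounds_penalty(coords: np.ndarray, bounds: BoundsMatrix,
                   grad: bool = False):
    """Sum of squared bound violations (and its gradient) over all pairs.

    Works for 3D or 4D coordinates; the bounds apply to the full-dimensional
    interatomic distance.
    """
    return _pair_penalty(np.asarray(coords, dtype=float),
                         bounds.lower, bounds.upper, grad=grad)


def _chirality_quads(topology: PeptideTopology,
                     index_map=None) -> np.ndarray:
    """(n_centers, 4) array of [CA, N, C, CB] atom indices per non-Gly
    residue; `index_map` remaps topology indices (for subsystems)."""
    quads = []
    for kind, res in zip(topology.sequence.residues, topology.sequence.indices):
        if kind == "G":
            continue
        idx = [topology.index_of(AtomRef(res, nm))
               for nm in ("CA", "N", "C", "CB")]
        if index_map is not None:
            idx = [index_map[i] for i in idx]
        quads.append(idx)
    return np.array(quads, dtype=int).reshape(-1, 4)


def _signed_volumes(x3: np.ndarray, quads: np.ndarray) -> np.ndarray:
    ca, nn, cc, cb = (x3[quads[:, k]] for k in range(4))
    return np.einsum("ij,ij->i", nn - ca, np.cross(cc - ca, cb - ca))


def chirality_volumes(topology: PeptideTopology, coords3d: np.ndarray) -> np.ndarray:
    """Signed volume (N-CA, C-CA, CB-CA) at each non-Gly CA; positive for
    the natural L configuration with the builder's geometry (~+2.5 A^3)."""
    return _signed_volumes(np.asarray(coords3d)[:, :3],
                           _chirality_quads(topology))


def _chirality_penalty(quads, coords, grad=False, weight=1.0):
    """Hinge penalty pushing every CA signed volume above CHIRALITY_MARGIN
    (acts on the first three coordinates only)."""
    x3 = coords[:, :3]
    if len(quads) == 0:
        return (0.0, np.zeros_like(coords)) if grad else 0.0
    v = _signed_volumes(x3, quads)
    short = np.maximum(0.0, CHIRALITY_MARGIN - v)
    e = weight * float((short ** 2).sum())
    if not grad:
        return e
    g = np.zeros_like(coords)
    act = np.flatnonzero(short > 0)
    if len(act):
        q = quads[act]
        ca, nn, cc, cb = (x3[q[:, k]] for k in range(4))
        dv = (-2.0 * weight * short[act])[:, None]
        g_n = np.cross(cc - ca, cb - ca) * dv
        g_c = np.cross(cb - ca, nn - ca) * dv
        g_cb = np.cross(nn - ca, cc - ca) * dv
        np.add.at(g[:, :3], q[:, 1], g_n)
        np.add.at(g[:, :3], q[:, 2], g_c)
        np.add.at(g[:, :3], q[:, 3], g_cb)
        np.add.at(g[:, :3], q[:, 0], -(g_n + g_c + g_cb))
    return e, g


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

# (w4 weight on the 4th coordinate, chirality weight, L-BFGS iterations)
DEFAULT_SCHEDULE = ((0.0, 1.0, 120), (0.3, 3.0, 120), (3.0, 10.0, 120),
                    (30.0, 30.0, 120), (300.0, 30.0, 80))


def _anneal_4d(x, lower, upper, quads, schedule):
    """Annealed 4D minimization followed by projection; returns 3D coords."""
    n = x.shape[0]

    def objective(flat, w4, wc):
        xx = flat.reshape(n, 4)
        e, g = _pair_penalty(xx, lower, upper)
        ec, gc = _chirality_penalty(quads, xx, grad=True, weight=wc)
        e += ec + w4 * float((xx[:, 3] ** 2).sum())
        g += gc
        g[:, 3] += 2.0 * w4 * xx[:, 3]
        if not np.isfinite(e):
            raise FloatingPointError("non-finite refinement energy")
        return e, g.ravel()

    for w4, wc, maxiter in schedule:
        res = _scipy_minimize(objective, x.ravel(), args=(w4, wc), jac=True,
                              method="L-BFGS-B", options={"maxiter": maxiter})
        x = res.x.reshape(n, 4)
        if w4 > 0 and np.abs(x[:, 3]).max() < 1e-4:
            break
    return x[:, :3].copy()


def _polish_3d(x3, lower, upper, quads, maxiter, chirality_weight=30.0):
    n = x3.shape[0]

    def objective(flat):
        xx = flat.reshape(n, 3)
        e, g = _pair_penalty(xx, lower, upper)
        ec, gc = _chirality_penalty(quads, xx, grad=True,
                                    weight=chirality_weight)
        if not np.isfinite(e + ec):
            raise FloatingPointError("non-finite refinement energy")
        return e + ec, (g + gc).ravel()

    res = _scipy_minimize(objective, x3.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": maxiter})
    return res.x.reshape(n, 3)


def refine(conformer: Conformer, bounds: BoundsMatrix,
           schedule=DEFAULT_SCHEDULE, chirality_weight: float = 30.0,
           polish_iter: int = 500) -> Conformer:
    """Four-dimensional penalty refinement.

    Minimizes bound violations plus an annealed penalty ``w4 * sum(x4^2)``
    on the fourth coordinate, stage by stage, until the fourth coordinate
    collapses (max |x4| < 1e-3 A), then polishes in 3D. A chirality penalty
    keeps the CA centers in the L configuration, after an initial global
    reflection if the majority of chiral centers embed inverted. Returns a
    3D conformer whose energy is the pure bounds penalty.
    """
    x = np.array(conformer.coords, dtype=float)
    topo = conformer.topology
    quads = _chirality_quads(topo)
    if x.shape[1] == 3:
        e0 = bounds_penalty(x, bounds)
        if e0 < 1e-12:
            return Conformer(topo, x, energy=float(e0),
                             metadata={**conformer.metadata, "stage": "refined"})
        x = np.hstack([x, np.zeros((x.shape[0], 1))])

    vols = _signed_volumes(x[:, :3], quads)
    if len(vols) and (vols < 0).sum() > len(vols) / 2:
        x[:, 0] *= -1.0  # mirror image: reflect

    x3 = _anneal_4d(x, bounds.lower, bounds.upper, quads, schedule)
    x3 = _polish_3d(x3, bounds.lower, bounds.upper, quads, polish_iter,
                    chirality_weight)
    e = bounds_penalty(x3, bounds)
    return Conformer(topo, x3, energy=float(e),
                     metadata={**conformer.metadata, "stage": "refined"})


# ---------------------------------------------------------------------------
# fixed-schedule minimization
# ---------------------------------------------------------------------------

def minimize(conformer: Conformer, bounds: BoundsMatrix,
             n_steepest: int = 200, n_conjugate: int = 10,
             step: float = 0.02) -> Conformer:
    """Exactly `n_steepest` steepest-descent then `n_conjugate`
    conjugate-gradient steps on the restraint-penalty + soft-sphere energy,
    with the per-atom displacement capped at `step` Angstrom per move.
    Energy is non-increasing across the run (uphill moves are rejected).
    """
    x = np.array(conformer.coords3d(), dtype=float)
    e, g = bounds_penalty(x, bounds, grad=True)

    def capped(direction):
        norms = np.linalg.norm(direction, axis=1)
        m = norms.max()
        if m < 1e-15:
            return None
        return direction * (step / m)

    for _ in range(n_steepest):
        d = capped(-g)
        if d is None:
            break
        xn = x + d
        en, gn = bounds_penalty(xn, bounds, grad=True)
        if en <= e:
            x, e, g = xn, en, gn

    prev_g = None
    direction = None
    for _ in range(n_conjugate):
        if prev_g is None:
            direction = -g
        else:
            beta = max(0.0, float((g * (g - prev_g)).sum() / (prev_g * prev_g).sum()))
            direction = -g + beta * direction
        d = capped(direction)
        if d is None:
            break
        xn = x + d
        en, gn = bounds_penalty(xn, bounds, grad=True)
        if en <= e:
            prev_g = g
            x, e, g = xn, en, gn
        else:
            prev_g = None  # restart CG from steepest descent
    return Conformer(conformer.topology, x, energy=float(e),
                     metadata={**conformer.metadata, "stage": "minimized"})


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def _sample_distances(l0, u0, rng, fraction=0.1, beta=3.0):
    """Tolerant partial metrization: fix a random `fraction` of the free
    pairs one at a time (uniform within current bounds, propagated after
    each fix; a crossed pair is clamped at its bound midpoint), then sample
    the remaining pairs independently with a compactness bias and repair
    the result to a metric by shortest paths."""
    n = l0.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    l, u = l0.copy(), u0.copy()
    free = np.flatnonzero(u[iu, ju] - l[iu, ju] >= 1e-6)
    k = max(1, int(round(fraction * len(free)))) if len(free) else 0
    for p in rng.permutation(free)[:k]:
        i, j = int(iu[p]), int(ju[p])
        lo, hi = l[i, j], u[i, j]
        v = 0.5 * (lo + hi) if lo > hi else rng.uniform(lo, hi)
        _fix_pair(l, u, i, j, v)
    np.minimum(l, u, out=l)
    frac = rng.beta(1.0, beta, size=len(iu))
    dd = l[iu, ju] + frac * (u[iu, ju] - l[iu, ju])
    d = np.zeros((n, n))
    d[iu, ju] = dd
    d += d.T
    return floyd_warshall(d, directed=False)


class DGRunFailure(RuntimeError):
    """A single distance-geometry run did not converge to an acceptable
    structure (residual violations too large or inverted chiral centers)."""


# atom names of the coarse subsystem solved first in each run
SUBSYSTEM_ATOMS = ("N", "CA", "C", "O", "H", "HA", "HA2", "HA3",
                   "CB", "HB", "HB2", "HB3")
ATTEMPT_GATE = 3.0     # A^2: triage energy below which an attempt is pursued
SUCCESS_ENERGY = 2.0   # A^2: a converged run must end below this


class _FoldContext:
    """Precomputed state shared by all runs on one bounds matrix."""

    def __init__(self, bounds: BoundsMatrix, fraction: float = 0.3):
        self.bounds = bounds
        self.fraction = fraction
        self.topology = bounds.topology
        base = smooth_bounds(bounds)
        topo = self.topology
        self.sub = np.array([i for i, a in enumerate(topo.atoms)
                             if a.atom_name in SUBSYSTEM_ATOMS])
        self.ls = base.lower[np.ix_(self.sub, self.sub)]
        self.us = base.upper[np.ix_(self.sub, self.sub)]
        remap = {g: k for k, g in enumerate(self.sub)}
        self.quads_sub = _chirality_quads(topo, index_map=remap)
        self.quads_full = _chirality_quads(topo)
        self.sub_index = {topo.atoms[g]: k for k, g in enumerate(self.sub)}

    def backbone_from(self, x3sub: np.ndarray) -> np.ndarray:
        seq = self.topology.sequence
        bb = np.zeros((len(seq), 3, 3))
        for k, res in enumerate(seq.indices):
            for m, nm in enumerate(("N", "CA", "C")):
                bb[k, m] = x3sub[self.sub_index[AtomRef(res, nm)]]
        return bb


def fold_once(ctx: _FoldContext, seed: int, max_attempts: int = 8,
              schedule=DEFAULT_SCHEDULE) -> Conformer:
    """One seeded structure calculation.

    The backbone-centred subsystem (N, CA, C, O, CB and their protons) is
    solved first by metrization, 4D embedding and annealed refinement
    against the subsystem block of the smoothed bounds; side chains are
    then rebuilt onto that backbone in clash-minimizing rotamers and the
    full system is polished in 3D. Up to `max_attempts` subsystem attempts
    are made; a run whose final structure retains large violations or any
    inverted CA center raises DGRunFailure.
    """
    from .peptide import assemble_on_backbone

    bounds = ctx.bounds
    rng = np.random.default_rng(seed % (2**31))
    best = None
    for _ in range(max_attempts):
        d = _sample_distances(ctx.ls, ctx.us, rng, fraction=ctx.fraction)
        x = embed(d, dimensions=4)
        vols = _signed_volumes(x[:, :3], ctx.quads_sub)
        if len(vols) and (vols < 0).sum() > len(vols) / 2:
            x[:, 0] *= -1.0
        x3 = _anneal_4d(x, ctx.ls, ctx.us, ctx.quads_sub, schedule)
        x3 = _polish_3d(x3, ctx.ls, ctx.us, ctx.quads_sub, 400)
        e_sub = _pair_penalty(x3, ctx.ls, ctx.us, grad=False)
        if e_sub > 1.5:
            continue  # tangled embedding; a fresh attempt is cheaper
        for _cycle in range(3):
            v = _signed_volumes(x3, ctx.quads_sub)
            if e_sub < 0.05 and not (v < 0).any():
                break
            x3 = _polish_3d(x3 + rng.normal(0.0, 0.2, x3.shape),
                            ctx.ls, ctx.us, ctx.quads_sub, 400)
            e_sub = _pair_penalty(x3, ctx.ls, ctx.us, grad=False)
        conf = assemble_on_backbone(ctx.topology.sequence,
                                    ctx.backbone_from(x3))
        xf = _polish_3d(conf.coords, bounds.lower, bounds.upper,
                        ctx.quads_full, 250)
        e = bounds_penalty(xf, bounds)
        if best is None or e < best[1]:
            best = (xf, e)
        if e < ATTEMPT_GATE:
            break
    if best is None:
        raise DGRunFailure(
            f"run at seed {seed}: no subsystem attempt reached feasibility")
    xf = best[0]
    for _cycle in range(2):
        xf = _polish_3d(xf, bounds.lower, bounds.upper, ctx.quads_full, 700)
        if bounds_penalty(xf, bounds) < 0.05:
            break
    conf = Conformer(ctx.topology, xf,
                     energy=float(bounds_penalty(xf, bounds)),
                     metadata={"seed": seed, "stage": "refined"})
    conf = minimize(conf, bounds)
    inv = int((_signed_volumes(conf.coords, ctx.quads_full) < 0).sum())
    if inv > 0 or conf.energy > SUCCESS_ENERGY:
        raise DGRunFailure(
            f"run at seed {seed} did not converge: residual penalty "
            f"{conf.energy:.2f} A^2, {inv} inverted CA center(s)")
    return conf


@dataclass
class ConformerEnsemble:
    """A set of conformers over one topology, with selection metadata."""

    conformers: list[Conformer]
    selection_rule: tuple[int, int] | None = None  # (n_generated, n_kept)
    failures: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])


def generate_ensemble(bounds: BoundsMatrix, n: int, seed: int,
                      fraction: float = 0.1,
                      schedule=DEFAULT_SCHEDULE) -> ConformerEnsemble:
    """Run `n` independent seeded structure calculations (run i uses seed
    `seed + i`), each a metrize -> embed(4D) -> refine -> minimize chain
    (hierarchical: backbone subsystem first, full system after side-chain
    rebuilding). Failed runs are recorded, not silently dropped; if every
    run fails an error with per-run diagnostics is raised.
    """
    ctx = _FoldContext(bounds, fraction=fraction)
    conformers: list[Conformer] = []
    failures: list[tuple[int, str]] = []
    for i in range(n):
        run_seed = seed + i
        try:
            conformers.append(fold_once(ctx, run_seed, schedule=schedule))
        except (DGRunFailure, InconsistentBoundsError,
                FloatingPointError) as exc:
            failures.append((run_seed, str(exc)))
    if not conformers:
        lines = "; ".join(f"seed {s}: {m}" for s, m in failures[:5])
        raise RuntimeError(f"all {n} distance-geometry runs failed: {lines}")
    return ConformerEnsemble(conformers=conformers,
                             selection_rule=(n, len(conformers)),
                             failures=failures)


def select_lowest(ensemble: ConformerEnsemble, k: int) -> ConformerEnsemble:
    """Keep the `k` lowest-energy conformers, sorted by energy ascending;
    ties broken by generation order (stable sort)."""
    if not 1 <= k <= len(ensemble.conformers):
        raise ValueError(f"k={k} outside 1..{len(ensemble.conformers)}")
    order = np.argsort([c.energy for c in ensemble.conformers], kind="stable")
    kept = [ensemble.conformers[i] for i in order[:k]]
    n_gen = ensemble.selection_rule[0] if ensemble.selection_rule else len(ensemble)
    return ConformerEnsemble(conformers=kept, selection_rule=(n_gen, k),
                             failures=list(ensemble.failures))
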