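"""Chemical-shift-perturbation mapping.

The per-residue perturbation is the weighted 1H/15N Euclidean distance

    d = sqrt( (dH^2 + (alpha dN)^2) / 2 ),

with alpha = 0.14 for all residues except glycine (alpha = 0.20), the
Williamson weighting. Residues are classified against the standard
deviation sigma of the assigned d set: the binding epitope is read from
the > 2 sigma and > sigma tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PeakTable

ALPHA_DEFAULT = 0.14
ALPHA_GLYCINE = 0.20

TIER_STRONG = ">=2sigma"
TIER_WEAK = ">=1sigma"
TIER_BELOW = "<sigma"
TIER_UNASSIGNED = "unassigned"


def alpha_for(residue_kind: str) -> float:
    return ALPHA_GLYCINE if residue_kind.upper() == "G" else ALPHA_DEFAULT


def compute_csp(free, bound, residue_kind: str = "A") -> float:
    """Weighted 1H/15N Euclidean shift distance between two peaks.

    `free` and `bound` are (h_shift, n_shift) pairs (or PeakEntry); the
    glycine nitrogen weighting is applied when `residue_kind` is G.
    """
    fh, fn = ((free.h_shift, free.n_shift) if hasattr(free, "h_shift")
              else tuple(free))
    bh, bn = ((bound.h_shift, bound.n_shift) if hasattr(bound, "h_shift")
              else tuple(bound))
    a = alpha_for(residue_kind)
    dh = bh - fh
    dn = bn - fn
    return float(np.sqrt((dh * dh + (a * dn) ** 2) / 2.0))


@dataclass
class CSPProfile:
    """Per-residue perturbations with sigma-tier labels.

    `d` is None for residues that could not be followed unambiguously
    through the titration (the negative bars of the usual CSP plot);
    those residues carry no d and never contribute to sigma.
    """

    entries: list[tuple[int, float | None, str]]  # (residue, d, tier)
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for res, d, tier in self.entries:
            if (d is None) != (tier == TIER_UNASSIGNED):
                raise ValueError(f"residue {res}: d/tier inconsistent")
            if d is not None and d < 0:
                raise ValueError(f"residue {res}: negative perturbation")

    def tier(self, residue: int) -> str:
        for res, _, t in self.entries:
            if res == residue:
                return t
        raise KeyError(residue)

    @property
    def assigned(self) -> dict[int, float]:
        return {res: d for res, d, _ in self.entries if d is not None}

    def residues_in_tier(self, tier: str) -> list[int]:
        return [res for res, _, t in self.entries if t == tier]


@dataclass
class TrackedTitration:
    """Output of peak tracking: per-residue positions across ratios."""

    ratios: list[float]
    trajectories: dict[int, np.ndarray]       # residue -> (n_ratios, 2) ppm
    kinds: dict[int, str]
    ambiguous: set[int] = field(default_factory=set)

    def unambiguous(self) -> dict[int, np.ndarray]:
        return {r: t for r, t in self.trajectories.items()
                if r not in self.ambiguous}


#: candidate whose runner-up is closer than this factor away is ambiguous
AMBIGUITY_FACTOR = 2.0


def track_peaks(series: list[PeakTable]) -> TrackedTitration:
    """Follow each assigned free-state peak through the titration.

    Tables must be ordered by ratio with the fully assigned zero-ratio
    table first. Linking is stepwise nearest-neighbour in the scaled
    (dH, alpha dN) space; a residue whose best and second-best candidates
    in some step differ by less than a factor of 2 is marked ambiguous
    (its assignment cannot be transferred), as is any residue whose
    nearest peak is claimed by a closer competitor.
    """
    if not series:
        raise ValueError("empty titration series")
    series = sorted(series, key=lambda t: t.ratio_label)
    free = series[0]
    if free.ratio_label != 0:
        raise ValueError("titration series lacks the zero-ratio reference")
    kinds = {e.residue_index: e.residue_kind for e in free.entries}
    pos = {e.residue_index: np.array([e.h_shift, e.n_shift])
           for e in free.entries}
    traj = {r: [p] for r, p in pos.items()}
    ambiguous: set[int] = set()
    for table in series[1:]:
        peaks = np.array([[e.h_shift, e.n_shift] for e in table.entries])
        claims: dict[int, tuple[int, float]] = {}  # peak index -> (residue, dist)
        new_pos = {}
        for res, p in pos.items():
            a = alpha_for(kinds[res])
            scaled = (peaks - p) * np.array([1.0, a])
            dist = np.linalg.norm(scaled, axis=1)
            order = np.argsort(dist)
            bi = int(order[0])
            best = dist[bi]
            if len(dist) > 1 and dist[order[1]] < AMBIGUITY_FACTOR * best:
                ambiguous.add(res)
            prev = claims.get(bi)
            if prev is not None:
                # two residues converge on one peak: both are unsafe
                ambiguous.add(res)
                ambiguous.add(prev[0])
            else:
                claims[bi] = (res, best)
            new_pos[res] = peaks[bi]
        for res, p in new_pos.items():
            traj[res].append(p)
        pos = new_pos
    return TrackedTitration(
        ratios=[t.ratio_label for t in series],
        trajectories={r: np.array(t) for r, t in traj.items()},
        kinds=kinds, ambiguous=ambiguous)


def profile_from_tracking(tracked: TrackedTitration,
                          population_sigma: bool = True) -> CSPProfile:
    """CSP profile from the endpoint of each unambiguous trajectory."""
    values = {}
    for res, t in tracked.trajectories.items():
        if res in tracked.ambiguous:
            continue
        values[res] = compute_csp(tuple(t[0]), tuple(t[-1]),
                                  tracked.kinds[res])
    return classify_epitope(values,
                            unassigned=sorted(tracked.ambiguous),
                            population_sigma=population_sigma)


def classify_epitope(values: dict[int, float], unassigned=(),
                     population_sigma: bool = True) -> CSPProfile:
    """Tier the assigned perturbations against sigma and 2 sigma.

    sigma is the (population, by default) standard deviation of the
    assigned d values only; tier membership uses strict > comparisons.
    Unassigned residues are carried through with no d value. Raises if
    fewer than two residues are assigned (sigma undefined).
    """
    if len(values) < 2:
        raise ValueError("sigma undefined: need >= 2 assigned residues")
    d = np.array(list(values.values()), dtype=float)
    sigma = float(d.std(ddof=0 if population_sigma else 1))
    entries: list[tuple[int, float | None, str]] = []
    for res in sorted(set(values) | set(unassigned)):
        if res in values:
            v = values[res]
            if sigma > 0 and v > 2 * sigma:
                tier = TIER_STRONG
            elif sigma > 0 and v > sigma:
                tier = TIER_WEAK
            else:
                tier = TIER_BELOW
            entries.append((res, float(v), tier))
        else:
            entries.append((res, None, TIER_UNASSIGNED))
    return CSPProfile(entries=entries, sigma=sigma)
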