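# Methods

`shiftfold` reimplements, as one tested pipeline, the computational chain
used to map a calmodulin-binding epitope by NMR chemical-shift
perturbation (CSP), extract a dissociation constant from a fast-exchange
titration, fit plate-reader dose-response curves, convert transferred-NOE
intensities into distance restraints, and calculate a bound-peptide
structure by distance geometry. This note records the models, the
numerical choices, and what the synthetic-data tests do and do not show.

## Chemical-shift perturbation mapping

For each backbone amide the perturbation between free and ligand-bound
spectra is the weighted Euclidean distance

    d = sqrt( (dH^2 + (alpha * dN)^2) / 2 )          [ppm]

with `alpha = 0.14` for all residues except glycine (`alpha = 0.20`), the
Williamson weighting that puts the 15N axis on the 1H scale. The epitope
is classified against the standard deviation sigma of the assigned `d`
set: residues with `d > 2 sigma` form the strong tier, `d > sigma` the
weak tier. Comparisons are strict, and sigma is the population standard
deviation over assigned residues only (a `population_sigma=False` switch
gives the sample convention). Residues that cannot be followed through
the titration carry no `d` and never contribute to sigma.

Peak tracking across titration points is stepwise nearest-neighbour in
the scaled `(dH, alpha*dN)` plane. Two situations mark a residue
unassignable: its best and second-best candidate peaks lie within a
factor of 2 of each other, or two residues claim the same peak. On
noiseless synthetic titrations every *unambiguous* trajectory recovers
the simulated bound-state displacement exactly; the flagged set is the
price of honest assignment transfer in crowded spectra.

## Fast-exchange K_D

Under fast exchange the observed shift is the population-weighted mean of
free and bound shifts. Because the protein concentration (55 uM) is
comparable to the dissociation constant, the bound fraction uses the
exact single-site mass balance with ligand depletion,

    f = ((P + L + K_D) - sqrt((P + L + K_D)^2 - 4 P L)) / (2 P),

never the L >> P approximation. The fit has one global K_D shared by all
residues; the per-residue bound-state displacement is profiled out
linearly at each trial K_D (variable projection), leaving a 1-D
optimization over log K_D started from 8 log-spaced values between
P/100 and 100 P. Residues whose total displacement is below 3x the noise
floor are excluded as unidentifiable. The reported uncertainty is a
delta-method standard error on log K_D from the profiled 1-D Jacobian;
the results object reports both the point estimate and a 95% interval,
since a range can reflect either per-residue spread or fit uncertainty.

## Dose-response fitting

Plate signals are fitted with the four-parameter logistic

    y = m1 + (m2 - m1) / (1 + (x / m3)^m4),

which has y(0) = m2 and y(inf) = m1 for m4 > 0, so `m2` is the zero-analyte
signal and `m1` the saturating plateau; `m3` is the inflection
concentration, read out as K_D (direct format) or IC50 (competition
format, descending curve). The fit is Levenberg-Marquardt on
(m1, m2, log m3, m4) with 8 log-spaced m3 starts; monotone-flat input is
flagged non-identifiable rather than fitted. `ic50_from_fit` refuses an
ascending curve when the competition flag is set.

## NOE calibration and restraints

Intensities follow the isolated-spin-pair approximation I ~ r^-6.
Calibration uses a geminal CH2 proton pair whose separation is known from
covalent geometry: 2 * 1.09 A * sin(109.47/2 deg) = 1.78 A. A cross peak
of intensity I then gives r = r_ref (I_ref / I)^(1/6). Calibrated
distances are binned into the standard three restraint classes - upper
bounds 2.7, 3.5 or 5.0 A over a universal 1.8 A lower bound - because a
class scheme is robust to the intensity distortions (spin diffusion,
internal motion) that make exact distances unreliable. Pseudoatom upper
bound corrections are +1.0 A for methyls and +0.7 A for unresolved
methylene/aromatic pairs; duplicates merge to the tighter upper bound.
Geminal pairs sit slightly inside the conventional 1.8 A floor (1.74-1.78
A), a deliberate, universally accepted convention; violation statistics
show it as sub-0.1 A lower-bound violations.

Restraint files use a single X-PLOR-style `assign` line per restraint.
Two trailing numbers are read as explicit (lower, upper); three are read
deposition-style as (d, d-minus, d-plus), so the same reader imports
deposited restraint tables.

## Distance geometry

The engine converts bounds to coordinates in the classical stages, with
one structural choice described below.

**Bounds.** 1-2 and 1-3 distances (and all pairs inside rigid planar
groups: peptide planes, aromatic rings with their substituents,
guanidinium/amide/carboxylate termini) are fixed at ideal covalent
geometry taken from Chemical Component Dictionary residue templates. 1-4
distances are bounded by their cis/trans rotation extremes computed from
bond lengths and angles only. All other pairs default to a soft-sphere
lower bound of 0.8x the sum of van der Waals radii (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.10 A; polar H shrunk to 0.50 A so hydrogen-bonded
geometry stays feasible) and a chain-length ceiling. Experimental
restraints intersect the defaults where tighter; a restraint whose upper
bound undercuts a holonomically fixed distance is an error, while an NOE
lower bound softer than the steric one simply loses.

**Smoothing.** Upper bounds become all-pairs shortest paths
(Floyd-Warshall); lower bounds are raised by the inverse triangle
inequality iterated to a fixed point. An epsilon guard (1e-12 A) accepts
only genuine improvements, which makes the operation exactly idempotent
in floating point. Crossed bounds raise an error naming the pair.

**Metrization and sampling.** Partial random metrization is the default:
a seeded random 30% of the free pairs (10% for the generic
`metrize_sample` entry point) are fixed one at a time, each drawn
uniformly within its current bounds, with the consequences of each fix
propagated to all other pairs by the exact one-edge shortest-path update
(uppers) and its inverse-triangle counterpart (lowers). Full metrization
is available behind a flag. The remaining pairs are sampled independently
with a compactness bias (Beta(1,3) between the bounds) and the matrix is
repaired to a metric by one shortest-path pass. The strict
`metrize_sample` operation retries with a fresh order on inconsistency
and errors out after a bounded count; the fold protocol instead clamps a
crossed pair at its bound midpoint, accepting small inconsistencies that
the refinement stage absorbs.

**Embedding and refinement.** Coordinates come from the top eigenpairs of
the double-centred squared-distance Gram matrix, in four dimensions. The
refinement objective is the sum of squared bound violations (the "energy",
in A^2) plus an annealed penalty `w4 * sum(x4^2)` that collapses the
fourth coordinate, plus a hinge penalty keeping the signed volume at each
CA (spanned by N, C, CB) above +0.5 A^3 - the L configuration scores about
+2.5 A^3 with ideal geometry - after a global reflection if the majority
of centres embed inverted. Stages use L-BFGS; the fourth dimension lets
chirality and knot defects unwind before projection to 3D.

**Hierarchical protocol.** Direct all-atom refinement of a metrized
12-mer proved unreliable: most runs stalled in tangled minima. The
production protocol (`generate_ensemble`) therefore solves a
backbone-centred subsystem first - N, CA, C, O, CB and their protons,
against the subsystem block of the *fully smoothed* bounds, so side-chain
NOE information still reaches it through triangle paths - then rebuilds
side chains onto the solved backbone in clash-minimizing staggered
rotamers and polishes the full system in 3D. Each seeded run makes up to
8 subsystem attempts, aborting an attempt early when the subsystem
penalty stays above 1.5 A^2; a run whose final structure keeps a penalty
above 2 A^2 or any inverted CA centre is reported as failed, mirroring
the distinction between attempted and "successfully calculated"
structures. Failed runs are recorded with their seed and reason, never
silently dropped.

**Minimization and selection.** Each converged structure receives exactly
200 steepest-descent steps followed by 10 conjugate-gradient steps on the
same penalty (restraints + soft-sphere), with per-atom displacement
capped at 0.02 A per step and uphill moves rejected, so the energy is
non-increasing by construction. An ensemble run generates n structures
(run i seeded base+i; the default protocol uses n=97) and keeps the k
lowest energies (default 21), ties broken by generation order.

The final physical force-field minimization of the original workflow is
replaced here by the same-count steepest-descent/conjugate-gradient
schedule on the restraint penalty: the package deliberately contains no
force field, so its energies are pure restraint-violation scores.

## Synthetic data: what it shows and what it does not

The generators are pure functions of (inputs, seed). Titrations follow
the depletion mass balance exactly plus additive Gaussian shift noise
(default 0.002 ppm); NOESY intensities are exact r^-6 with relative
Gaussian noise (default 2%); plates are exact logistic curves plus
additive noise (default ~1% of range). Default conditions are the study
conditions: P = 55 uM, true K_D = 60 uM, six-point ratios
{0, 0.5, 1, 1.5, 2, 5}:1 (five ratios are stated for the titration; the
sixth point is this package's choice, placed at 2:1 to sample the
approach to saturation), competition inflection 63 uM, direct-binding
inflection 2 uM, 5 A NOE cutoff.

Passing tests therefore demonstrate *internal consistency*: the fitters
invert the generators, the structure engine recovers a helix from its own
NOE set, classification recovers a planted epitope. They do not
demonstrate robustness to what the generators omit: spin diffusion at
long mixing times, exchange broadening, peak overlap beyond simple
crowding, baseline drift in plates, or protein-side flexibility. The
ideal-helix builder uses fixed backbone geometry and staggered rotamers
chosen deterministically to minimize clashes; it is a ground-truth
generator for recovery tests, not a conformer search.

## Numerical conventions and degenerate inputs

- Energies and violations are in A^2 and A; shifts in ppm; concentrations
  in molar throughout the library (CLI summaries print uM).
- Residue numbering is preserved from input (62-73 for the reference
  peptide), never renumbered.
- Fewer than `dimensions` positive Gram eigenvalues at embedding issues a
  degenerate-geometry warning and pads with zeros.
- sigma over fewer than two assigned residues, empty titrations, plates
  with fewer than five distinct concentrations, uniform CSP profiles in
  pose scoring, and all-failed ensembles are errors, not silent results.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the full pipeline is bit-reproducible for a
  fixed seed (this is under test).

## Known limitations

- The restraint class bounds and pseudoatom corrections are conventions;
  deposited per-restraint bounds, where available, can be imported
  through the three-number `assign` reader instead.
- The tracker transfers assignments by proximity only; it will flag, not
  resolve, genuinely swapped or overlapped peaks.
- Rank correlation in pose scoring needs at least three residues with
  both a CSP value and coordinates, and variance in both.
- The DG engine targets short peptides (tens of residues); the dense
  bounds matrices scale as O(N^2) memory and O(N^3) smoothing time.
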