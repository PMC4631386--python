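# shiftfold

Tools for mapping where a short peptide binds on a protein by NMR
chemical-shift perturbation, quantifying the interaction, and solving the
bound conformation of the peptide from transferred-NOE distance
restraints. The package grew out of a study of the calmodulin-binding
region of cFLIP DED1, whose R4 peptide (residues 62-73, VRRFDLLKRILK)
binds calcium-loaded calmodulin in the canonical wrap-around mode, but
every stage works on any assigned peak lists, plate tables, NOE
intensity tables and peptide sequences in the supported text formats.

It is aimed at structural-biology groups who have HSQC titrations, plate
assays and a transferred NOESY in hand and want a scripted, reproducible
path from those measurements to an epitope map, a K_D/IC50, and a
restraint-consistent structural ensemble - plus a synthetic-data module
that makes the whole chain testable without any experimental input.

## The models at the core

**CSP mapping.** Per-residue perturbation
`d = sqrt((ΔδH² + (α·ΔδN)²)/2)` with α = 0.14 (0.20 for Gly); the epitope
is read from the residues with `d > 2σ` and `d > σ`, σ being the standard
deviation of the assigned `d` set.

**Fast-exchange K_D.** Observed shifts are population-weighted averages,
`δ_obs = δ_free + f_bound·Δδ_bound`, with the bound fraction from the
exact single-site mass balance with ligand depletion
`f = ((P+L+K_D) − sqrt((P+L+K_D)² − 4PL))/(2P)`; one global K_D is fitted
across residues with per-residue amplitudes profiled out.

**Dose response.** Four-parameter logistic
`y = m1 + (m2−m1)/(1+(x/m3)^m4)`; `m3` is K_D (direct binding) or IC50
(competition).

**Transferred-NOE restraints.** `I ∝ r⁻⁶`, calibrated against a geminal
CH₂ pair at 1.78 Å, binned into 2.7/3.5/5.0 Å upper-bound classes over a
1.8 Å floor.

**Distance geometry.** Holonomic + experimental bounds → triangle
smoothing → random (partial) metrization → metric-matrix embedding in
four dimensions → annealed penalty refinement with chirality enforcement
→ 200 steepest-descent + 10 conjugate-gradient steps (0.02 Å cap) →
generate 97, keep the 21 lowest-energy structures.

See `docs/methods.md` for assumptions, parameter defaults and numerical
conventions.

## Worked example

Generate a complete synthetic data set at the default study conditions
(55 µM protein, true K_D 60 µM, six-point titration, 63 µM competition
IC50), then run the analysis stages:

```sh
shiftfold simulate --seed 1 --outdir sim
shiftfold fitkd sim/peaks_ratio*.tsv --protein-conc 55e-6 --noise-floor 0.002
```

```text
Fast-exchange titration fit
===========================
residues fitted      113
ratios               0, 0.5, 1, 1.5, 2, 5
P (protein)          55.0 uM
K_D                  60.27 uM
95% CI               [59.49, 61.05] uM
residual rms         0.00176 ppm
converged            True
```

113 of 118 simulated residues could be followed unambiguously through
the titration; the fitted K_D recovers the planted 60 µM within its
confidence interval, and the residual rms matches the simulated 0.002 ppm
shift noise.

```sh
shiftfold fit4pl sim/plate_competition.tsv --competition
```

```text
Four-parameter logistic fit
===========================
curve                descending (competition)
m1 (plateau, x=inf)  105.8 +- 2.8
m2 (baseline, x=0)   998.4 +- 3.4
m3 (inflection)      6.146e-05 M +- 7.6e-07
m4 (Hill slope)      1.552 +- 0.027
residual rms         8.059
converged            True
IC50: 61.46 uM
```

The displacement curve falls from ~1000 to ~100 signal units and the
fitted inflection recovers the planted 63 µM IC50 within ~2.5% under 1%
plate noise.

```sh
shiftfold calibrate            # -> 1.78   (geminal CH2 reference, A)
shiftfold fold --restraints sim/restraints.tbl --seq sim/peptide.fasta \
          --n 97 --keep 21 --seed 7 --out ensemble.pdb
shiftfold validate --ensemble ensemble.pdb --restraints sim/restraints.tbl \
          --seq sim/peptide.fasta
```

`fold` runs 97 seeded distance-geometry calculations on the 921 restraints
derived from the simulated NOESY and writes the 21 lowest-energy
conformers as a multi-MODEL PDB with a per-conformer energy table;
`validate` reports restraint-violation statistics and the ensemble's
backbone precision.

The same functionality is available as a library, with
statsmodels-style model objects for the fitting stages:

```python
from shiftfold import FastExchangeTitration, track_peaks, read_peak_table

tables = [read_peak_table(p) for p in sorted(paths)]
tracked = track_peaks(tables)
result = FastExchangeTitration(tracked.unambiguous(), 55e-6,
                               tracked.ratios).fit(noise_floor=0.002)
print(result.summary())
```

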