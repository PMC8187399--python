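# confobs

Analysis pipeline for peptide–fatty-acid complexes of the HAMLET family:
conformational-ensemble statistics for a helix/coil peptide with a bound
oleate-like ligand, the solution observables that characterise the complex
(PFG-NMR diffusion, CPMG relaxation, SE-HPLC, CD), the replica-exchange
temperature ladder used to sample such ensembles, and the power-based
sample-size computation for the associated clinical endpoint.

It is written for structural/biophysical researchers who want each of these
computations as a small, tested library function rather than as steps buried
in an MD or spectrometer vendor toolchain. Every stochastic analysis can be
exercised end-to-end on synthetic inputs with known ground truth.

## What it computes

- **Replica ladders** (`confobs.remd`) — geometric temperature progressions
  T_i = T_min (T_max/T_min)^(i/(n−1)) and solute-tempering scaling factors
  λ_i = T_ref/T_i.
- **Dihedral PCA and free-energy surfaces** (`confobs.dpca`) — backbone φ/ψ
  series, PCA on their (cos, sin) embedding, and the binned Boltzmann
  inversion F_i = −RT ln(P_i/P_o) over PC1/PC2 with watershed basin
  detection.
- **Ensemble metrics** (`confobs.metrics`) — pairwise superposition RMSD,
  GROMOS neighbour-count clustering, a φ/ψ-region secondary-structure
  classifier with the 3₁₀/α/π → helix grouping (also applicable to external
  DSSP label streams), and peptide–ligand contact probabilities at a
  0.55 nm minimum-distance cutoff.
- **NMR and chromatography observables** (`confobs.nmr`) — Stejskal–Tanner
  fits I(g) = I₀ Σ f_j exp(−D_j σγ²g²δ²(Δ−δ/3)) with one or two components,
  hydrodynamic radii by internal dioxane referencing
  R_H = 2.12 Å · D_dioxane/D_solute, monoexponential CPMG T₂ fits,
  peak-area stoichiometry, log-linear SE-HPLC calibration, and mean residue
  ellipticity [θ] = θ·MRW/(10·l·c).
- **Trial design** (`confobs.trial`) — exact noncentral-t power of the
  paired t-test and the minimal sample size reaching a target power.
- **Synthetic data** (`confobs.synthetic`) — two-state helix/coil ensembles
  with a ligand at a tunable contact fraction, PFG/CPMG decays and peak
  tables, all with recorded ground truth.

## Worked example

```python
import numpy as np
from confobs import synthetic, dpca, metrics, nmr, remd, trial

# replica ladder for an effective 300-800 K range
ladder = remd.geometric_ladder(300, 800, 20)
print(ladder.rounded_temperatures()[:3])   # [300.    315.893 332.629]

# two-state ensemble -> dPCA -> free-energy surface -> basins
spec = synthetic.EnsembleSpec(n_residues=10, n_frames=2000,
                              helix_fraction=0.5, contact_fraction=0.5,
                              seed=2024)
traj = synthetic.gen_conformer_ensemble(spec)
series = dpca.dihedral_timeseries(traj)
model, proj = dpca.fit_dpca(series)
grid = dpca.build_fes(proj, bins=32, temperature=300.0)
basins = dpca.locate_basins(grid, depth_cutoff=100.0)
print(len(basins))                          # 4 (two dominant: helix, coil)

# contacts against the generator's truth
prof = metrics.contact_probability(traj, cutoff_nm=0.55)
print(round(prof.any_contact, 3))           # 0.514

# hydrodynamic radii from measured D pairs (1e-10 m^2/s instrument scale)
print(nmr.round_rh(nmr.hydrodynamic_radius(2.162, 14.10)))   # 13.83 A
print(nmr.round_rh(nmr.hydrodynamic_radius(0.986, 13.61)))   # 29.3 A

# sample size for the paired cell-shedding endpoint
design = trial.TrialDesign(mean=41.3, sd=60.4, alpha=0.05, power=0.90, tails=1)
print(trial.minimal_n(design))              # 20
```

The first two radii are the naked peptide and the peptide–oleate complex:
the threefold drop in solute diffusion relative to the shared dioxane
reference translates into a radius growing from ~14 Å (disordered monomer)
to ~29 Å (oligomeric complex). The sample size of 20 is what lifts the
normal-approximation answer (~19) once the exact t-distribution tails are
used.

The same steps are packaged as narrative drivers:

```
python analysis/01_remd_ladder.py
python analysis/02_ensemble_analysis.py
python analysis/03_nmr_observables.py
python analysis/04_trial_power.py
```

each of which prints its findings and writes tables under `results/`.

There is also a CLI covering every operation (`confobs --help`;
subcommands `simulate`, `ladder`, `dpca`, `fes`, `basins`, `cluster`,
`ss`, `contacts`, `dosy`, `t2`, `rh`, `stoich`, `sehplc`, `mre`, `power`,
`samplesize`).

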