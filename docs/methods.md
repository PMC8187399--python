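# Methods

This note documents the models, conventions and numerical choices behind
`confobs`, and what its synthetic-data tests do and do not establish
about real data.

## Synthetic two-state ensembles

The conformer generator emulates the *statistical* structure of a
helix/coil peptide ensemble with a bound fatty-acid-like ligand, not its
energetics. Each frame is assigned a single state by one
Bernoulli(helix_fraction) draw: in a helix frame every residue's (φ, ψ)
is drawn from a von Mises mode centred on (−60°, −45°) (concentration
κ, default 100, ≈ 6° circular SD), rejection-truncated to the helical
classifier window; in a coil frame angles are uniform over an
extended-region box (φ ∈ [−180°, −105°], ψ ∈ [90°, 175°]) disjoint from
that window. Two consequences are intentional:

- the ensemble has exactly two conformational modes, so dPCA/FES/cluster
  analyses have unambiguous ground-truth frame labels;
- the per-residue helical propensity is an exact Bernoulli estimate of
  helix_fraction (coil draws can never be classified H), so propensity
  recovery is a clean binomial test.

A per-frame state (rather than independent per-residue draws) was chosen
because the downstream analyses are only testable against frame-level
labels; the marginal per-residue statistics are identical.

Coordinates are built from the sampled dihedrals by natural-extension
(NeRF) chain construction with fixed ideal geometry (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, trans peptide bonds) and the whole side chain
reduced to one pseudo-proton 2 Å off CA. That is sufficient for RMSD,
clustering and contact statistics at desk scale; it does not reproduce
sterics, side-chain rotamers or realistic compactness.

Ligand "molecules" are single pseudo-protons. In a contact frame
(probability contact_fraction) they are placed 3.0–5.0 Å from one
randomly chosen side-chain proton, guaranteeing a minimum distance below
the 5.5 Å contact cutoff; otherwise they are placed at least 15 Å from
every peptide atom, guaranteeing a clear non-contact. Coordinate noise
(additive Gaussian, default 0) must stay well below the 0.5 Å placement
margin for the labels to remain exact.

Decay generators use multiplicative Gaussian noise (intensity errors on
spectrometers scale with signal), and all randomness flows through one
`numpy` Generator seeded explicitly; identical seeds give bit-identical
outputs.

What passing tests therefore show: the estimators recover known
parameters under the assumed noise models at the stated sample sizes.
What they do not show: robustness to force-field bias, solvent effects,
spectral overlap, baseline drift, or any feature of real trajectories
and spectra the generators do not model.

## Replica ladders

`geometric_ladder` places n temperatures at constant ratio between
T_min and T_max; full precision is kept internally and values are
rounded to 3 decimals only at the interface. Scaling factors follow the
standard solute-tempering convention λ_i = T_ref/T_i (reference rung
λ = 1, λ strictly decreasing). The exact functional form used by any
particular H-REMD engine (e.g. separate exponents for charge vs
Lennard-Jones scaling) is engine-specific; only the temperature list is
treated as a checkable quantity. Exchange acceptance rates are a
property of real runs and are out of scope.

## Dihedral PCA and free-energy surfaces

φ/ψ are computed for internal residues by the standard four-atom torsion
with the IUPAC sign convention (cross-checked against an independent
atan2 oracle and `mdtraj.compute_dihedrals`). Angles are embedded as
(cos θ, sin θ) before PCA — the standard dPCA transform, which removes
the ±180° wrap discontinuity — and the plain (unweighted) covariance is
eigendecomposed with `numpy.linalg.eigh`. Constant angle columns yield
zero eigenvalues rather than errors.

The FES uses F_i = −RT ln(P_i/P_o) with R = 0.0083145 kJ/(mol·K),
T = 300 K by default, on a 64×64 histogram spanning the data extrema
(both configurable). The reference bin is the most populated one, ties
broken by lowest flat index; empty bins are masked rather than capped so
the invariants F ≥ 0 and F(modal bin) = 0 hold exactly and F is
invariant under rescaling all counts.

Basins are found by an ascending-F watershed: bins are visited in
increasing F (ties by flat index); a bin with no visited 4-neighbour
seeds a candidate basin; otherwise it joins the deepest adjacent basin,
and shallower adjacent basins whose minimum lies within `depth_cutoff`
of the meeting level are merged into it (persistence criterion —
this is what keeps count-quantisation plateaus from fragmenting one
physical minimum into many). Membership is capped at min F +
depth_cutoff, so depth 0 reduces basins to their minimum bins, and basin
count is non-increasing in the cutoff. Disconnected islands of occupied
bins (isolated outlier frames) remain separate basins by construction;
on sparse grids a handful of one-frame satellite basins alongside the
dominant ones is expected behaviour, not an error. The default depth
cutoff is 2 kJ/mol (≈ RT at 300 K). Representatives are the RMSD medoid
of a basin's frames when coordinates are supplied, else the first frame
in the minimum bin.

## Clustering, secondary structure, contacts

Pairwise RMSD superposes every frame pair on the selected atoms
(backbone N/CA/C by default) by Kabsch/SVD before computing RMSD; the
implementation is validated against an independent quaternion
(Horn-method) oracle. GROMOS clustering is the neighbour-counting
scheme: the frame with most neighbours within the RMSD cutoff becomes a
centre, it and its neighbours are removed as one cluster, and the
procedure repeats; ties go to the lowest frame index and final ids are
ordered by decreasing size. The cutoff is configurable (default 0.2 nm;
no universally correct value exists — it sets the granularity of the
partition).

The secondary-structure classifier assigns H for (φ, ψ) in
[−100°, −30°] × [−80°, −5°], E for φ ∈ [−180°, −90°] with ψ in
[90°, 180°] or [−180°, −170°], else O. This replaces a hydrogen-bond
(DSSP) assignment, which is meaningless on the reduced synthetic
geometry; `group_ss_labels` applies the identical 3₁₀/α/π → H,
sheet/bridge → E grouping to externally computed DSSP letter streams so
real assignments aggregate into the same propensity statistics.

Contacts use the minimum distance between a residue's selected atoms
(side-chain protons by default) and any ligand atom, with a *strict*
inequality at the 0.55 nm cutoff. Besides per-residue probabilities,
the any-residue contact rate is reported; for the synthetic generator it
estimates contact_fraction exactly.

## NMR observables

Stejskal–Tanner fits use the kernel k(g) = σγ²g²δ²(Δ−δ/3) with γ the
proton gyromagnetic ratio and σ = (2/π)² the half-sine gradient shape
factor (both configurable). The shape factor and gradient calibration
cancel in every derived quantity the pipeline reports, because
hydrodynamic radii are the Stokes–Einstein *ratio* to the internal
1,4-dioxane reference (R_H = 2.12 Å) measured in the same run; measured
D values on the instrument's 10⁻¹⁰ m²/s scale can be used directly.
Radii are rounded at the interface to 2 decimals up to 20 Å and 1 above,
matching common reporting practice; full precision is retained
internally.

Fits are multi-start nonlinear least squares in log-D (three log-spaced
starts seeded from the log-linear slope). The two-component fit adds a
peeling start (slow D from the tail slope, fast D from the early
residual) and reports components ordered by decreasing D with a
logistic-parameterised fraction. A conditioning flag marks decays whose
gradient ramp spans at least one 1/e attenuation of the slowest fitted
component. For a 90/10 mixture with tenfold D contrast at 1%
multiplicative noise, the minor component's D has ≈ 10% statistical
scatter on a 60-point logarithmic ramp — an information limit of the
data, not of the optimiser (the noiseless fit recovers both components
to 10⁻⁶) — so tests bound the minor component by its Monte-Carlo
precision rather than by the dominant component's 5%.

CPMG T₂ is a monoexponential least-squares fit; constant decays raise a
fit error (T₂ unbounded) instead of returning a number. R₂ is reported
as exactly 1/T₂.

Stoichiometry divides each well-resolved region's integrated area by its
protons-per-molecule and averages the ligand/peptide ratio over all
region pairs. SE-HPLC calibration fits log₁₀(R_H) linearly against
elution volume on ≥ 3 standards; predictions outside the standards'
volume span, and in any case past 3.8 mL where column linearity is lost,
are flagged as extrapolations rather than refused. Mean residue
ellipticity uses the mg/mL convention, [θ] = θ(mdeg)·MRW/(10·l·c); the
molar-concentration convention maps onto it via c(mg/mL) =
c(mol/L)·MW/1000.

## Trial design

The paired design is treated as a one-sample t-test on within-patient
changes, one-tailed per the protocol (H₀: mean change 0, H_A: > 0).
Power is the exact noncentral-t tail probability, and `minimal_n` scans
upward from n = 2; the normal approximation
((z₁₋α + z_power)/d)² is exposed as a lower-bound sanity check. The
exactness matters: for d = 41.3/60.4 the approximation gives ≈ 18.3
while the t correction yields 20. No dropout or continuity adjustment is
applied.

## Problem sizes

Defaults throughout are chosen for statistically meaningful desk-scale
runs: 2000-frame ensembles for contact/propensity recovery (binomial SE
≈ 1%), 200-frame subsamples for O(n²) RMSD clustering, 60-point gradient
ramps and 15 logarithmic CPMG delays matching standard acquisition
practice, and 200-seed repeats for parameter-recovery statistics. The
8 µs aggregate-sampling bookkeeping (20 replicas × 400 ns) is recorded
as arithmetic; nothing at desk scale reproduces the sampling itself, so
the ensemble-level claims of any real campaign are covered here only by
the property suite on synthetic ensembles.

## Known limitations

- The synthetic geometry has no sterics or side chains; RMSD scales and
  cluster structures are not comparable to real peptides in magnitude.
- The dihedral secondary-structure classifier is a proxy, not DSSP; on
  real trajectories use DSSP labels with `group_ss_labels`.
- Only discrete 1- and 2-component diffusion fits are provided (no
  continuous D distributions / Laplace inversion).
- Basin labels depend on bin count and depth cutoff; annotation of
  specific minima is left to the analyst.
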