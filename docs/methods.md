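# Methods

## Forward model and units

The pseudocontact shift of a nucleus at metal→nucleus vector **r** is

δ_PC = 1/(12π r³)·[Δχ_ax(3cos²θ−1) + (3/2)Δχ_rh sin²θ cos2Ω],

with (r, θ, Ω) polar coordinates in the principal axis frame (PAF) of the
traceless symmetric anisotropy tensor **Δχ**. One unit convention is fixed
package-wide: Δχ in 10⁻³² m³, distances in Å, shifts in ppm. Dimensional
bookkeeping gives the composite prefactor 10⁴/(12π): 10⁻³² m³/(10⁻¹⁰ m)³ =
10⁻², times 10⁶ for ppm. Two equivalent code paths exist — the polar form
above and the Cartesian form δ = (10⁴/(12π))·3(r̂ᵀχr̂)/r³ over the five
independent components (χxx, χyy, χxy, χxz, χyz; χzz = −χxx−χyy) — and the
test suite holds them to 1e-12 ppm of each other. A 0.1 Å guard radius
around the metal rejects evaluations where the point-dipole model diverges.

Principal-frame reporting orders eigenvalues |χzz| ≥ |χyy| ≥ |χxx|, so
Δχ_ax = (3/2)χzz and Δχ_rh = χxx − χyy. No |Δχ_rh| ≤ (2/3)Δχ_ax clamp is
applied: fitting happens in unconstrained component space and negative
rhombicity with positive axiality is reported as obtained. A caveat
documented here because it shows up in real output: when |Δχ_rh| approaches
(2/3)|Δχ_ax| the magnitudes |χzz| and |χyy| nearly tie, the z-label of the
PAF becomes unstable, and (Δχ_ax, Δχ_rh) can flip to an equivalent
parameterization of essentially the same tensor. Convergence checks and
tensor comparisons therefore operate in component space, which is
label-free; the PAF-rotation convergence criterion is skipped when the
magnitude gap is under 5 %. Euler angles are ZYZ, active, degrees.

## Dataset construction

PCS observations are shift differences between a paramagnetic sample and a
diamagnetic reference, one entry per (residue number, atom name) key present
in **both** tables. Keys present in only one table are dropped and logged,
never penalized: near the metal, paramagnetic relaxation enhancement (PRE)
broadens peaks beyond detection, so absence carries no usable sign.
Matching ignores the residue name (cosmetic naming differences between
independently assigned samples are common); a mismatch at a matched key
warns. Pairing tables from different solvents (H₂O vs D₂O) is refused by
default — the tensor itself is solvent-dependent when the ion stays
partially hydrated — and allowed only with an explicit override plus
warning. An exchangeable-proton filter (H1, H3, H21/H22, H41/H42, H61/H62)
supports D₂O datasets. NMR-STAR v3 chemical-shift loops are read by a
minimal in-package parser covering the `_Atom_chem_shift` tags a shift
table needs; TSV tables require a header with residue_number, residue_name,
atom_name, shift (optional sigma, default 0.02 ppm).

NOE volume calibration assigns the conventional classes strong
(1.8–3.0 Å), medium (2.0–4.0 Å), weak (2.2–5.0 Å). The volume cutoffs —
strong at V ≥ 0.5·V_ref, medium at 0.1·V_ref — bracket the ~2.4 Å reference
distance (cytidine H5–H6, sugar H2'–H2'') on an r⁻⁶ scale; they are
parameters, not measurements.

## Tensor and position fitting

At fixed site the model is linear in the five tensor components; the fit is
weighted linear least squares (uniform by default, inverse-variance
optional), with a rank check that names the null-space dimension when the
observed atoms are degenerate (e.g. collinear). The joint fit of several
datasets sharing one site nests an exact per-dataset linear solve inside an
outer search over the three site coordinates: a coarse grid (default 2 Å
spacing over the structure's bounding box inflated by 10 Å — the r⁻³ basins
are narrow, so grid-first avoids local minima) followed by Nelder-Mead from
the best node (1e-4 Å coordinate tolerance). Observations within 5 Å of a
candidate site are down-weighted ×0.1: the closest nuclei carry the most
leverage and the most unmodeled physics (contact shifts, local dynamics).
Ambiguous diastereotopic pairs, when flagged, are assigned within-pair by
the permutation minimizing the pair's residual sum, re-evaluated each outer
iteration. After a joint fit, cheap per-dataset refits near the joint site
flag inconsistency (joint Q more than twice the separate Q) — the signature
of datasets that do not actually share a site.

Q = √(Σ(obs−calc)²/Σobs²), no mean-centering. Cross-validation refits on
training folds (leave-one-out or k-fold) and reports Q_work/Q_free; a
holdout-nucleus mode excludes a whole nucleus type (e.g. ³¹P) from training
entirely, the protocol used to validate a structure against data that never
entered refinement. Parameter uncertainties come from a parametric
bootstrap (Gaussian resampling of the back-calculated PCS at the stated
sigma, full refit per replicate) and are labeled as such.

## Refinement

The restraint energy is a flat-bottom quadratic per observation,
E = k·max(0, |δcalc−δobs|−tol)², summed over datasets that share one metal
site — multi-dataset additivity is exact and tested. Gradients with
respect to nuclear coordinates and the site are analytic
(∇δ = s·3(2χr/r⁵ − 5(rᵀχr)r/r⁷)) and verified against central finite
differences at 1e-6 relative. Defaults: tolerance 0.05 ppm, force constant
1.0 energy·ppm⁻² — both configurable; no experimental consensus exists for
either.

In place of a molecular-dynamics force field the package uses a harmonic
geometry template: distance terms extracted from a reference conformer,
optionally restricted to intra-block (per-helix) pairs so that local
geometry is maintained while inter-helix orientation stays free — the
template is a stand-in sufficient for verifying the restraint machinery,
declared openly, not a force field. Cartesian minimization is adaptive
steepest descent with backtracking (energy trace monotone by construction).
Because the soft degrees of freedom of a junction are rigid-body helix
placements that per-atom descent moves only very slowly, a rigid-block
stage optimizes 6 DOF per mobile block; in its strongest form the tensors
are profiled out (variable projection: exact linear re-solve at every trial
placement, site coordinates co-optimized), making the outer objective the
fully minimized PCS misfit — with self-consistent data its global minimum
is the true placement, avoiding the slow zigzag of alternating full tensor
fits with fixed-tensor minimization.

The iterative protocol alternates (a) site+tensor fitting on current
coordinates with (b) restrained minimization at fixed tensors (rigid stage
first when blocks are declared, tensors re-solved after blocks move), and
declares convergence when between consecutive rounds the tensor components
change < 1 %, the PAF rotates < 2° (skipped near the rhombicity boundary),
the site moves < 0.1 Å and coordinates move < 0.05 Å RMSD — thresholds
chosen tighter than typical fitted-parameter uncertainties. Three
consecutive objective increases abort with the trace. Bundle selection
ranks candidates by geometry + PCS energy; bundle size is a parameter.

Ensemble analytics: all-pairs Kabsch superposition (SVD with reflection
guard) for mean pairwise RMSD; metal spread as the rms scatter of
superposed site positions about their mean; helix axes as the principal
direction of base-pair C1'-midpoint series (≥ 3 pairs), oriented 5'→3'
along the first strand, with interhelical angles in [0°, 180°]. The
C1'-midpoint axis definition was chosen because it is robust and available
for reduced-atom synthetic structures; published angle conventions vary and
none is canonical.

## Synthetic data

The generators emulate the statistical structure of a lanthanide-binding
three-helix-junction study. Idealized duplexes are built by helical
symmetry (B-form defaults: rise 3.38 Å, twist 36°) from a reduced
per-nucleotide template (P, C1', a base-nitrogen proxy, 2–4 proton sites);
PCS depends only on positions, so nucleotide chemistry is unnecessary.
Paired C1' atoms are antipodal, putting base-pair midpoints exactly on the
axis. Junctions place additional helices at requested inter-axis angles
around a junction point with a clash check; the construction angle is
recorded as ground truth. Planted datasets evaluate the forward model at
every proton-like atom, add Gaussian noise, remove atoms inside a PRE blind
radius, and drop a further random fraction — defaults 0.02 ppm, 7 Å, 20 %,
the regime of a well-behaved experimental PCS set with substantial
PRE-driven peak loss. The four default tensors span axialities −3.88 to
+1.42 with mixed-sign rhombicities (10⁻³² m³) and four distinct PAF
orientations — the magnitude range measured for lanthanides in a partially
hydrated DNA site, deliberately an order of magnitude below protein-tag
tensors. All randomness flows through one explicitly seeded generator.

What the generators do **not** emulate: sequence-dependent geometry, sugar
puckers and groove widths, contact-shift contributions near the metal,
anisotropic PRE, conformational averaging of the tensor, and assignment
errors. Passing tests therefore demonstrate the correctness of the
estimators and refinement machinery under the stated noise model, not
robustness to every pathology of real spectra.

## Problem sizes and numerical choices

The synthetic study uses 6 bp per helix (120 atoms, ~35–48 observations per
metal after censoring), 20 replicates for the paired with/without-PCS
comparison, 100 bootstrap replicates for uncertainties, and 100 seeds for
the Kd-recovery study — sizes at which every property under test is already
well resolved while the full suite runs in minutes on one CPU. Degenerate
inputs are first-class errors: empty datasets after censoring, rank-deficient
geometry, all-zero observations (undefined Q), folds below five training
observations, non-positive volumes/sigmas, lattice counts below 2, clashing
helices. Ties and sign conventions: eigen-ordering by magnitude with a
right-handed frame; Kabsch reflection corrected via the determinant;
axis-angle rotations are exact (no small-angle approximation).

## The binding and RDC side computations

The 1:1 equilibrium is solved in closed form with the cancellation-free
root [LM] = 2LM/(b + √(b²−4LM)), b = L+M+Kd, verified against bisection.
Titration fitting models the observable as linear in the bound fraction of
the **ligand** (the spectroscopic signal reports on the oligonucleotide's
conformation, not the metal's), with Kd, free and bound signals as
parameters and a saturation diagnostic that warns when the smallest
titration point already leaves the ligand > 95 % bound. Self-alignment RDC:
D = −(B0²/15kT)·(γaγbħ/8π²r³)·[Δχax(3cos²θ−1)+(3/2)Δχrh sin²θcos2Ω]; the
maximum magnitude is attained on a principal axis (factor values 2Δχax,
−Δχax±(3/2)Δχrh), verified against a dense angular grid. Constants are
CODATA 2018; temperature defaults to 298 K. The spin pair for any quoted
coupling must be given explicitly — a geminal ¹H–¹H pair at 1.8 Å is the
natural upper-bound choice in a DNA context.

## Known limitations

- The geometry template is not a force field: no electrostatics, no
  excluded volume beyond the template pairs, no solvent. Refined structures
  verify restraint handling, not nucleic-acid stereochemistry.
- Contact shifts and residual anisotropic chemical shifts are outside the
  forward model; the 5 Å down-weighting is a guard, not a correction.
- The rigid-block profile refinement assumes block decomposition is known;
  it is, for synthetic junctions, and is a user decision for real systems.
- Bootstrap uncertainties assume the stated noise sigma; misspecified sigma
  scales them accordingly.
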