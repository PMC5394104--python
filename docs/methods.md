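# Methods

This note documents the models, conventions and numerical choices behind
`groovedyn`, and what the synthetic-data generators do and do not
emulate.

## Units and indexing

Coordinates are stored in Å, times in ns, masses in u; conversions
happen only at I/O boundaries (XTC nm→Å and ps→ns; forces reported in pN
via 1 kJ·mol⁻¹·Å⁻¹ = 16.6054 pN, with the constant isolated and
unit-tested).  Atom and residue indices are 0-based internally; the
author-assigned PDB residue number is preserved so outputs can name
residues the way structural biologists do ("Y85", "T138").  Charges and
Lennard-Jones parameters come from a separate CSV parameter table
(chain, residue number, atom name, charge, σ, ε), since PDB files carry
none.

## Superposition and deviation analyses

Rigid-body fits use the Kabsch algorithm via SVD with the reflection
branch corrected (det R = +1).  Fit weights are equal by default —
common practice for Cα fits — and configurable.  Collinear fit points
make the rotation about the line unconstrained; this is detected from
the singular values of the cross-covariance and rejected.

The fit selection and the measurement selection are decoupled: measuring
peptide dissociation requires a receptor-frame fit (default: groove
scaffold Cα), since fitting on the peptide itself would remove the very
motion being measured.  Per-residue RMSD is computed per frame against
the starting structure; for single-atom (Cα) residue groups it is that
atom's displacement.  Ties at exactly the dissociation threshold
(default 3 Å) count as bound.  Mean RMSD averages over frames within
each replica, then over replicas with equal weight; bound fractions pool
all retained frames.

Replica exclusion: a replica is dropped from **all** analyses when both
terminal residues exceed the threshold continuously from some time until
the trajectory end for at least the persistence window (default 10 ns in
MD units; the analysis drivers use 0.01 ns because the toy-groove runs
span only ~0.16 ns).

Equilibration discard drops frames with time < t_equil (default 10 ns)
before any averaging.

## Groove widths and block-averaged errors

Widths are Euclidean distances between named Cα pairs; no superposition
is needed (distances are rigid-motion invariant, and a test asserts
this).  Statistics pool frames across retained replicas for mean and SD;
the SEM is block-averaged per replica and combined as √(Σ semᵣ²)/R.
Whether SD should be over pooled frames or replica means is genuinely
open; pooled frames is used and recorded in the table metadata.

The block-averaging plateau is realised as the maximum of
SEM(b) = sd(b contiguous block means)/√b over b ∈ {5, 10, 20, 50}
(configurable).  This estimator is deterministic and testable but noisy
on a single series: each SEM(b) is an sd over few block means (relative
sampling error 1/√(2(b−1)), i.e. 35% at b = 5), and the max over the
grid is biased upward by roughly 15%.  Calibration checks against the
i.i.d. CLT value σ/√n and the AR(1) effective-sample-size closed form
√((1+φ)/(1−φ)/n) therefore compare the **median over five independent
series**, which measures the same calibration with the sampling noise of
the check averaged down; a single series would miss a 30% band about one
time in five even for a perfectly calibrated estimator.

## Schlitter entropy

S = ½R Σᵢ ln(1 + αλᵢ) per mole, with α = k_B T e²/ℏ² and λᵢ the
eigenvalues of M^{1/2} C M^{1/2} in SI units.  Constants: CODATA
k_B = 1.380649×10⁻²³ J/K, ℏ = 1.054572×10⁻³⁴ J·s, R = 8.314463
J/(K·mol).  Numerical choices:

* the determinant is evaluated through a symmetric eigendecomposition
  and a sum of log1p terms, not a direct determinant — stable for the
  near-singular covariances that fitted trajectories produce;
* negative round-off eigenvalues are clamped to zero (each contributes
  ln 1 = 0), preserving the upper-bound property;
* the covariance uses the population normalisation (1/F); at F ~ 10⁵
  the distinction from 1/(F−1) is immaterial but the choice is fixed;
* a single-mode oracle is kept as `schlitter_mode_term`; m = 12 u,
  λ = 0.01 Å², T = 300 K gives 7.771 J/(K·mol) and is frozen in a test.

The trajectory must be superposed on the same selection used for C, with
the starting structure as reference.  Residual rigid drift is detected
by comparing the selection centroid averaged over the first and last
deciles of frames (instantaneous centroids would flag plain thermal
noise) and triggers a warning above 0.5 Å.  F ≤ 3N triggers a
rank-deficiency warning.

Per-domain entropies are computed as independent runs on the respective
residue-range selections, each with its own fit.  A global fit would let
inter-domain hinge motion dominate C, so the per-domain fit is the
deliberate choice.  When several replicas contribute, they are
concatenated before the covariance (accumulation over all sampling)
rather than averaged per replica; both modes exist, concatenation is the
default.

**Convergence error.**  |S_full − S_sub| where the subsample removes a
uniformly random 10% of frames with a caller-supplied seed.  Two facts
about this estimator, established empirically and used by the tests:
(1) for a stationary converged ensemble it reads ≈0.35 σ(S), because the
subsample shares 90% of its frames with the full estimate — so it
*underestimates* the seed-to-seed scatter of S (≈1.41 σ(S)) by a factor
of about 2, and null calibrations must test that ratio rather than
expect |ΔS| < error; (2) a *linear* mean drift barely inflates it, since
the sample variance of an evenly-spanned ramp is nearly invariant under
random frame deletion — genuine non-convergence is constructed in tests
as a barely-sampled late transition (mean jumps 3 Å for the last 1% of
frames), whose rare-state weight does fluctuate under frame removal
(measured 18-180× the stationary error).

ΔS between systems uses a conservative summed error; combined errors
below 10 J/(K·mol) are flagged as sub-floor rather than reported as
meaningful.

## Force distribution analysis

The nonbonded model is LJ 6-12 + Coulomb with Lorentz-Berthelot
combination, truncated at 10 Å.  Under force-shift truncation the raw
radial force at the cutoff is subtracted so the force is continuous at
the boundary; potential-shift and plain truncation are available.  Plain
Coulomb (no mesh electrostatics) is a deliberate scope choice: the use
case is inter-chain interfaces where nonbonded terms are the only
contributors, and the validation fixtures are analytic.  Bonded terms
are out of scope.

Averaging order: the per-frame vector sum of atom-atom forces for a
residue pair is averaged over frames **first**, then the norm is taken.
Oscillating forces can therefore cancel; this is intentional, because a
norm-then-average quantity cannot carry a sign.  The sign is the
projection of the mean force on the first residue onto the mean
centre-of-mass separation axis (positive = repulsive); the underlying
convention is one consistent realisation of "attractive and repulsive
distinguished by sign" and is recorded in output metadata.

Neighbour search uses a k-d tree queried slightly beyond the cutoff,
with final inclusion decided by the same Euclidean norm the force kernel
uses, so the pair set matches an O(N²) double loop exactly; scalar and
vector paths share one kernel, making them bit-identical.  Newton's
third law holds exactly at atom level and, by construction of the mean
vectors, at residue level.

Force-difference maps subtract signed values (sign × magnitude) per pair
and drop pairs below a 30 pN floor, mirroring the significance floor
used when visualising residue-pair force changes; the floor is recorded
in metadata.  The interface summary is Σ sign × magnitude over pairs —
more negative means a more attractive interface.

## Synthetic-data generators

All generators take explicit seeds; there is no global random state.

**Gaussian ensemble.**  I.i.d. multivariate-normal frames about a fixed,
well-separated base structure, from either per-coordinate variances or a
full 3N×3N covariance (PSD-checked).  The analytic Schlitter entropy of
the *specified* covariance is returned alongside, giving a closed-form
oracle for the entropy stack.  What it does not emulate: temporal
autocorrelation — every frame is independent, so convergence behaves
like n_frames effective samples, unlike real MD.

**Two-state peptide.**  Per-residue bound/unbound continuous-time Markov
chains sampled exactly at frame boundaries through the 2×2 transition
matrix of the generator (no discretisation bias in dwell times), initial
state drawn from the stationary law, the unbound state displaced 8 Å
along +z over σ = 0.3 Å isotropic noise.  Ground truth: the state
series and the stationary bound fraction k_on/(k_on+k_off).  Default
rates follow the partial-dissociation regime probed in the tests
(k_off = 4 µs⁻¹, k_on = 1 µs⁻¹ → 20% bound).

**Toy groove.**  A coarse one-bead-per-residue fixture: two wall rows
and a floor row (chain M, harmonically restrained), an extended 9-mer
peptide (chain P) with anchor beads at positions 2 and 9.  Each anchor
(charge −0.6 e) pairs with an opposite-charged floor bead; the pocket
bead is raised so the anchor starts at its force equilibrium (solved by
bisection of the radial force), and the flanking floor beads carry a
like charge so the anchor cannot swing around or hop off its single
partner — a caged pocket.  Consecutive peptide beads are joined by
harmonic bonds with rest length 3.75 Å against a 3.8 Å spacing, so the
doubly-anchored chain is slightly taut; this suppresses the soft
buckling mode of the bound control and is what makes the anchor-deletion
contrast detectable at desk scale.  σ = 3 Å, ε = 0.3 kJ/mol for all
beads.

**Langevin propagator.**  Overdamped updates
x ← x + (dt/γ)F + √(2k_BT dt/γ)ξ with γ in kJ·mol⁻¹·ps·Å⁻².  Stability
requires (dt/γ)·k ≪ 1 for the stiffest effective spring; defaults
(dt = 4 fs, γ = 50) keep that product ≤ 0.06 for the toy groove's anchor
pockets (k_eff ≈ 400-700 kJ·mol⁻¹·Å⁻²).  Divergence (any coordinate
beyond 10⁴ Å) raises an instability error suggesting a smaller step.
Default runs are 40 000 steps sampled every 100 — about 30 s for the
ten runs of the five-seed anchor-deletion experiment, chosen so the
free tail of the truncated peptide has time to peel while the whole
battery stays interactive.

What the toy groove shows and what it does not: it reproduces the
*pattern* that deleting the C-terminal anchor destabilises the central
residues (in ≥4 of 5 seeds at the default run length) while the intact
control keeps both anchors far below the 3 Å threshold, and that
removing the anchor charges makes the interface strictly less attractive
on the same frames.  Its walls are harmonically restrained, so it cannot
show groove widening or narrowing — the width machinery is exercised on
the fixture but real width effects require unrestrained receptor
dynamics.  No water, no real force field, no microsecond kinetics;
passing tests on the fixture validates the analysis algebra and the
relative/ordering claims, not force-field fidelity.

## Pipeline

A single YAML config names systems (structure + replica trajectories +
parameter table), the reference system, and the analysis settings; all
defaults (300 K, 10 ns discard, 3 Å threshold, 30 pN floor) are
overridable.  Replica exclusion is applied before any averaging and
logged.  Outputs are a pure function of (config, input files, seed);
every table carries the config hash, seed and package version, and
deterministic stages are byte-identical on rerun.  Comparison tables use
system − reference ordering, with |Δ| columns for RMSF.

## Problem sizes used in tests and drivers

Closed-form entropy agreement uses 20 atoms × 10⁵ frames; RMSF and
convergence checks 3-5 atoms × 10⁵ frames; occupancy and dwell-time
recovery 2×10⁵ frames at 10 ns spacing; force oracles 500 atoms per
frame; the toy groove 45 beads × 40 000 steps × 5 seeds.  These sizes
put each statistical check 3-10× inside its tolerance while keeping the
whole suite a few minutes on one CPU.

## Known limitations

* Entropy: Schlitter only — no Karplus-Kushick, no mutual-information
  expansion, no quantum corrections beyond the formula itself.
* Forces: no PME/Ewald, no bonded terms, no virial/stress; intra-residue
  and adjacent-residue pairs are not excluded automatically unless the
  selections make them disjoint.
* The dissociation analysis classifies per-residue displacement only; it
  does not cluster dissociated conformations or estimate rate constants
  beyond occupancy fractions.
* The fixture trajectory dialect is the only write format; XTC/DCD are
  read-only.
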