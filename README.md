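# groovedyn

Trajectory analysis of peptide-binding-groove dynamics for MHC class I
-like systems: per-residue dissociation analysis, groove-width geometry,
quasi-harmonic configurational entropy, and residue-resolved pairwise
force distribution analysis (FDA), exercised end-to-end on synthetic
trajectories with known ground truth.

## Who this is for

Simulation groups studying how peptide cargo modulates MHC-I plasticity
(peptide editing, tapasin-mediated exchange) accumulate microseconds of
MD and then need a reproducible analysis layer: which peptide residues
detach from the groove, how the groove geometry responds, how much
configurational entropy a domain gains, and which residue-residue forces
change.  `groovedyn` implements that layer as a tested library plus a
set of analysis drivers, with synthetic-data generators so every stage
can be validated against closed forms before touching real MD output.

## The quantities it computes

**Per-residue dissociation.**  Frames are superposed on the receptor
frame (Kabsch fit on Cα atoms), and each peptide residue's Cα RMSD from
the start structure is classified against a dissociation threshold
(default 3 Å; ties count as bound).  Outputs: per-residue mean RMSD,
bound-time fractions, the fraction of frames with both termini bound,
and a replica-exclusion rule for peptides that leave the groove for good.

**Groove widths.**  Distances d₁, d₂, d₃ between named Cα pairs, pooled
over replicas, with the SD over pooled frames and a block-averaged
standard error: SEM(b) = sd(block means)/√b, with the plateau taken as
the maximum over b ∈ {5, 10, 20, 50}.

**Configurational entropy.**  The Schlitter upper bound

    S = ½ k_B ln det(1 + k_B T e² ℏ⁻² M^{1/2} C M^{1/2})

with M the 3N-dimensional diagonal mass matrix and C the positional
covariance of the superposed Cα coordinates (population normalisation).
The determinant is evaluated per mode as Σ ln(1 + αλᵢ) from a symmetric
eigendecomposition.  The convergence error is |S_full − S_subsample|
after discarding a random 10% of the frames.

**Force distribution analysis.**  Nonbonded pairwise atom-atom forces
(Lennard-Jones 6-12 + Coulomb, force-shifted to zero at a 10 Å cutoff)
are recomputed from the coordinates, summed per residue pair, vector
-averaged over time, and reported as F_vw = |Σᵢⱼ ⟨Fᵢⱼ⟩| in piconewton
with an attractive/repulsive sign.  Difference maps between systems
apply a 30 pN significance floor.

## Worked example

Build the synthetic study systems (a coarse-grained groove holding a
9-mer peptide anchored at positions 2 and 9, and its C-terminally
truncated counterpart) and run the dissociation analysis:

```bash
python analysis/01_build_systems.py   # 5 Langevin replicas per system
python analysis/02_dissociation.py
```

prints, among other lines:

```
d1c: replica d1c_rep0.traj fully dissociated -> excluded
d1c: 4 replicas retained; both-termini bound fraction 0.282
full: residues above the 3.0 A threshold: none
d1c: residues above the 3.0 A threshold: ['G8']
per-residue mean RMSD (full vs d1c):
  G2: 0.91 -> 0.88 A
  G5: 1.25 -> 1.83 A
  G8: 1.62 -> 4.47 A
```

Deleting the C-terminal anchor leaves the N-terminal half in place
(G1-G2 unchanged) while the central and C-proximal residues detach —
the RMSD rises monotonically toward the free end and residue G8 crosses
the dissociation threshold.  One truncated replica dissociated entirely
and was excluded from all averages by the persistence rule.  The
remaining drivers compute groove widths (`03`), scaffold entropy with
subsampling errors (`04`) and the residue-pair force maps (`05`); each
writes its table under `results/`.

The same battery is available as a config-driven CLI:

```bash
analyze run config.yaml --out analysis_out
analyze rmsd groove.pdb rep0.traj --fit "chain M and name CA" \
        --measure "chain P and name CA"
```

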