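# Methods

## Model and domain scheme

The subject is the cytoplasmic domain of the KIT receptor tyrosine kinase.
`kitcd.core.kit_domain_scheme()` stores the analysis regions: juxtamembrane
region (547–581), N-lobe (582–693), kinase insert domain KID (694–753),
C-lobe (754–935) and C-terminal tail (936–976), plus the elongated KID
(689–768) as an auxiliary range. The end-to-end reference pair is
(F689, D768); the crystallographic Cα–Cα distance between them in the
autoinhibited kinase domain (PDB 1T45) is 9.9 Å. Residue 936 is shared by
the C-lobe and the C-term ranges as published; `DomainScheme` treats a
single shared boundary residue as an allowed, flagged overlap.

All distance-based analyses use Cα atoms. The source material never names
the atom pair for d; Cα reproduces the printed 9.9 Å and is the universal
analysis selection elsewhere, so it is used throughout.

## Stage 1 — screening

1. **Distance filter**: keep models with |d − 9.9| ≤ 1.0 Å (inclusive).
2. **Clash screen**: reject models with any non-bonded pair (sequence
   separation ≥ 2) closer than 1.5 Å. This replaces the original visual
   inspection for "intramolecular nodes" with a reproducible criterion.
3. **Score ranking**: keep the best `k_top = 26` models by the external
   statistical-potential score (lower is better; ties broken by id).
4. **SS clustering**: pairwise distance = 1 − fraction of identical
   secondary-structure symbols per position; complete-linkage (farthest
   point) agglomeration cut at 4 clusters. Complete linkage is used because
   it bounds the diameter of each cluster — every member pair is at least
   as similar as the merge height.
5. **Representatives**: the medoid (minimum summed distance to its cluster)
   of each cluster.

All stage counts, membership and the merge tree are recorded in the report;
an empty stage raises `EmptyStageError` rather than passing silently.

## Stage 2/3 — trajectory metrics and consensus

Per candidate trajectory (burn-in frames excluded from statistics):

- per-domain RMSD mean/sd (Kabsch fit on the domain itself),
- RMSF mean (iterative average-structure fit, tolerance 1e-6 Å),
- d mean/sd and |d_mean − 9.9|,
- KID radius of gyration mean/sd,
- secondary-structure conservation of the kinase lobes versus the template
  assignment (helix subtypes H/G/I merged before comparison),
- a plateau flag per domain: the OLS slope over the last 25 % of the RMSD
  series is indistinguishable from zero (|slope| < 2 × its standard error).

Candidates are ranked per metric (lower is better for RMSD mean/sd, RMSF,
|d − 9.9| and Rg sd; higher for SS conservation; `rankdata` with
method="min") and aggregated by unweighted rank-sum. Ties in the aggregate
are broken by |d − 9.9|, then id, and are flagged in the output. Equal
weights are the deliberate default: the source analysis treats the metrics
as qualitatively independent lines of evidence, and any weighting would be
an extra free parameter.

## Essential dynamics, DCCM, clustering, change points

- Covariance of fitted Cα coordinates (fit target: converged average
  structure by default), diagonalised with `numpy.linalg.eigh`; eigenvalues
  descending; eigenvector sign fixed so the largest-magnitude component is
  positive. Mode k's per-atom displacement is √λ_k times the eigenvector's
  3-vector block; a porcupine-style two-frame PDB can be exported.
- DCCM: normalised 3-vector fluctuation covariances; zero-fluctuation atoms
  get zero off-diagonals and unit diagonal, and are flagged.
- Conformational clustering: features are fitted Cα coordinates flattened
  per frame; k-means (scikit-learn, k-means++ seeding, best of 10 restarts,
  fixed seed). k is chosen by maximising Calinski–Harabasz; if the
  Davies–Bouldin minimum disagrees, the smaller k wins and the conflict is
  recorded. CH is primary because it is monotone-comparable across k on
  compact well-separated clusters; the smaller-k rule avoids over-splitting.
- Change points: exact dynamic-programming least-squares piecewise-constant
  segmentation (all change counts m ≤ max_changes in one DP pass), model
  selected by a BIC-style penalty 2σ̂²·log n per change, with σ̂ from the
  median absolute first difference / (0.6745·√2) — robust to the jumps
  themselves.

## Secondary structure

A from-scratch Kabsch–Sander implementation: amide hydrogens are
reconstructed 1 Å from N opposite the preceding carbonyl; H-bond energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bonded when
E < −0.5 (pairs under 0.5 Å get the −9.9 clash sentinel; prolines cannot
donate); n-turns, helices (G/H/I), bridges and ladders (B/E), turns (T) and
bends (S, Cα curvature > 70°) with final priority H > E > B > G > I > T > S.
The test suite cross-checks assignments against mdtraj's DSSP on ideal
helices and an optimised antiparallel sheet; mdtraj is an oracle only,
never the implementation.

## Synthetic generators — what they emulate and what they don't

- `generate_bead_protein`: self-avoiding Cα chains (3.8 Å spacing,
  ≥ 3.0 Å non-consecutive separation) with a named domain scheme. No
  excluded-volume realism beyond the floor.
- `generate_gaussian_trajectory`: i.i.d. Gaussian frames with a planted
  low-rank covariance. Planted directions are projected orthogonal to the
  6-dimensional rigid-body subspace of the reference structure — otherwise
  the superposition step absorbs part of the planted variance and recovery
  tests would measure the fit, not the estimator. There is no kinetics:
  frames are uncorrelated in time.
- `generate_transition_trajectory`: linear interpolation between two states
  over a switch window plus isotropic noise; the ramp reaches state B on
  the window's final frame. A statistical stand-in for a conformational
  transition, not dynamics.
- `generate_candidate_ensemble`: planted d ~ Uniform(7, 13) imposed exactly
  by translating the chain tail along the flank axis (this can create
  clashes, which the clash screen legitimately removes — stage counts
  reflect that); SS strings from group templates with 5 % per-position flip
  noise; scores ~ N(−30000, 500).
- Backbone builders (`ideal_helix`, `ideal_strand`,
  `ideal_antiparallel_sheet`, `build_peptide_backbone`): NeRF internal-
  coordinate construction with standard bond geometry. The sheet places the
  second strand by optimising rigid-body parameters against N···O = 2.9 Å
  and H···O = 1.9 Å targets over a small register scan (seeded differential
  evolution + Nelder–Mead polish); this takes ~30 s and is session-cached
  in the tests.

No force field, thermostat or integrator anywhere: synthetic trajectories
validate estimators, not physics.

## Numerical and size choices

- Kabsch rejects < 3 points and degenerate (collinear) configurations;
  reflections corrected by sign flip of the smallest singular direction.
- RMSD100 requires N ≥ 20 (the formula's validity floor).
- Synthetic scales: 40–80 beads, 1 200–5 000 frames — the smallest sizes at
  which the recovery tolerances (PCA cosine > 0.99, eigenvalues within
  10 %, ARI ≥ 0.95, transition within 2 % of series length) hold with
  comfortable margin at generic seeds; minutes of CPU in total.
- Default trajectory time step 1 ps; SS timelines sampled every 10 ps.

## Open / deliberate decisions

- d is a Cα–Cα distance (see above).
- The distance filter band is inclusive at both edges.
- choose_k conflict policy: smaller of the CH/DB optima, recorded.
- The screening clash cutoff (1.5 Å) is intentionally permissive — it
  removes only physically impossible models, mirroring the original
  coarse visual triage.
- No console-script CLI: the numbered `analysis/` drivers are the runnable
  interface.
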