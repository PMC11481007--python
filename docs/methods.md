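# Methods

`pharmfunnel` implements a ligand-based virtual-screening funnel of the
kind used to search natural-product libraries for GPR40 (free fatty acid
receptor 1) agonists: pharmacophore perception and distance-constraint
matching, retrospective active/decoy validation, EC50-thresholded
machine-learning triage, external docking-score ingestion, Tanimoto
novelty filtering, trajectory analytics and MM-GB/PBSA-style energy
bookkeeping.  Every stage can be exercised on synthetic inputs with
known ground truth, so the pipeline's correctness is testable without
proprietary software, an MD engine, or external databases.

## Pharmacophore model and matcher

A model is a set of typed feature points — here three aromatic rings
(R1–R3), one hydrophobic group (Hy1) and one hydrogen-bond acceptor
(A1), mirroring the agonist-site interactions of GPR40 (π-stacking with
Phe87/Tyr91, Phe142 and Trp174; the lipid-facing hydrophobic groove; the
carboxylate engaging Arg183/Tyr2240) — with pairwise Euclidean distance
constraints `d_ij` and a fractional tolerance `τ` per pair.  A molecule
matches when at least `min_required` features (default 4 of 5) can be
assigned injectively to perceived feature points of the same kind such
that every constrained pair among the matched features satisfies
`|r_ij − d_ij| ≤ τ·d_ij`.

Design choices where the published description leaves the design open:

* **Geometry source.** Inter-feature distances are never published for
  this class of model, so a model is constructed from a reference pose
  (`build_model_from_reference`), from an explicit YAML listing of
  `d_ij`, or from the packaged idealized geometry
  (`default_gpr40_model`), an elongated acid-headed agonist arrangement
  spanning ~16 Å from carboxylate to lipophilic tail.
* **Which feature is optional.** The acceptor and hydrophobic features
  are `required` by default and any one aromatic may be dropped; the
  carboxylate contact is the interaction consistently described as
  essential.  Config can override both flags.
* **Tolerance.** Default `τ = 0.125`, the midpoint of the conventional
  10–15% band, per-pair overridable.
* **Scoring.** `score = Σ matched weights − λ·RMS(|r_ij − d_ij|/d_ij)`
  with `λ = 1`: more matched features always beat a tighter fit because
  weights are 1 and the deviation penalty is bounded by `τ < 0.5`.
  Exactly one conformer is reported per molecule (the best-scoring one);
  ties break toward the earlier conformer and, in screens, toward the
  lexicographically smaller molecule id.
* **Search.** The matcher is a backtracking search over feature-to-point
  assignments with pairwise distance-feasibility pruning; because all
  constraints are pairwise, pruning is exact and the search provably
  returns the same optimum as exhaustive enumeration
  (`match_bruteforce`), which the test suite verifies on random
  instances with up to 8 candidate points.

Feature perception (on RDKit chemistry): aromatic points at the centroid
of each 5/6-membered aromatic ring; acceptor points on N/O atoms with an
available lone pair and non-positive formal charge (both carboxylate
oxygens emit points); hydrophobic points at the centroid of each maximal
connected group of ≥ 3 non-aromatic carbons; donor/anionic/cationic by
SMARTS rules.  Conformers are embedded with ETKDG, at most 3 per
molecule, deduplicated at 0.5 Å heavy-atom RMSD (a concrete reading of
"distinct conformations"; no published cutoff exists).

## Validation statistics

For a retrospective screen over a database of `D` molecules containing
`A` known actives, returning `Ht` hits of which `Ha` are active:

* % yield of actives = `100·Ha/Ht` (precision)
* % ratio of actives = `100·Ha/A` (recall)
* enrichment factor `EF = (Ha/Ht)/(A/D)` (1 = random)
* Güner–Henry score
  `GH = [Ha(3A + Ht)/(4·Ht·A)]·[1 − (Ht − Ha)/(D − A)]` (1 = perfect)

These reproduce the published three-model validation table for models 2
and 3 to the printed precision, and the model-1 recall column; the
published model-1 yield (60.09 vs computed 60.71) and GH (0.59 vs
computed 0.576) do not follow from that model's own counts and are
treated as typesetting errors — two of three columns validating the
formula anchors correctness.  Values are carried at full precision;
formatting rounds half-to-even on the decimal rendering (so the exact
GH = 0.495 of model 3 prints as 0.50).

## Machine-learning triage

Compounds with EC50 ≤ 1000 nM (inclusive) are labeled active; rows with
undefined or non-positive EC50 are dropped and duplicate ids keep the
lowest EC50.  Features are 13 RDKit physicochemical descriptors, MACCS
keys (166 bits) and Morgan radius-2 fingerprints (2048 bits); constant
columns are dropped at fit time.  (PubChem-style fingerprints have no
canonical open implementation contract and are replaced by MACCS +
Morgan.)  Seven classifier families with fixed hyperparameters stand in
for a broader survey: LightGBM gradient boosting, random forest, extra
trees, AdaBoost, bagging, a single decision tree and an RBF-kernel SVM.
A stratified train/test sweep from 80/20 to 70/30 in steps of 0.02
selects the (ratio, model) pair with the best test accuracy (ties to the
larger training fraction, then lexicographic model name); 20-fold
stratified cross-validation reports stability.  Stratification is used
throughout so both classes appear in every split at desk scale.  The
selected model filters a library, reporting the retention percentage to
two decimals.

## Similarity and novelty

Tanimoto `c/(a + b − c)` over explicit bit vectors (0/0 defined as 0),
computed for both MACCS and Morgan schemes against every reference
compound; the per-candidate maximum over the two schemes sets the flag,
with ≥ 0.85 (inclusive) meaning "known-like" and anything lower "novel".
The in-package Tanimoto is cross-checked against RDKit's implementation
in the tests.

## Trajectory analytics

* **Superposition** is the Kabsch least-squares rigid fit (SVD with a
  determinant correction so the rotation is always proper); degenerate
  (collinear or < 3-atom) selections are rejected.  It is cross-checked
  against `scipy.spatial.transform.Rotation.align_vectors`.
* **RMSD series** fit each frame on a fit selection (conventionally the
  receptor) and measure on another (the ligand); **RMSF** is the
  per-atom fluctuation about the time-mean position after per-frame
  fitting.
* **Hydrogen bonds** use donor–acceptor distance ≤ 3.5 Å and H–D–A
  angle ≤ 30° (the GROMACS-style criterion).  Published interaction
  tables in this area are ambiguous about whether the printed distance
  is D–A or H···A (and occasionally print geometrically impossible
  angles), so the tool always reports both distances.  Donor hydrogens
  are found by covalent proximity (≤ 1.25 Å); analyses on structures
  without explicit hydrogens fail with an instruction to normalize
  first.
* **Contacts / minimum distance** are brute-force cross-pair scans with
  a 4 Å default contact cutoff.
* **PCA** diagonalizes the covariance of centered per-atom coordinates
  after optional superposition; projections onto the top two
  eigenvectors are the collective coordinates for the landscape.
* **Free-energy landscape**: `G_i = −k_B·T·ln(P_i/P_max)` over a 2D
  histogram (default 32×32 bins, T = 300 K since no temperature is
  published for the landscape, `k_B = 0.0019872 kcal/mol/K`).  The
  global minimum is exactly 0 at the modal bin; empty bins are capped at
  the sampled maximum + 1 `k_B T` because an unbounded `−ln 0` is
  undefined.

## Energetics ledger

The MM-GB/PBSA decomposition is bookkeeping over four ingested
components (kcal/mol): `ΔG_gas = ΔE_vdW + ΔE_elec`,
`ΔG_solv = ΔE_GB + ΔE_surf`, `ΔG_total = ΔG_gas + ΔG_solv`.
`verify_ledger` audits these identities at a tolerance of 0.015, which
absorbs independent 2-decimal rounding of printed components.  Entropy
(−TΔS) is excluded from totals, matching the published decomposition's
column structure.  The polar GB term is ingested, never computed — a
full GB solver is out of scope; a single-ion Born formula
(`−166·q²/R·(1 − 1/ε_r)`) serves purely as a test oracle for the
ingestion path.  The nonpolar term is `γ·SASA + β` with the community
defaults γ = 0.0072 kcal/mol/Å², β = 0.  Toy gas-phase terms use the
6–12 Lennard-Jones potential with Lorentz–Berthelot combination and a
screened Coulomb sum with `k = 332.0637 kcal·Å/(mol·e²)`, no cutoff.
SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å, Bondi radii).

Ranking orders candidates by ascending total; the "better than control"
subset is strictly below the control's total, ties breaking by id.  The
packaged published decomposition for the ten GPR40 candidates and the
TAK-875 control reproduces the reported better-than-control set
{1, 3, 4, 5, 6, 10}.  One caveat the package surfaces rather than hides:
the published row for candidate 3 is internally inconsistent (its
component sums disagree with its printed ΔG_gas/ΔG_solv/ΔG_total by up
to ~19 kcal/mol), so `verify_ledger` fails that row by design while the
other ten rows pass within rounding.

## Funnel orchestration

Stages run in a fixed order — library, pharmacophore screen, ML triage,
docking cut, novelty filter, energetics ranking — each consuming the
previous stage's survivors, so stage counts are monotone non-increasing.
Docking is external by construction (the reference scorer is
proprietary): scores enter as CSV, and the control-relative cut is
non-strict by default (score ≤ control) because the published 10-molecule
cut retains two candidates tying the control redock score at −12.1; a
`strict` flag exposes the `<` reading.  The published hit-rate
percentage for the pharmacophore stage is not reproducible from its own
numerator and denominator (0.0187% vs 3772/224205 = 1.68%), so the
funnel always reports the computed percentage.

## Synthetic data: what it emulates and what it does not

* **Feature libraries** place actives at the model's reference geometry
  plus i.i.d. Gaussian noise under a random rigid motion; decoys
  displace both required features far outside their constraints (> 2×
  tolerance) and are rejection-checked against exhaustive matching so no
  k-of-n assignment exists.  Each entry carries a second tier — a small
  real scaffold SMILES from a templated family — so the full
  SDF/conformer/perception path can be smoke-tested.  Exact geometric
  control is impossible with real chemistry alone; the cloud tier tests
  matcher geometry exactly, the scaffold tier tests perception and I/O.
* **Activity tables** plant a recoverable structure–activity rule
  (carboxylic acid + ≥ 2 aromatic rings ⇒ potent, base EC50 100 nM vs
  ~31.6 μM otherwise) with multiplicative log-normal noise (default
  0.3 log10 units), matching how potency measurements scatter.
* **Trajectories** are a pose plus i.i.d. Gaussian wobble and optional
  linear drift (closed form: E[RMSD²] = 6σ² between independently
  perturbed copies), or planted orthonormal collective modes with
  sinusoidal time courses for PCA/landscape tests.
* **Toy complexes** are random receptor/ligand point sets with per-atom
  σ, ε, q and a minimum separation of 2.2 Å, so LJ/Coulomb sums have
  brute-force oracles.

Passing tests on these generators demonstrates the correctness of the
algorithms, not performance on real chemistry: decoys are geometric, not
property-matched (no DUD-E-style bias control); the planted activity
rule is far cleaner than assay data; the trajectories have no solvent,
periodicity or anharmonicity.  Published figures that depend on
proprietary scorers, accession-scale downloads or microsecond MD
(docking scores, the externally trained classifier metrics, long-MD
observables, ADMET predictions, similarity values against an unversioned
reference set) are deliberately not reproduction targets; the
property-based checks above stand in for them.

## Problem sizes and numerical choices

The shipped tests run the matcher-equivalence check on 200 random
instances (≤ 8 feature points), the noisy-recall check on 500 actives at
noise σ = τ/2 (in Å), the rule-recovery check on a 2 000-row activity
table with a 20-repeat permutation null, and trajectory checks on
40-atom poses with 200–1000 frames — sizes chosen so the full suite
completes in about a minute on a laptop while keeping Monte-Carlo
standard errors well inside the asserted margins.  Seeds are explicit
everywhere; there is no global random state, and every generator is a
pure function of its spec.
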