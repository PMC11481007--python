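# pharmfunnel

A tested, reusable implementation of a ligand-based virtual-screening
funnel for GPR40 (free fatty acid receptor 1) agonist discovery — the
staged pipeline a computational chemist runs between "here is a compound
library" and "these few candidates deserve an assay":

1. **Pharmacophore screening** — a 5-feature model (three aromatics, one
   hydrophobe, one acceptor, mirroring the GPR40 agonist site) with
   pairwise distance constraints, fractional tolerance τ and k-of-n
   matching, evaluated by an exact backtracking search.
2. **Decoy-set validation** — % yield `100·Ha/Ht`, % ratio `100·Ha/A`,
   enrichment factor `EF = (Ha/Ht)/(A/D)` and the Güner–Henry score
   `GH = [Ha(3A+Ht)/(4·Ht·A)]·[1 − (Ht−Ha)/(D−A)]`.
3. **ML triage** — EC50 ≤ 1 μM labeling, descriptor + MACCS + Morgan
   featurization, a leaderboard of seven classifier families over an
   80/20→70/30 split sweep, 20-fold cross-validation.
4. **External docking-score ingestion** with a control-relative cut.
5. **Tanimoto novelty filtering** (MACCS + Morgan, known-like at ≥ 0.85).
6. **Trajectory analytics** — Kabsch RMSD/RMSF, geometric hydrogen
   bonds, contacts, covariance PCA, and free-energy landscapes by
   Boltzmann inversion `G = −k_B T ln(P/P_max)`.
7. **MM-GB/PBSA energy ledgers** — `ΔG_gas = ΔE_vdW + ΔE_elec`,
   `ΔG_solv = ΔE_GB + ΔE_surf`, `ΔG_total = ΔG_gas + ΔG_solv`, verified
   and ranked against the TAK-875 control.

Every stage has a synthetic-data generator with controlled ground truth
(feature-cloud actives/decoys, planted structure–activity rules, wobble
trajectories, toy complexes with closed-form energies), so the whole
funnel runs and is validated end-to-end with no proprietary software or
external database.

## Worked example

Generate a demo dataset and validate a screen:

```sh
$ pharmfunnel fixtures --outdir fx --seed 7 --n-actives 20 --n-decoys 80
fixtures written to fx

$ pharmfunnel validate --counts 100 20 24 18 --name "model 2"
Pharmacophore validation — model 2
  Database size (D)        100
  Known actives (A)        20
  Total hits (Ht)          24
  Active hits (Ha)         18
  % yield of actives       75.0
  % ratio of actives       90.0
  Enrichment factor (EF)   3.75
  False positives          6
  False negatives          2
  Goodness of hit (GH)     0.73
```

Of the 24 hits this screen returned, 18 are true actives: precision
75%, recall 90%, a 3.75-fold enrichment over random picking, and a
Güner–Henry composite of 0.73 (1.0 would be a perfect screen).

Audit the packaged MM-GBSA decomposition of the ten GPR40 candidates
and rank them against the TAK-875 control:

```sh
$ pharmfunnel energetics fx/ledger.csv
         1  total   -63.29  ok
         2  total   -40.26  ok
         3  total   -47.60  FAIL (max residual 19.04)
         ...
   Control  total   -42.45  ok
6 of 10 candidates better than Control (-42.45): 1, 4, 6, 3, 10, 5
```

Six candidates (1, 3, 4, 5, 6, 10) bind more favorably than the control;
the `FAIL` line is deliberate — candidate 3's published component row is
internally inconsistent, and the ledger audit surfaces that instead of
papering over it (see `docs/methods.md`).

Run the full funnel on a synthetic library with a planted ground truth:

```sh
$ pharmfunnel funnel funnel.yaml --outdir run1
Screening funnel (seed 7)
  library           200  (100.00% of library)
  pharmacophore      20  (10.00% of library)
  ml_triage          20  (10.00% of library)
  novelty            20  (10.00% of library)
```

At zero geometric noise the pharmacophore stage recovers exactly the 20
planted actives; the classifier trained on the planted EC50 rule keeps
all of them; none resembles the TAK-875 reference above the 0.85
Tanimoto threshold, so all 20 reach the final report.

The same operations are available as a library:

```python
from pharmfunnel.screen_metrics import ScreenCounts, summarize
summarize(ScreenCounts(D=100, A=20, Ht=24, Ha=18))
# ScreenStats(yield_pct=75.0, ratio_pct=90.0, EF=3.75, FP=6, FN=2, GH=0.7284375)
```

## Layout

```
src/pharmfunnel/
  chemio.py          molecules, structures, trajectories; SDF/SMILES/PDB/XYZ I/O
  synth.py           synthetic libraries, activity tables, trajectories, complexes
  pharmacophore.py   models, feature perception, k-of-n distance matching, screening
  screen_metrics.py  yield/ratio/EF/Güner–Henry validation statistics
  ml_triage.py       EC50 labeling, featurization, model leaderboard, library filter
  similarity.py      Tanimoto fingerprints, max-similarity, novelty flags
  traj.py            Kabsch, RMSD/RMSF, H-bonds, contacts, PCA, free-energy landscape
  energetics.py      energy ledgers, LJ/Coulomb, Shrake–Rupley SASA, control ranking
  funnel.py          staged orchestration, external-score ingestion, final report
  cli.py             `pharmfunnel` command-line interface
```
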