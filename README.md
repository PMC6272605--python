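# consdock

A toolkit for **consensus-docking virtual screening**: deciding which
docking hits to trust by asking whether several independent docking
programs place the same ligand in the same binding disposition.

Docking a compound with one program gives a pose and a score; both are
noisy. Consensus docking docks the compound with *k* programs, keeps each
program's best-scored pose, and measures all pairwise heavy-atom RMSDs
between those poses *in the shared receptor frame* (no re-superposition —
where the ligand sits in the site is the signal). The poses are then
clustered by **complete linkage** with a 2.0 Å threshold, so every
cluster's members are all less than 2.0 Å from one another. The
**consensus level** of the compound is the size of the largest cluster;
with four engines, level 4 means full agreement. Screening a library
against an **ensemble** of receptor conformations (canonically four:
open/closed × cofactor-bound/free, treated independently) shortlists the
compounds that reach full consensus in at least one conformation.
Shortlisted poses can finally be triaged by a short MD run: a hit is kept
only if the ligand's average heavy-atom RMSD from the docked pose stays
strictly below 2 Å over the trajectory.

The package implements everything downstream of the docking engines:

- `consdock.pose_model` — poses, manifests, SDF/MOL2/PDB I/O, best-pose
  selection
- `consdock.geometry` — graph-automorphism–corrected in-place RMSD,
  Kabsch superposition, steric-clash and H-bond post-filters
- `consdock.cluster` — complete-linkage clustering, consensus level,
  representative (medoid) pose
- `consdock.ensemble` — screening across receptor states, level counts
- `consdock.enrichment` — EF, EF@x%, percent-of-max EF, ROC/AUC
  (continuous scores and discrete consensus levels)
- `consdock.stability` — the MD pose-stability filter
- `consdock.fixtures` — synthetic molecules/poses/libraries/trajectories
  with known ground truth
- `consdock.cli` — `consdock` command with `manifest`, `consensus`,
  `screen`, `enrich`, `mdfilter`, `fixtures` subcommands

## Key quantities

For a selection that retrieves NC compounds out of a library of NC_tot
containing A = t_p + f_n actives (t_p retrieved, f_n discarded):

```
EF      = [t_p / (t_p + f_n)] · (NC_tot / NC)
EF_max  = [min(NC, A) / A]    · (NC_tot / NC)
%max EF = 100 · EF / EF_max
```

EF = 1 for random selection (or the whole library); EF@1%/5%/10% are
capped at 100/20/10 when A fits in the retrieved set. The ROC over
consensus levels thresholds at level ≥ k for each k; its trapezoidal
area equals the tie-corrected Mann–Whitney statistic.

## Worked example

Consensus-cluster four engine poses of one compound and score a screen:

```python
>>> import pandas as pd
>>> from consdock import EnrichmentCounts, enrichment_factor, \
...     percent_of_max_ef, roc_from_levels
>>> from consdock.cluster import consensus_for_poses
>>> from consdock.fixtures import make_pose_ensemble

>>> poses, truth = make_pose_ensemble([2, 2])   # two engine-pairs agree
>>> res = consensus_for_poses(poses, threshold=2.0)
>>> res.consensus_level
2

>>> counts = EnrichmentCounts(t_p=12, f_n=81, n_retrieved=32, n_total=10_093)
>>> round(enrichment_factor(counts), 1)
40.7
>>> round(percent_of_max_ef(counts), 1)
37.5

>>> levels = pd.DataFrame({"level": [1, 2, 3, 4],
...                        "actives": [93, 75, 43, 12],
...                        "decoys": [10_000, 1952, 177, 20]})
>>> round(roc_from_levels(levels).auc, 2)
0.84
```

Reading: a full-consensus selection that keeps 32 of 10,093 compounds,
12 of them among the 93 actives, enriches 40.7-fold over random — 37.5%
of the best possible at that retrieval size — and ranking compounds by
consensus level separates actives from decoys with AUC 0.84.

The same from the shell, on a generated desk-scale bundle:

```bash
consdock fixtures --n-compounds 8 --n-consensus 3 -o bundle/
consdock screen --manifest bundle/manifest.csv --labels bundle/labels.csv \
    --out-decisions decisions.csv --out-levels levels.csv
# -> "selected 3 of 8"
consdock enrich --counts levels.csv -o metrics.json
```

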