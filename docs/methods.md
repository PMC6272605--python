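# Methods

## The consensus-docking model

The platform treats a docking engine as a black box that, per compound
and per receptor conformation, returns one best-scored pose in the
receptor's coordinate frame. Agreement between engines is measured as
the heavy-atom RMSD between poses **in place** — no superposition —
because two poses that have the same internal shape but sit in different
parts of the site are different binding hypotheses. Hydrogens are parsed
and kept but excluded from every RMSD: engines disagree wildly about
protonation and hydrogen placement, and heavy-atom RMSD is the de facto
standard for pose comparison. This choice is not configurable for
consensus clustering; for trajectory analysis the atom selection is
explicit.

### Symmetry correction

A plain index-wise RMSD is ill-defined when the ligand has topological
symmetry (a phenyl ring rotated 60° is the same pose) or when two
engines emit atoms in different orders. Both problems are solved the
same way: the RMSD is minimised over all element- and bond-preserving
isomorphisms between the two heavy-atom graphs (VF2 via networkx). Bond
orders are collapsed (single/double/aromatic treated as equal edges)
before matching, so pose identity never depends on the Kekulé structure
an engine happened to write. Automorphism enumeration is capped at
10,000 mappings; beyond the cap the code falls back to the identity
mapping with a warning — the RMSD then loses symmetry correction but
remains well-defined. Symmetry correction is on by default and exposed
as a flag, since the equivalent behaviour of widely used `rms_analysis`
tools varies; the invariant `symmetry-corrected ≤ identity-mapped` holds
by construction.

## Complete-linkage clustering and the consensus level

Clustering is agglomerative complete linkage on the k×k RMSD matrix
(k = number of engines, typically 4): starting from singletons, the two
clusters with the smallest maximum-pairwise distance are merged, and
merging stops when that smallest distance reaches the 2.0 Å threshold
(strictly-below survives). Complete linkage is the right linkage here
because it controls cluster *diameter*: every member of a final cluster
is less than 2.0 Å from every other member, which is exactly the notion
of "the same pose found by several programs". The diameter property is
asserted post-hoc on every run.

Merge ties are broken deterministically by the lowest (min index of
block A, min index of block B); without a fixed rule, consensus levels
could differ between runs on tied matrices. The consensus level is the
size of the largest cluster. The representative pose of a compound is
the **medoid** of the largest cluster (minimum summed RMSD to the other
members) — the natural centroid-free choice for a 4-element cluster.
When two clusters tie for largest, the tighter one (smaller diameter)
wins, then engine priority (configurable; default lexicographic
engine id): tighter consensus is stronger evidence.

## Ensemble screening

Receptor conformations are independent: poses are never compared across
receptors, and a compound is shortlisted when any single receptor state
reaches the required level (default: all engines agree). A compound may
therefore be selected through different binding modes in different
states — that is intended, since the ensemble exists precisely because
the target's site can be open or closed, with or without cofactor. An
engine that fails to produce a pose reduces the attainable level at that
receptor (flagged in the output) rather than aborting the compound.
Compound identity across engines is tracked by id string; a validation
pass warns when heavy-atom counts for one id differ between engines.

## Enrichment metrics

EF, EF_max and percent-of-max are implemented exactly as defined in the
README. The library size NC_tot includes the actives (e.g. 10,093 for a
93 + 10,000 benchmark); this convention is validated by exact
reproduction of the benchmark EF (40.7) and AUC (0.84). Note one known
inconsistency in the published benchmark table this package is checked
against: the printed EFs at levels 2 and 3 (3.7 and 19.5) do not follow
from the stated formula applied to the printed counts (which give ≈4.0
and ≈21.2); the level-4 EF and the AUC do. The package implements the
stated formula and does not chase the two inconsistent printed values.

ROC from discrete consensus levels thresholds cumulatively at level ≥ k,
one vertex per level plus (0,0); the trapezoidal area is then identical
to the Mann–Whitney U statistic with ties counted ½ (verified against
explicit pair counting to 1e-9). ROC from continuous scores delegates to
scikit-learn. EF@x% retains floor(x · NC_tot) compounds; score ties
straddling the cut are resolved pessimistically by default (actives
after decoys within the tied block), so a tie never flatters the
selection; an optimistic policy is available.

## MD pose-stability filter

Each trajectory frame is rigidly superposed onto frame 0 by a
least-squares (Kabsch) fit on protein heavy atoms — the measured
quantity is ligand drift relative to the binding site, not whole-complex
tumbling — and the ligand's identity-mapped heavy-atom RMSD from the
docked reference is computed with no ligand refit, so a ligand that
keeps its shape but leaves the pocket registers as unstable. The frame-0
protein is the alignment reference, with the docked pose assumed to be
in frame 0's frame. `align='none'` disables the fit. The verdict
averages over frames with t ≥ burn-in (default 0 ps; configurable, since
equilibration windows are protocol-specific) and **passes only when the
average is strictly below 2.0 Å** — an average of exactly 2 Å is
discarded. Superposition uses `scipy`'s SVD-based rotation fit; residual
RMSDs of identical coordinate sets are zero only to ~1e-7 Å (floating
point), which the tests account for.

## Post-filters: clashes and H-bonds

Steric clash: a ligand/protein heavy-atom pair closer than
0.75 × (r_vdW,i + r_vdW,j) with Bondi radii — the common soft-clash
convention; the scale is a parameter. Hydrogen bonds: donor–acceptor
(N/O) heavy-atom distance ≤ 3.5 Å, plus a D–H···A angle ≥ 120° when the
donor hydrogen is explicit (ligand side); protein donors are assessed on
distance alone because deposited structures usually lack hydrogens.
Residue filters (e.g. {R169, T248} of the lactate-dehydrogenase site)
accept one- or three-letter labels and reject labels absent from the
structure, so a typo cannot silently disable the filter.

## Synthetic fixtures: what they do and do not show

The fixture generator builds every test input as a pure function of a
seed:

- **Molecules** with hand-written connectivity whose automorphism counts
  are provable (benzene 12, C–C 2, C–N–O 1, an asymmetric 10-heavy-atom
  ligand 1).
- **Pose ensembles** as rigid translations of a base pose, so planted
  pairwise RMSDs are exact (translation by t ⇒ in-place RMSD |t|) and
  the ground-truth complete-linkage partition is known by construction;
  recipes whose margins would make the truth ambiguous are rejected.
  Defaults: 0.5 Å within-cluster spacing, 5 Å between cluster centres,
  against the 2.0 Å threshold.
- **Libraries** with a molecular-weight window of 315–560 g/mol (bounds
  inclusive — "between" is read inclusively and documented here), decoys
  sampled without replacement from a wider pool, defaults of 93 actives
  against the decoy count chosen per test.
- **Trajectories** with prescribed per-frame ligand drift along a fixed
  axis over a static protein scaffold, so the expected average RMSD is
  the arithmetic mean of the drift series.

These fixtures exercise the *bookkeeping and geometry* of the platform
exactly, but they are deliberately idealised: poses differ by rigid
translation only (no conformational change), decoys have no real
chemistry, and trajectories have no thermal noise unless requested.
Passing tests therefore demonstrate algorithmic correctness, not docking
accuracy on real targets.

## Problem sizes and numerics

Unit and property tests run at desk scale: clustering is cross-checked
on 1,000 random matrices with n ≤ 6 (the production case is n = 4
engines), automorphism brute force covers molecules ≤ 8 heavy atoms
(8! permutations), Monte-Carlo checks of EF/AUC null expectations use
10,000 and 1,000 resamples, and the end-to-end screen fixture uses 40
compounds × 4 receptors × 4 engines. Exact planted quantities are
asserted at 1e-6–1e-12; quantities passing through rigid-body fits at
1e-6–1e-7 (see above); Monte-Carlo means at 2–5% of their scale.

## Known limitations

- Compound identity across engines is by id string, not graph
  isomorphism; the consistency validator only warns.
- MOL2 support reads SYBYL atom types but uses element + connectivity
  only; charges and substructure records are ignored.
- PDB pose input derives bonds from CONECT records or proximity, so
  bond orders are nominal there.
- The clash and H-bond filters are purely geometric; no electrostatics,
  scoring or minimisation anywhere.
- The stability filter consumes trajectories; it does not run MD.
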