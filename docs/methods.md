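# Methods

## Scope and assumptions

`nbrank` operates on two-chain complexes: one antigen chain (receptor,
default chain id `A`) and one nanobody chain (ligand, default `H`). All
geometry is heavy-atom and residue-level; hydrogens are discarded on read
because upstream docking and refinement programs protonate inconsistently,
and no feature in the set depends on them. Only the first model of a
multi-model file and the highest-occupancy altloc conformer are kept, so a
given file always yields one deterministic structure. Residues are matched
between a model pose and its native by `(chain id, author residue number,
insertion code)`; there is no alignment fallback — poses must come from the
same sequence, which is the self-docking setting the package targets.

## Pose quality and labels

DockQ combines three CAPRI-style components with the standard constants:
native contacts at a 5 Å heavy-atom cutoff (Fnat), interface residues at
10 Å for iRMS with scaling d1 = 1.5 Å, and antigen-superposed nanobody
backbone RMSD for LRMS with d2 = 8.5 Å; backbone means N, CA, C, O.
Superposition is least-squares (Kabsch via SVD, proper rotation enforced).
All constants are exposed in `QualityParams`.

The binary nativeness label is 0 iff DockQ < 0.23, so 0.23 itself is
native-like; the CAPRI bands are [0, 0.23) incorrect, [0.23, 0.49)
acceptable, [0.49, 0.80) medium, [0.80, 1.0] high, with half-open upper
bounds except the top. Distance comparisons are inclusive (a contact at
exactly the cutoff counts), and the same 5 Å convention defines the
paratope/epitope for the contact features, so labels and features share one
notion of "interface". A buried-surface-area definition of the interface
would be a defensible alternative; the distance criterion was chosen for
that consistency and because it needs no SASA engine.

## CDR annotation

User-supplied spans (0-based, half-open, via JSON/YAML) always win and are
only validated. Without them, a sequence heuristic anchors the loops: the
first framework cysteine (searched at positions 10–35) fixes Chothia-like
windows CDR1 = [cys1+4, cys1+11) and CDR2 = [cys1+30, cys1+35); CDR3 runs
from three residues past the second framework cysteine (the last Cys before
the J-segment) to the tryptophan of the first `WG.G` motif after it. Any
unresolvable loop rejects the structure, mirroring the practice of
excluding complexes with missing CDRs. The heuristic assumes a single
complete VHH domain of at least 60 residues; it is not a numbering scheme
and will mis-place loops on heavily engineered frameworks — supply spans
there.

In the contact block, "proportion of CDR residues in the paratope" uses the
paratope size as denominator (0 for an empty paratope); the per-loop
fractions divide by each loop's full length. Amino-acid counts cover the 20
standard residues; nonstandard residues (mapped to X) count toward paratope
and epitope sizes but toward no letter.

## Feature schema

Fixed column order: contact (52) | Rosetta (20) | FoldX (44) | property of
paratope (66) | property of epitope (66) = 248. Blocks can be disabled;
the common offline mode is contact+property (184 columns). Energy values
come only from parsers for Rosetta InterfaceAnalyzer score files and FoldX
AnalyseComplex tab files — the package never runs either program. Absent
canonical columns become NaN, which the tree learner routes natively; a
zero would silently mean "perfectly average energy". The 20 Rosetta and 44
FoldX slot names are canonical lists fixed in `featset.py`, drawn from the
standard outputs of each program and asserted to those counts.

The 66 descriptors are ten published amino-acid scale families
(Cruciani 3, Kidera 10, z-scales 5, FASGAI 6, T-scales 5, VHSE 8,
ProtFP 8, ST-scales 8, BLOSUM indices 10, MS-WHIM 3). The packaged table
(`data/aa_descriptors_synthetic.csv`) transcribes the published Kidera and
z-scale values; the other eight families are deterministic synthetic
stand-ins on a zero-mean unit scale, frozen at build time, because the
original tables are not redistributable here. Every analysis is agnostic
to the actual values — swap in a literature table with
`load_descriptor_table(path)` for interpretable property features.
Property features are plain sums of descriptor rows over the interface
residues (additive by construction; X contributes zero). No feature
scaling is applied anywhere: tree ensembles are scale-invariant.

## Learning and ranking

Partitions are grouped by complex id: 5 independent seeded shuffles, first
80% of complexes to training. This is repeated random splitting, not
disjoint folds — all five test sets are drawn independently. The classifier
is scikit-learn's `HistGradientBoostingClassifier` (300 iterations, depth
6, learning rate 0.1, `early_stopping=False` for strict determinism); it
was chosen because it is the pre-installed gradient-boosted tree learner
with native missing-value routing. It has no row-subsampling parameter, so
none is exposed. Class imbalance is handled by a positive-class sample
weight of n_neg/n_pos computed on the training records (switchable off).

A parent pose's score is the arithmetic mean of its refined children's
predicted native-like probability (children only; the parent itself is not
scored). Ties break by the maximum child probability, then parent id, so
rankings are a deterministic permutation 1..n. For evaluation a parent is
native-like iff its *own* DockQ ≥ 0.23, not its children's — this is
configurable since either convention is defensible. Rank percentiles use
linear-interpolation (type-7) quantiles. PR-AUC is computed per refined
pose (average precision over all thresholds). The Wilcoxon matched-pairs
signed-rank comparison drops zero differences, returns p = 1 when all pairs
tie, and uses the exact null for ≤ 25 untied pairs, otherwise the normal
approximation with continuity correction.

## Attribution

Feature contributions are exact tree-path (Saabas-style) attributions in
raw log-odds space: walking a sample down each tree, the change in the
count-weighted expected leaf value at every split is credited to the split
feature. The telescoping sum makes `base + Σ contributions` equal the
ensemble's raw output exactly per sample (tested at 1e-6). Global
importance is the mean absolute contribution over the evaluated set,
descending. Unlike full Shapley attribution this credits only features on
the decision path and can split credit unevenly among correlated features;
it preserves the two properties the package relies on — exact additivity
and recovery of genuinely informative features.

## Synthetic data: what it does and does not establish

The generator emulates the *shape* of a docking campaign, not its physics.
Natives are idealized helical mini-chains (N/CA/C/O plus a radial CB)
placed in contact (≥ 5 residue contacts at 5 Å), with the nanobody sequence
carrying the planted cysteine/`WGxG` anchors so CDR annotation is exact.
Defaults: 12 complexes, 8 parents per complex, 4 refined children per
parent — a desk-scale stand-in for a campaign of hundreds of poses per run.
Parents are rigid-body perturbations of the nanobody cycling through paired
translation/rotation scales (0.5–24 Å, 3–120°), chosen to straddle the
DockQ bands; children add a small refinement-scale perturbation (0.3 Å,
2°). Bands are populated by rejection sampling (DockQ is not invertible in
rotation), every complex is guaranteed at least one native-like and one
non-native-like parent, and poses landing within 0.02 DockQ of the 0.23
boundary are resampled so that PDB round-tripping (10⁻³ Å precision) cannot
flip a label. Pseudo-energy fixtures (linear in DockQ plus seeded noise)
can be emitted to exercise the full 248-column path.

Consequently a green end-to-end test establishes that the machinery —
labelling, grouped splitting, training, averaging, ranking, attribution —
recovers signal when signal exists; it says nothing about how well real
Nb–Ag energetics separate native from non-native poses. Benchmark-scale
results (median ranks on real docking campaigns, PR-AUC on hundreds of
thousands of refined poses) require real structure collections, docking and
Rosetta/FoldX runs and are out of scope by design.

## Numerical choices

- Kabsch superposition needs ≥ 3 points; reflection is prevented via the
  determinant sign correction. RMSD agreement with an independent
  quaternion oracle is tested to 1e-6 Å.
- DockQ of an identical pose is exactly 1.0 (contacts identical, both RMSD
  terms 0).
- `make_splits` uses `floor(train_frac · n)` training complexes.
- All randomness flows from explicit integer seeds; synthetic generation is
  reproducible to byte-identical manifests. Seeds derived internally stay
  below 2³¹.
- Degenerate inputs fail loudly: natives without contacts
  (`DegenerateNativeError`), single-class training labels, empty parent
  groups, mismatched schemas.
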