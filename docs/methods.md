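# Methods

## Problem setting

Ligand-based virtual screening casts activity prediction as binary
classification over molecular fingerprints. Public bioactivity tables give
continuous potencies as pChEMBL values (negative log10 of a half-maximal
measurement; unitless; higher = more potent). We binarize with a
two-cutoff scheme — strictly above the positive cutoff → active, strictly
below the negative cutoff → inactive, the closed band between excluded —
to keep assay noise away from the label boundary. Defaults are 7.5/6.5
(kinase targets) with 7/6 available for GPCRs. Values exactly on a cutoff
are excluded: the cutoffs are read as strict inequalities. Conflicting
measurements for the same structure are merged by median (a robust choice
when IC50/Ki/EC50-derived values are mixed); structures are canonicalized
at read time so duplicate detection is structure-based.

The practical obstacle is negative data: confirmed inactives are scarce,
and the ones that exist are biased toward the structural neighbourhoods
medicinal chemists have already explored. Training on positives plus a
broad unlabeled sample of chemical space (PU learning) trades a lower
false-negative rate for unlabeled-pool contamination by undiscovered
actives.

## Data pools

A compound library is clustered by k-means on its fingerprint matrix
(binary vectors treated as real). Per target:

* **putative negatives** — one uniformly random member of each cluster
  containing no known active, then a uniform subsample to the pool cap
  (default 50,000). The negativity evidence is cluster-level absence of
  actives, which activity cliffs can defeat.
* **unlabeled** — one representative per cluster (the member nearest the
  centroid, ties broken by lowest id), likewise capped.

"Known active" means the positive set of the current target; pools are
per-target. The cap subsample is per target as well. The desk-scale
default cluster count is `max(10, n/150)`, configurable; clustering can
use either the screening fingerprint or an 881-bit substructure-key
fingerprint. Pools are rebuilt bit-identically from the same seed, and
putative negatives never share a cluster with a known active (asserted in
tests).

## Base learner and calibration

All strategies share one base learner: soft-margin SVC with an RBF kernel,
C = 1, gamma = 1/(n_features · Var X) ("scale"). Probabilities come from
Platt sigmoid calibration fitted by internal cross-validation on the
decision values (`CalibratedClassifierCV(ensemble=False)`, 5 folds,
reduced when a class has fewer members). An optional per-target grid
search (C ∈ 10⁻¹…10², gamma ∈ 2⁻¹²…2⁻⁴, 5-fold CV, F1) is provided but
not used by default. Calibration matters scientifically here: the fitted
sigmoid encodes the training class ratio, so positive-heavy training sets
yield liberal probability scales and negative-heavy ones conservative
scales — part of how the strategies differ at a fixed 0.5 threshold.

## The six strategies

* **baseline** — single fit, P vs true negatives N.
* **putative-negative augmentation** (`fit_tao`, after the cluster-based
  strategy it follows) — single fit, P vs N ∪ putative negatives, all at
  weight 1. Raises specificity, costs recall.
* **PN-weighted** — single fit; the unlabeled pool joins the negative
  class at sample weight 0.5 (< 1, encoding its lower credibility).
* **PU-iterative** — start from P vs N; score the remaining unlabeled
  pool, absorb everything predicted negative (probability ≤ 0.5), refit;
  stop when a round absorbs nothing or `max_rounds` is hit. Each round
  strictly shrinks the pool or stops, so at most |U| rounds run.
  Intermediate rounds skip calibration (only the class call is used); the
  returned model is refit calibrated.
* **PU-bagging** — ensemble of `n_bags` members; each bag holds all of P
  versus an equal-sized random draw of U treated as negative.
* **NAPU-bagging** (negative-augmented PU-bagging) — as PU-bagging, but
  the non-positive portion of each bag mixes true negatives and unlabeled
  compounds at a fixed N:U ratio, merged into one negative class. The
  final configuration is bag size = |P| with N:U = 0.4:4.5
  (P:N:U = 1:0.4:4.5).

Bag semantics: "bag size" is the size of the non-positive portion, as a
multiple of |P| (`bag_multiplier`, default 1). This is the only reading
under which an N:U split of 0:1 at multiplier 1 coincides exactly with
1:1 PU-bagging — and that degeneracy is enforced by construction and by
test (identical bags, members and predictions under shared seeds). The
alternative reading (portion = 4.9 × |P|) is available via
`bag_multiplier=4.9`.

Draws are without replacement within a bag whenever the pool allows.
When a requested draw exceeds the pool (e.g. an n_fraction sweep against
a 40-compound negative pool), the draw is taken with replacement and the
resulting duplicates are collapsed to unique compounds with multiplicity
sample-weights before fitting. The SVM objective is identical to literal
duplication (C_i = C · count), but Platt calibration no longer sees copies
of one compound on both sides of a CV split — literal duplication leaks
across folds and produces severely mis-calibrated, over-liberal members.

`n_bags` defaults to 100 (the aggregated probability is stable well below
that at desk scale; the distributional tests use 30–50 to stay fast).
Aggregation is the mean of member probabilities — a continuous score is
required for screening thresholds such as 0.75 — and hit calls use a
strict `probability > threshold`.

## Metrics

Confusion metrics (SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC, F1) report
NaN with a warning on zero denominators, never a silent 0. BEDROC_α uses
the exponentially weighted robust-initial-enhancement formulation with
the standard sinh/cosh normalization (α = 80.5 by default; verified
against both a term-by-term enumeration at n ≤ 20 to 1e-10 and an
independent cheminformatics implementation). Hit rate at fraction f takes
the top ⌈f·n⌉ compounds by score (stable sort; ties broken by input order
with a warning); EF_f = HR_f / prevalence, so EF at f = 1 is identically
1. Rank averaging ranks methods within each dataset (higher metric →
higher rank, midrank on ties) and averages ranks across datasets; it is
the right comparison when class ratios differ too much across datasets
for raw metric values to be comparable.

## Screening

Per-target ensembles score a deck (all targets must share one fingerprint
config); multitarget hits are compounds strictly above the hit threshold
(default 0.75) for *every* target. Drug-likeness filtering applies
Lipinski's rule of five in its customary at-most-one-violation form
(MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10) and the Ghose ranges as a hard
all-conditions pass (160 ≤ MW ≤ 480, −0.4 ≤ logP ≤ 5.6, 20 ≤ atoms ≤ 70
including hydrogens, 40 ≤ molar refractivity ≤ 130); logP and molar
refractivity use the Crippen atom-contribution scheme. Structural alert
sets (PAINS-like) are consumed as named SMARTS catalogs supplied at run
time — none are vendored, since their licensing and versioning vary; a
three-pattern demo catalog supports tests. Filters are applied to the
intersection and both the pre- and post-filter counts are reported
(filtering and intersection commute, so the order is presentational).
Novelty is reported per hit and target as the maximal Tanimoto similarity
to the known actives; the all-zero/all-zero Tanimoto corner is defined as
1.0 (identical empty bit sets) and zero/non-zero as 0.

## Synthetic data: what it emulates

`pubag.synthetic` generates binary fingerprint corpora whose geometry
carries the pathologies the strategies are designed for. Clusters are
sparse random prototypes (density 5% of 256 bits); members are prototypes
with independent bit flips (noise 0.05 ≈ 13 flipped bits, giving
within-cluster Tanimoto ≈ 0.3, i.e. realistically diffuse ECFP
neighbourhoods). Eight of twenty clusters are active chemotypes; each
carries a *near-miss shell* — the prototype with 16 dedicated "cliff
bits" toggled — representing the specific small structural change that
abolishes activity (an activity cliff: close in similarity, resolvable
only through negative examples near the cliff).

Pool composition mirrors assay reality:

* 200 training actives from the chemotype cores;
* 40 true negatives, 60% near-miss shell compounds and 40% generic, from
  the chemotypes covered by assays (`observed_chemotype_fraction`, 1.0 by
  default; 0.5 in the partial-coverage scenario);
* 400 putative negatives from generic clusters only;
* 2,000 unlabeled compounds from generic space with 10% hidden actives
  drawn from the chemotype cores;
* held-out compounds are shifted relative to training: held-out actives
  are cliff-straddling analogues (each cliff bit toggled with probability
  uniform in [0, 2·`test_cliff_drift`]), held-out negatives are near-miss
  compounds, and `test_noise_factor` can add the extra radial noise of
  external validation sets.

This geometry reproduces, mechanistically, the empirical pattern the
strategies show on real kinase data: supervised fits with scarce N are
over-liberal or locally over-tight; putative-negative augmentation
pushes specificity up and recall down; P-vs-U bagging is the most
sensitive and least specific (its bags under-represent the near-miss
regions); and negative augmentation of the bags restores most of the
specificity at a modest recall cost.

What the generator does **not** emulate: real ECFP bit correlations and
hashing collisions, heterogeneous assay noise, inter-target correlations,
size/property gradients, and any medicinal-chemistry semantics (the
drug-likeness module is exercised on real molecules instead). Passing the
distributional tests therefore demonstrates that the implementation has
the claimed inductive behaviour on data with the assumed structure — not
that the same margins will be observed on any particular real target.

The clean control condition (`SynthConfig.noiseless()`) removes every
corruption — bit noise, contamination, cliffs, held-out shift — and
enlarges the true-negative set (120, all generic) so that every inactive
chemotype is represented in training; on it, every strategy must reach
held-out SEN = SPE = 1.0 exactly, which the suite asserts. The
enlargement matters because with 40 draws over 12 generic clusters some
clusters can go unseen, making perfect specificity information-
theoretically unreachable for the supervised baseline rather than a
separability failure.

Two scenario details are deliberate:

* The n_fraction trade-off sweep runs on the generator defaults, where
  assay coverage spans all chemotypes and held-out actives differ from
  training ones along the cliff axis. There the true negatives carry more
  rejection evidence per draw than the unlabeled pool everywhere the
  held-out compounds live, which is the regime in which swapping U for N
  tightens the classifier monotonically — the regime the original
  bag-composition experiment operated in (it kept bag draws within the
  true-negative pool size).
* The strategy-ordering comparison uses the partial-coverage scenario
  (`observed_chemotype_fraction=0.5`, extra held-out noise), i.e. assays
  that probed only half of the active chemotypes and an external
  validation set — the situation in which the recall advantage of
  bagging over single-fit augmentation is largest.

## Numerical choices and degenerate inputs

* ECFP4 width 2048 bits (community default; the representation benchmark
  in the literature does not fix a width), binary not counts, consistent
  with Tanimoto usage.
* The 881-bit substructure-key option is a hashed RDKit pattern
  fingerprint at that width — a substructure fingerprint family of the
  same shape as the PubChem key set, not the CACTVS key definitions.
* Bags that would contain zero negative-class samples raise immediately
  (the one legitimate cause — an empty pool — is better reported than
  resampled around).
* Tied scores in ranking metrics are broken by stable input order with a
  warning; top-fraction size uses the ceiling.
* Ensembles require identical fingerprint configs across members and
  targets; width mismatches raise.
* Model persistence is a directory: a JSON manifest (strategy, threshold,
  fingerprint config) plus joblib-serialized members.

## Problem sizes

The test suite and the acceptance script run the distributional checks at
30–50 bags, 5–10 replicate seeds, and the generator's default corpus
(≈ 3,100 compounds, 256 bits); the full suite completes in a few minutes
on one CPU. These sizes were chosen as the smallest at which the ensemble
means are stable across seeds; n_bags = 100 remains the library default
for real screens.

## Known limitations

* The Platt class-ratio effect means reported probabilities are not
  comparable across strategies trained on different pool sizes; compare
  rankings (BEDROC/EF) or threshold-level operating points.
* PN-weighted with a very large unlabeled pool is strongly conservative
  at the 0.5 threshold (its calibration prior is dominated by the
  negative-weighted pool); the acceptance table shows this plainly.
* k-means on raw binary vectors is the procedure the pool construction
  follows, but Euclidean centroids are a crude geometry for sparse
  fingerprints; substructure keys (881 bits) mitigate this somewhat.
* No statistical tests between strategies are provided; orderings are
  asserted on means over replicate seeds.
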