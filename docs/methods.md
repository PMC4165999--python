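# Methods

This note documents the models and procedures implemented in `dnabind`,
the parameters that matter, the conventions adopted where several are in
circulation, and what the synthetic-data fixtures do and do not show.

## Sequence curation

Sequences are restricted to the 20-letter amino-acid alphabet. The six
letters B, J, O, U, X, Z (ambiguity codes, selenocysteine/pyrrolysine,
unknowns) are handled by policy: the default `strip` deletes them in place
and re-checks length afterwards, so the filtered alphabet defines the
analysable sequence; `reject` drops the whole record. Length limits default
to 50–6000 residues — shorter entries are likely fragments, longer ones
unwieldy multi-domain giants. All rejections are logged with reason codes
rather than raised, since curation is a bulk operation.

Family dereplication keeps the longest member of each protein family
(ties broken to the lexicographically smaller id, for determinism); a
record belonging to two families may represent both. Negative pools are
built by excluding any record sharing a family with the positive set, so
negatives are not trivial homologues of positives.

## Redundancy clustering

The greedy incremental scheme of CD-HIT: sequences sorted longest-first
(ties by id), each joining the first existing cluster whose representative
it matches at or above the identity threshold, else founding a new
cluster. Supported thresholds cover the 0.4–0.9 sweep in steps of 0.1 (any
value in (0, 1] is accepted).

Identity is a convention, not a universal: here it is the number of
identical columns divided by the alignment length (gap columns included)
of one optimal global alignment under match +1, mismatch 0, linear gap −1.
Arguments are canonically ordered before aligning so the measure is exactly
symmetric despite co-optimal alignment ties. A shared-2-mer count prefilter
skips alignments provably unable to reach the threshold (if identity ≥ t
the shorter sequence has at most e = L_short − ⌈t·L_long⌉ residues outside
match columns, each destroying at most k of its k-mers, so the spectra must
share at least (L_short − k + 1) − k·e k-mers); the filter is an
optimisation only and is property-tested to never change the clustering.

## Feature extraction

**188D CTD descriptor.** 20 composition frequencies, then per property a
21-dim block: class composition (3), class transitions (3), class
distribution (15). Conventions:

* Transitions are the three *unordered* between-class adjacent pairs
  (1,2), (1,3), (2,3), counted in either order and divided by L−1;
  same-class adjacencies are not transitions. A single-residue sequence has
  no adjacent pairs and returns zeros.
* Distribution follows the literal five-equal-parts reading: the sequence
  is split into five contiguous segments with 0-based half-open boundaries
  [⌊(s−1)L/5⌋, ⌊sL/5⌋) — total coverage, no dropped residues — and each
  value is a class's frequency *within its segment* (so the three classes
  sum to 1 per segment). This differs from the 0/25/50/75/100%
  residue-position variant found elsewhere in the CTD literature; the
  per-segment form was chosen as the direct reading of "distribution
  frequencies of each class in the five parts", and segment-length (not
  whole-length) normalisation keeps the 15 values on a common scale.
* The 8 default property partitions are the standard CTD groupings
  (Cai et al. 2003 lineage): hydrophobicity, normalised van der Waals
  volume, polarity, polarizability, charge, secondary-structure propensity,
  solvent accessibility, surface tension. They ship as an editable JSON
  file (`dnabind/data/property_partitions.json`) validated on load
  (3 disjoint classes exactly covering the 20 letters). Published example
  groupings for surface tension are inconsistent across sources; the
  shipped table is a documented convention, not a canonical fact.

**n-gram.** 1-gram is amino-acid composition (20 dims, identical by
construction to the first 20 CTD features); 2-gram the 400 ordered
dipeptide frequencies with denominator L−1. Each block sums to 1.

**PseAAC (type 1).** Composition plus λ sequence-order correlation factors
from three scales — hydrophobicity, hydrophilicity (Hopp–Woods), side-chain
mass — each z-scored over the 20 amino acids (population SD). The j-th
factor is the mean over positions of the mean squared difference of the
three scale values at positions i and i+j; the final vector
(f₁..f₂₀, w·θ₁..w·θ_λ) is normalised to sum to 1. Defaults λ=10, w=0.05
(the field's customary values). λ=0 reduces exactly to composition; λ must
be smaller than the sequence length.

## mRMR feature selection

Features are discretised per column into three states at mean ± α·σ
(α = 1, the original mRMR practice; constant columns collapse to one
state). Mutual information is computed from the empirical contingency
table in bits (log₂). Greedy forward selection: the first pick maximises
I(f; y); later picks maximise I(f; y) − mean_{s∈S} I(f; s) (MID) or
I(f; y) / max(mean_{s∈S} I(f; s), 10⁻¹²) (MIQ). Ties break to the lower
feature index; the stored score is the criterion value at selection time,
so the output table (order / feature / score) is self-documenting. MID and
MIQ necessarily agree on the first pick.

The PCA attribute ranking standardises features, fits a full PCA, and
attributes each component's explained-variance share back to features via
squared loadings; with all components kept the contributions sum to 1.

## The imDC ensemble

Configuration: `top_k` (default 5) learners kept from a 16-family
catalogue; `iterNum` balanced rounds (default "auto" = ⌈m/n⌉ so the
cycle-partition sampler walks the whole majority exactly once);
`weight_metric` (default minority-class F-measure — the quantity single
classifiers fail on under imbalance); decision threshold 0.5, exposed.

Choices made where the procedure is genuinely open:

* **Pool ranking** uses stratified CV on the full training data with the
  weight metric; a learner that fails to fit scores 0 with a warning
  instead of aborting. The five learners are selected once, not re-chosen
  per round.
* **Round construction** (`cycle_partition`): shuffle the majority once,
  split into ⌈m/n⌉ blocks of minority size, cycle blocks across rounds,
  pad the short tail block by wrapping around the shuffled order. Every
  round therefore holds all n minority samples and n distinct majority
  samples, and auto iterNum covers every majority sample at least once.
  `random_undersample` (fresh draw per round) is available as an
  alternative.
* **Vote weights** are computed on the out-of-round holdout (the samples
  not in the member's balanced training set), avoiding the optimism of
  in-round scores. When the input is already balanced there is no holdout
  and the round's own samples are used. Weights are floored at 0; an
  all-zero ensemble raises rather than predicting arbitrarily.
* **Votes are hard 0/1 labels**, not probabilities: the score is
  Σ wⱼ·voteⱼ / Σ wⱼ. This keeps the 16 heterogeneous learner families on
  an equal footing (several provide no calibrated probability).

The catalogue maps the classical names to scikit-learn estimators (RBF and
linear SVM, Gaussian naive Bayes, kNN, random forest, decision tree,
bagged trees, boosted stumps, logistic regression, ridge, LDA, QDA,
perceptron, small MLP, extremely randomised trees, decision stump), with
feature standardisation piped in front of the scale-sensitive ones. All
seeds for members derive deterministically from the config seed, so
(data, config, seed) fully determine the model and its predictions.

## Evaluation

Standard confusion-based definitions with label 1 (DNA-binding) positive:
accuracy (TP+TN)/N, precision TP/(TP+FP), recall TP/(TP+FN), F the
harmonic mean. 0/0 ratios are reported as 0 and flagged, matching the
convention of printing 0 precision for a classifier that never predicts
positive. Per-class and support-weighted averages are both reported. AUC
is the Mann–Whitney probability that a random positive outscores a random
negative with half credit for ties — exactly the trapezoidal ROC area and
independent of any monotone rescaling of scores. Cross-validation is
stratified, pools the confusion across folds (per-fold values are also
kept), and is deterministic given its seed.

## Synthetic data and what it shows

`simulate_sequences` draws residues i.i.d. from a background distribution
(default uniform 1/20, chosen so analytic expectations are simple);
positives re-weight a chosen residue set (default C/H/K/S, echoing the
residues repeatedly implicated in DNA binding) by an enrichment factor
(default 3) and renormalise. Lengths are uniform on 50–300 — inside the
curation window, scaled for quick iteration. The default labelled set is
100 positives vs 900 negatives (1:9), the imbalance regime the ensemble
targets. `inject_redundancy` adds per-site-mutated descendants with a
provenance map; `simulate_tabular` produces two isotropic Gaussian clouds
(8 dims) whose means are `separation` apart, 50 vs 450 samples.

The tabular default separation is 1.4 at unit noise — a balanced-prior
Bayes error near 24%, i.e. genuinely overlapping classes. This is the
regime the ensemble is for: learners trained on the raw 1:9 data
under-predict the minority class and their minority F collapses, while
balanced-round training preserves recall. At much larger separations the
problem stops being hard and well-specified single models (on Gaussian
data, naive Bayes and LDA are exactly well-specified) match or beat the
ensemble — a property of the easy regime, not a failure of the method.

Because sequences are i.i.d. residue draws, the compositional signal is
fully captured by 1-gram features; transitions, distributions and
dipeptides carry only redundant noise here. Passing tests on these
fixtures therefore demonstrate the mechanics (dimensionality, oracle
equivalence, imbalance behaviour, determinism, recovery of planted
structure) — not that 188D features outperform alternatives on real
proteins, which depends on order structure these generators deliberately
lack (no motifs, domains or indels).

## Numerical and degenerate-input conventions

Frequencies, not raw counts, everywhere (sequences differ in length).
Alignment identity tie-breaks are fixed by canonical argument ordering;
clustering ties by id. mRMR ties go to the lower feature index; pool
ranking ties to the learner name. The MIQ denominator guard is 10⁻¹².
Distribution requires L ≥ 5; PseAAC requires L > λ; transitions on L < 2
return zeros. Zero-variance features discretise to a single state and
standardise to zero for PCA. Empty FASTA files and empty record sets are
valid and round-trip.

## Problem sizes

The shipped demo pipeline simulates 600 sequences and cross-validates
five-fold; the imbalance study uses ten seeded 500-sample datasets with
held-out evaluation on an equal-sized fresh draw; clustering recovery uses
20 families × 3 members. These sizes were chosen to make the full suite
and the acceptance script comfortably reproducible on a single CPU while
leaving the measured properties clearly resolved.

## Known limitations

* The identity measure, word-filter bound and first-fit assignment follow
  the published description of greedy incremental clustering but are not
  bit-compatible with any particular CD-HIT release.
* The i.i.d. sequence generator cannot exercise order-sensitive feature
  superiority; real-data benchmarking is out of scope.
* Mutual information uses the plug-in estimator on three discrete states;
  continuous MI estimators (kNN/KDE) are deliberately out of scope.
* Binary classification only; the positive class must be labelled 1.
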