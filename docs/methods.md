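# Methods

## Scope and model

`pcmbench` benchmarks amino-acid descriptor sets by the quality of the
proteochemometric (PCM) models they support.  A PCM dataset is a sparse
compound × target activity matrix; each record becomes one design-matrix
row consisting of a ligand block (hashed circular fingerprint of diameter
6 folded to 512 bits, optionally followed by a physicochemical property
block) and a protein block (the encoded binding-site residue string).
Peptide-only sets (dipeptide inhibitor panels) use the protein block alone.
The learner is a random forest: regression or classification, 1500 trees by
default and 1000 for peptide-only sets, with the number of candidate
features per split fixed at `max(1, floor(0.5 * n_columns))` and
out-of-bag predictions retained.  No column scaling is applied before
training — trees are scale-invariant — while the PCA diagnostics center and
unit-variance scale explicitly.

## Descriptor tables

Thirteen sets are bundled, plus three combinations (feature codes ⊕
Z-scales(3); Z-scales(3) + per-target mean/SD block; ProtFP-PCA3 ⊕ binned
Z-scales).  Components per residue: Z-scales 3/5, binned Z-scales 12
(3 components × 4 bins), VHSE 8, MS-WHIM 3, FASGAI 6, T-scales 8,
ST-scales 5, BLOSUM 10, ProtFP-PCA 3/5/8, feature code 1.

Numeric values: Z-scales, VHSE and MS-WHIM are transcribed from the
original publications.  For FASGAI, T-scales, ST-scales, the BLOSUM indices
and the ProtFP PCA components no machine-readable source was available, so
the package ships clearly labelled *synthetic stand-ins*
(`*_synthetic.csv`) generated deterministically by `pcmbench._scalegen`:
PCA (or varimax-rotated PCA, for the factor-analysis- and VARIMAX-derived
sets) of a fixed 20-amino-acid physicochemical or topological property
matrix, or of the standardized rows of BLOSUM62.  The stand-ins preserve
what the benchmarking machinery actually consumes — component count,
continuous character, a chemically sensible similarity structure — but not
the published constants; any conclusion about a *specific published scale*
requires substituting the original values (a one-file drop-in via the
resource-file interface).  All shipped files are validated against frozen
SHA-256 checksums at load time.

Design choices on the encodings:

* **Binned Z-scales** use the first 3 components with 4 equal-width bins
  per component (right-closed top bin), i.e. 12 binary features per
  residue; the bin count is exposed because the original binning recipe is
  not published.
* **Feature code** assigns integers 1..20 in alphabetical one-letter order,
  one variable per residue, making all residue substitutions equidistant; a
  20-level one-hot variant is available for distance computations.
* **Target-average block**: per-component mean then sample SD (n−1
  denominator) over all site residues; a length-1 sequence has SD 0 with a
  warning.
* Non-natural residues and the gap character are errors by default; an
  opt-in imputation substitutes the per-component mean over the 20 amino
  acids.  Alignment columns gapped in *any* sequence are dropped for *all*
  sequences when carving binding sites (gap handling would otherwise favor
  descriptor sets with small value ranges).
* Coordinates are 1-based throughout (alignment columns, residue
  positions).

## Validation protocols and metrics

* 70–30: test folds are a uniform random 30% of records (rounded half-up),
  ten repeats by default, record-level sampling without stratification.
* LOSO: one fold per target; the held-out target contributes *all* its
  records to the test fold, probing target-space extrapolation.
* Leave-fraction-targets: targets shuffled and partitioned into
  `ceil(1/fraction)` disjoint groups (fraction ∈ (0, 0.5]); the tractable
  LOSO surrogate for 1000+-target panels.
* R₀² regresses observed on predicted through the origin (the orientation
  is recorded in every report; the alternate is behind a flag).  The MCC
  zero-denominator convention is 0.  Folds whose training data is
  single-class are recorded as failed and excluded from aggregates with a
  warning, not imputed.
* "Class size equalization" is implemented as scikit-learn's
  `class_weight="balanced_subsample"` (per-bootstrap balanced weighting),
  the closest native analogue of sample-size balancing in R-style forests;
  whether the reference setup downsampled or reweighted is not documented.
* Rows are fed to the learner in a seed-controlled randomized order even
  though the forest is order-invariant, so repeats stay independent.

## Ranking and significance

Each experiment (dataset × protocol × validation parameter) produces
fractional ranks (1 = best, average ties); a full four-dataset benchmark
yields 14 ranks per descriptor (regression sets contribute RMSE and R₀²
ranks, classification sets MCC and sensitivity ranks; LOSO does not apply
to peptide-only sets).  Aggregation is median rank plus MAD.  Pairwise
comparisons use a two-sided Wilcoxon signed-rank test implemented
in-package: zeros discarded before ranking (the Pratt variant is behind a
flag), exact null distribution by dynamic programming over doubled ranks
for ≤ 25 non-zero pairs (ties handled exactly), normal approximation with
continuity and tie correction above.  No multiplicity adjustment is applied
to the matrix, matching common practice for such overviews; a
Bonferroni-adjusted copy is emitted as supplementary output.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical shapes* the protocols care about,
not chemistry:

* `dipeptide_additive` — n random dipeptides, activity linear in a chosen
  descriptor encoding, standardized to 1.2 log units of spread, plus
  Gaussian noise (default 0.3 log units); peptide-only.  Ground truth is
  stored for recovery tests.
* `mutant_panel` — point mutants of one random base sequence, mutations
  confined to a pool of candidate columns (default 24, 1–13 per mutant,
  mirroring resistance-mutant panels); surrogate random-bit compounds;
  activity = standardized compound effect + a target effect carried by the
  descriptor encoding of the mutated columns + a rank-2 bilinear
  compound × target interaction (scale 0.5 — the simplest structure that
  makes a joint PCM model strictly better than per-target models) + noise;
  subsampled to a requested completeness with ≥ 1 record per target.  A
  `singleton` option gives the first mutant a private mutation column and a
  +3 log-unit private offset, the canonical hard case for LOSO.
* `gpcr_classification` — receptors in sequence families (default 32 in 8
  families, last family dispersed); per receptor 100 actives clustered near
  a family chemical prototype and 75 + 25 diverse (presumed) inactives,
  labels from a latent pKi thresholded at 7.

Compound surrogates are random bit vectors so the module needs no
chemistry dependency; a SMILES-emitting mode routes end-to-end tests
through the RDKit featurizer.  None of the generators emulate real
assay-noise structure, activity cliffs or realistic SAR landscapes, so
passing benchmarks demonstrate that the *machinery* measures what it claims
under known ground truth — not that any descriptor set will win on a
particular laboratory dataset.

## Problem sizes used by the test suite and acceptance script

Descriptor-recovery runs use 200 dipeptides with 0.3 log units of noise and
ten 70–30 repeats at the peptide-only forest default (1000 trees); the
recovered mean R₀² is compared against the same pipeline with a
row-shuffled descriptor table (a bijective but physicochemically
meaningless code) on paired seeds.  The classification y-scrambling null
uses an 8-receptor, 400-record family panel with 200-tree forests — sized
so the fold-level MCC standard error (~0.03 for the 10-repeat mean) gives
adequate resolution against the ±0.1 null band.  Ordering checks use
10-target, 40-compound mutant panels at completeness 0.8 with 300-tree
forests.  These sizes are the package's choices for routine runs; all are
parameters.

## Numerical notes and limitations

* Everything is deterministic given seeds; sub-seeds are derived additively
  and stay below 2³¹.
* PCA components fix their sign by making each loading vector's
  largest-magnitude entry positive; constant columns are dropped with a
  warning.
* The neighbourhood-behavior statistic (mean |Δactivity| to the k = 5
  nearest items in score space, divided by the all-pairs mean) is a
  concrete, testable rendering of the Similar Property Principle; values
  below 1 indicate neighbourhood structure.  A constant activity vector is
  reported as ratio 1 with a degenerate flag.
* Exact ECFP reproduction is not attempted: any Morgan-style circular
  fingerprint of radius diameter/2 folded to the configured width satisfies
  the contract; bit-for-bit agreement across fingerprint software does not
  exist in general.
* Reported completeness is rounded both to 2 decimals and to the nearest
  percent, since published dataset tables round inconsistently; the raw
  ratio is always carried alongside.
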