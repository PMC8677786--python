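# Methods

## The problem

A phenotypic high-throughput screen on primary murine fibroblasts read
out two fluorescent reporters of myofibroblast activation — αSMA
promoter activity (RFP) and collagen α1(I) promoter activity (EGFP) —
as fold-over-control intensities (untreated control ≡ 1.0).  Such a
screen is bounded by its physical library (~640 compounds).  The
package implements the "dry" extension of that screen: learn a model
mapping compound structure to the two readouts, apply it to a much
larger candidate library, call hits predicted to reduce αSMA intensity
by at least 25%, filter unreliable predictions, drop compounds already
screened, and organise the survivors by structural similarity to known
drugs.

## Descriptors

Compounds are described by extended connectivity fingerprints (ECFP):
iteration 0 assigns each heavy atom a 64-bit hash of (element, degree,
attached-H count, formal charge, ring flag); iteration *r* re-hashes
each atom's previous identifier together with the sorted (bond-order
token, neighbour identifier) list; identifiers from all iterations are
folded into a binary vector by modulo.  Defaults are radius 2 and 2048
bits (the community-standard ECFP4 configuration); both are
configurable.  Notes:

* the hash is blake2b over a canonical byte string — deterministic
  across platforms and processes, independent of Python's hash
  randomisation;
* aromatic bonds carry their own order token (no Kekulé alternation),
  which keeps fingerprints invariant under atom relabelling;
* duplicate substructure environments are not removed before folding;
  folding into a binary vector collapses them anyway;
* stereochemistry is accepted on input and ignored (the iteration is
  achiral).

SMILES interpretation is delegated to RDKit behind `parse_smiles`; a
light pre-scanner reports offending positions for unbalanced branches,
ring closures and brackets, which RDKit's Python API does not localise.

## Model

The predictor is a bagging ensemble of multi-target predictive
clustering trees (PCTs).  A PCT splits on single fingerprint bits,
choosing at each node the bit that maximally reduces the summed
within-node variance of the *two-target vector*; leaves predict the
per-target mean (prototype).  Design points:

* **Normalisation.** Each target's variance is divided by its
  full-training-set variance so RFP and EGFP contribute comparably to
  the split criterion regardless of their dynamic ranges.  A
  zero-variance target falls back to scale 1.0 with a warning.
* **Variance convention.** Population (1/n) variance throughout, which
  makes the split search exactly reproducible by brute-force oracles.
* **Tie-breaking.** Equal variance reductions resolve to the lowest bit
  index, with a 1e-12 relative tolerance so float noise between
  mathematically equal reductions cannot flip the choice.
* **Stopping.** A node becomes a leaf when targets are constant, the
  depth cap is reached, or no split leaves `min_leaf` records in both
  branches.  A zero-reduction split is still taken when admissible:
  XOR-like target structure has no variance-reducing single bit yet is
  exactly representable at depth 2.
* **Defaults.** 100 trees, `min_leaf` 5, unlimited depth, bootstrap
  resampling of size n — conventional bagging settings at the n≈640
  scale of the screen; all configurable.
* **Randomness.** One root seed; per-tree seeds are spawned from a
  `numpy.random.SeedSequence`, so results are independent of evaluation
  order and bit-identical across reruns.

The ensemble prediction is the per-target mean over trees; the
per-target **population standard deviation of the individual-tree
predictions** is the per-prediction reliability score.  The two
targets' sds are kept separate; the screening stage chooses which to
filter on (default: RFP, the thresholded target).

## Evaluation

Performance is measured by mean absolute error under k-fold
cross-validation (default k=10; seeded shuffle, contiguous blocks,
remainder spread one-per-fold).  The aggregate MAE pools absolute
errors over all held-out predictions — well-defined under unequal
folds — with per-fold means reported alongside.  The reliability score
is validated by the Spearman rank correlation between per-prediction
sd and held-out absolute error (a monotone claim, hence a rank
statistic; ties take mid-ranks; a constant sd vector raises rather
than returning an arbitrary number).

## Screening and hit calling

* **Activity.** Predicted RFP ≤ (1 − 0.25) × control, boundary
  inclusive: a prediction of exactly 0.75 passes.  The threshold is on
  RFP only (the screen thresholds αSMA; collagen is predicted but not
  thresholded).
* **Reliability.** Keep compounds whose tree-sd is at or below a
  quantile (default 0.5 — the more reliable half) of the sd
  distribution over the full prediction set.  This is a deliberately
  parameter-light reading of "filter the weak predictions";
  all-equal sds degenerate to everyone passing.
* **Novelty.** Compounds whose fingerprint identity key equals a
  training compound's are excluded; candidate-internal duplicates keep
  the first occurrence.
* **Grouping.** Each surviving hit is assigned to the reference drug
  with maximal Tanimoto similarity if that maximum reaches τ = 0.4,
  else labelled "other"; ties resolve by panel order.  This replaces an
  online grouping tool whose coefficient and cutoff are not
  reproducible from any published description; max-Tanimoto
  nearest-reference assignment is standard ligand-based practice.
  Clinically-approved versus novel status comes from per-reference
  metadata flags, not from querying any registry.  An optional
  label-based exclusion list (e.g. a pharmacologically disqualified
  class such as corticosteroids) is supported and off by default.

## Synthetic data

The original screen's data are not deposited, so a generator stands in
for them with the statistical structure the analysis assumes:

* molecules are assembled by concatenating 1–4 fragments from a small
  organic-subset grammar (every assembled string is a valid SMILES);
* a sparse ground truth attaches effects to k=3 fingerprint bits;
  carrying a bit lowers expected RFP/EGFP by its effect size (drawn
  0.3–0.6, shared latent + 5% jitter so the two targets' effects are
  positively correlated, echoing the coupled αSMA/collagen phenotype);
* intensities are baseline 1.0 + additive N(0, σ) noise, clipped at 0;
  default σ = 0.08 per target, chosen to echo the error scale reported
  for the original model;
* default training size is 640 compounds over 2048-bit radius-2
  fingerprints — the size of the original screen.

Effect bits are drawn from bits with library prevalence in
[0.03, 0.15] that are the lowest-indexed representative of their
perfect-correlation class.  Rationale: a fragment substructure sets
several perfectly co-occurring bits (its identifiers at different
radii); attaching the effect to the class representative makes "which
bit does the root split on?" a well-posed question under the
lowest-bit tie rule, and the prevalence band keeps actives learnable
(≥ ~20 carriers at n=640) while rare enough that enrichment among hits
is measurable.

The heteroscedastic scenario (for reliability diagnostics) assigns
noise σ = 0.20 to compounds carrying the fingerprint bit whose library
prevalence is closest to 0.5, and σ = 0.02 to the rest.  The stratum is
structure-linked on purpose: tree disagreement for a test compound
reflects the target noise of its structural neighbours, which is
exactly the association the reliability score is meant to capture; an
unstructured random split of the library would leave tree variance
uninformative by construction.

**What the generator does not emulate:** realistic medicinal-chemistry
property distributions, activity cliffs from latent 3-D chemistry,
assay plate effects, dose–response, or cytotoxicity.  Because effects
live on fingerprint bits, the model class can represent the ground
truth exactly; passing tests therefore demonstrate that the pipeline's
machinery is correct and calibrated, not that this model class
generalises to any particular real screen.

## Numerical choices and problem sizes

* Split search is vectorised (sum/sum-of-squares per bit via one
  matrix product) and checked against a definitional per-bit
  implementation and an exhaustive oracle.
* Quantiles use numpy's default linear interpolation.
* CSV outputs use a fixed float format; reports omit filesystem paths
  so a rerun under the same seed regenerates every output
  byte-identically.
* Test and acceptance runs use the default study sizes (640 training
  compounds, 5,000-compound candidate libraries, 100-tree ensembles,
  10-fold CV) for the headline checks, and smaller instances
  (n = 40–200, 128–1024 bits, 5–50 trees) for unit-level contracts.

## Known limitations

* The grown trees are unpruned; with `min_leaf` 5 they chase noise in
  deep branches, which is conventional for bagging but makes single
  trees poor predictors on their own.
* The SMILES dialect is whatever RDKit accepts; molecules RDKit cannot
  sanitise are rejected rather than coerced.
* The reliability filter is a quantile rule relative to the screened
  library, so a compound's pass/fail status depends on the library it
  is screened with.
* Reported MAEs on synthetic screens characterise the generator's
  conditions, not the original wet screen, whose data and intensity
  scaling are unavailable.
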