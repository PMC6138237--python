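# Methods

`targetfish` implements a two-stage, ligand-based workflow for proposing
and triaging protein targets of a small molecule from its 2D structure:
an unsupervised target-fishing stage (consensus self-organizing maps over
pharmacophore autocorrelation descriptors) followed by a supervised
affinity-regression stage (per-target random forests with a
variance-penalized, floored report). This note records the models, the
parameters that matter, the numerical conventions, and what the synthetic
data used by the tests does and does not establish.

## Molecular graphs and pharmacophore typing

SMILES parsing, sanitisation, aromaticity perception and implicit-hydrogen
assignment are delegated to RDKit (its default aromaticity model); the
package then works on its own light-weight heavy-atom graph. Multi-fragment
inputs are reduced to the largest heavy-atom fragment, because counter-ions
and solvents corrupt autocorrelation counts. Molecules are typed *as
written*: no pH-dependent protonation-state or tautomer enumeration is
performed, trading realism for reproducibility (the quinone/hydroquinone
redox pair of the worked example is handled as two explicit input
structures).

Each atom receives a subset of six pharmacophore-point labels
{D, A, P, N, L, R} from a deterministic rule table over element, formal
charge, aromaticity, hydrogen count and bonded neighbourhood (see
`molgraph.assign_ppp` for the exact rules). Two conventions worth calling
out:

* pyrrole-type aromatic N–H, amide N and aniline-type N are *not*
  acceptors, while pyridine-type aromatic N is;
* both oxygens of a carboxylate carry the negatively-ionizable label
  (delocalisation), but only the hydroxyl oxygen of the *neutral* acid
  does.

These rules are in the spirit of published pharmacophore-pair typing but
are not guaranteed to coincide with any proprietary implementation; they
are fixed, documented and unit-tested, which is what descriptor
reproducibility requires.

## CATS2 descriptors

The descriptor autocorrelates label pairs over topological (bond-count)
distances 0–10, giving 21 unordered type pairs × 11 distance bins = 231
entries. Conventions:

* pairs are unordered and counted once; at distance 0 an atom pairs with
  itself, so a dual-typed atom (e.g. a {D, A} hydroxyl) contributes to the
  DA bin at d = 0;
* distances beyond 10 bonds are ignored, not folded into the last bin;
* default scaling is *occurrence* scaling: each entry is divided by the
  summed incidence of its two types (for a same-type pair this is twice
  the type's incidence; 0/0 is defined as 0). Raw counts remain available
  and are what the brute-force oracle tests compare against.

The serialized layout is pair-type-major ("DD_0" … "RR_10") and validated
on read.

## Consensus-SOM target fishing

A jury of 10 Kohonen maps (default 12×10, toroidal), identical except for
their seeds, is trained on the reference library's descriptors by online
learning: per sample, the best-matching unit (BMU) and a Gaussian
neighbourhood update, with learning rate decaying linearly 0.5 → 0.01 and
neighbourhood width max(w, h)/2 → 0.5 across epochs (default 20). BMU
ties break to the smallest (row, col). Training is bit-reproducible per
seed; jury member seeds are spawned from one global seed.

A query's per-target consensus score is the jury mean of distance-weighted
support: every reference ligand sharing the query's BMU contributes
1/(1 + Euclidean distance) to each of its annotated targets. Plain
co-occupancy counts would ignore within-neuron spread; the weighting makes
a tight neighbour worth more than a loose one.

Confidence is empirical: decoy queries are scored identically, each decoy
contributing the score of its best-supported target (0 if it co-clusters
with nothing), and a query target's p-like value is
(k + 1)/(n + 1) with k the number of decoy scores at least as large.
Higher support ⇒ smaller p-like; the add-one smoothing keeps the value in
(0, 1], so the tool never claims p = 0. At least 100 decoys are required;
the pipeline default is 200 random sparse non-negative vectors.

## Affinity regression

Bioactivity records (IC50, EC50, Ki, Kd; M to pM) are normalized to
p_Affinity = −log10(molar value); the four endpoint types are pooled per
target without offset correction. Curation drops qualified records
(relation `<` or `>`), aggregates replicates by median, and emits a
per-target dataset only when ≥ 30 compounds remain spanning ≥ 2 log units
(defaults; both configurable). A model trained on fewer compounds, or on a
narrow activity band, mostly memorises assay noise.

Per target, a random forest (500 trees, 16 ≈ ⌈√231⌉ features per split,
bootstrap sampling, unscaled descriptors) is fitted. A prediction reports

    penalized = mean(tree predictions) − Var(tree predictions),

with Var the population variance over trees — the ensemble's per-query
disagreement, the only uncertainty available at prediction time. Penalized
values below 4.0 (weaker than 100 µM) are reported as the string "<4.0":
in that regime the model extrapolates outside the potency range worth
reporting, and the floor is applied exactly at 4.0. The ensemble mean is
always inside the training-label range, so `penalized ≤ mean` and the
report can never overstate potency relative to the ensemble.

Quality is assessed by stratified 10-fold cross-validation: labels are
binned into 1-log-unit strata anchored at integer p_Affinity, bins with
fewer than k members merged into their nearest populated neighbour, and
folds drawn to preserve stratum proportions within one entry. The metric
is the per-fold mean absolute error (MAE, log10 units), reported as
mean ± sd over folds.

Ligand efficiency is 1.37 × p_Affinity / heavy-atom count
(kcal·mol⁻¹ per heavy atom; 1.37 ≈ 2.303·RT at 298 K), with > 0.30 the
conventional efficiency bar.

## Synthetic data: what it emulates, what it does not

The generators produce data with the statistical structure the pipeline
assumes, directly in descriptor space — separating descriptor-engine
correctness (checked on real fixture molecules against brute-force
oracles) from learner correctness (checked on planted structure):

* **Planted libraries** — each target a Gaussian cluster around a sparse
  non-negative centroid (30 active dimensions, uniform 0.1–1), default 5
  targets × 50 ligands, spread σ = 0.05, minimum centroid separation
  5 × σ. At that separation nearest-centroid assignment is ≥ 99 % correct,
  so jury retrieval failures indict the SOM stage, not the geometry.
* **Simulated SAR sets** — compounds drawn from a mixture of 20
  "chemotype" clusters (centroid spread 0.1), latent label a sparse linear
  map of 3 descriptor entries (weights 3.0/−2.5/2.0, intercept 6) plus
  Gaussian noise σ = 0.3, clipped to [3, 10]; default n = 500. The
  chemotype mixture mirrors how real per-target bioactivity sets are
  dominated by a few chemical series rather than unrelated singletons.
  Labels are emitted as raw records with mixed units (µM/nM), random
  endpoint types and an optional censored fraction; uncensored records
  round-trip through normalization to the latent label exactly.

Passing tests on these data show that the pipeline recovers structure it
is designed for, under its own assumptions. They do **not** show
performance on real bioactivity data: real descriptors are correlated in
ways the generators ignore, real labels carry inter-assay and inter-lab
systematic error (not i.i.d. Gaussian noise), activity cliffs break the
local-smoothness the chemotype mixture provides, and real target classes
share ligands. The cross-validated MAE on simulated data (≈ 0.25–0.35 log
units at the default settings) is therefore a lower bound on the error
regime, not an estimate of production accuracy.

## Numerical and experimental choices

* All stochastic components are seeded; global seeds are spawned into
  per-component seeds via `numpy.random.SeedSequence`, so an identical
  configuration and seed reproduce every output byte for byte.
* Descriptor vectors are clipped at 0 after noise addition (CATS entries
  cannot be negative).
* The planted-cluster retrieval experiment in the acceptance tests uses a
  jury of 10 maps, 15 training epochs, 150 decoys and 5 generator seeds,
  holding out 10 ligands per target; the cross-validation experiments use
  200-tree forests inside the CV loop and 5 generator seeds at n = 500
  (signal) and 3 seeds at n = 400 (pure noise). These sizes keep the full
  experiment battery comfortably reproducible on a single CPU while
  leaving the conclusions unchanged at larger settings.
* The uninformative-predictor reference for CV quality is σ̂·√(2/π), the
  closed-form MAE of a Gaussian around its mean, with σ̂ the empirical
  label standard deviation of the dataset under test.
* The pipeline shortlist threshold is p_like ≤ 0.05 by default — targets
  whose support exceeds ~95 % of decoy scores proceed to affinity
  regression; it is a configurable screening choice, not a significance
  claim.

## Known limitations

* Typing rules are fixed heuristics; no parity with proprietary
  pharmacophore typers can be asserted.
* No stereochemistry, 3D conformation, or tautomer handling.
* "Variance" as the ensemble-spread penalty is one defensible
  operationalisation among several (CV variance and ensemble SD are
  alternatives); it is the only one computable per query at prediction
  time.
* The SOM jury's p-like value is calibrated against synthetic decoys; with
  decoys drawn from a different chemical space the absolute p-like scale
  shifts, though rankings are stable.
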