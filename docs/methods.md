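# Methods

This note documents the models implemented in `rmlm`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not establish about behaviour on real data.

## Heterogeneous network and meta-paths

The network has two node types (miRNA, gene) and three base relations:
miRNA–miRNA functional similarity `sim` (dense, entries in [0, 1]),
gene–gene protein interaction `ppi` (binary, symmetric), and the
miRNA–gene link relation `regulate` (binary; 0 means *unknown*, not
absent). Registering a relation also registers its inverse (transposed
weights, name suffixed `^-1`), so meta-paths can traverse links backwards.

Meta-path enumeration returns every type-consistent loop from a node type
back to itself up to a maximum length (default 3, giving 8 loop paths per
side and 64 composite channels). Two choices here are deliberate:

* **The empty (identity) path is included.** The composite with empty
  sides reduces to the direct link relation itself, which must be one of
  the feature channels.
* **Inverse aliases of symmetric same-type relations are skipped during
  enumeration.** `ppi^-1` carries exactly the weights of `ppi`; keeping
  both names would enumerate every path through that relation twice and
  duplicate feature columns.

Channels are ordered canonically (path length, then lexicographic on
relation names; miRNA-side paths outer, gene-side inner), fixing feature
column identity across runs. Weighted path counts are ordinary matrix
products; continuous `sim` weights enter the products as-is.

## Disease-derived miRNA similarity

`SM` follows the MISIM best-match scheme over a MeSH-style hierarchy. A
disease contributes 1 to itself and `Δ` times the best contribution among
its in-closure children to each ancestor (`Δ` defaults to 0.5, the
standard choice, configurable). The similarity of two diseases is the sum
of both contribution profiles over their shared ancestor closure divided
by the sum of their total semantic values; two miRNAs are compared by
best-match averaging across their disease sets. A term occupying several
hierarchy positions uses the union of its ancestor closures. miRNAs whose
disease set is empty after mapping are rejected at load time, because the
best-match average is undefined on an empty set — silently assigning
similarity 0 would hide a data problem.

## RM relatedness

For a candidate pair, each channel divides the expected weighted path
count through the observed central links by the count that would be
realised if *every* central link existed. The denominator is computed as
an outer product of row sums and column sums (never by materialising the
all-ones matrix), which is exact and keeps the computation tractable at
realistic scale (hundreds of miRNAs by thousands of genes). Cells where
the denominator is 0 — a node isolated under the meta-path, so no evidence
either way — are scored 0, preserving the [0, 1] contract.

## Link model

The logistic posterior has no intercept by default: all RM channels are
already on a common [0, 1] scale, and an `include_bias` flag exists for
callers who want one. Weights are fitted by maximising the Bernoulli log
likelihood minus `ridge · ‖ω‖² / 2`:

* **Solver.** Damped Newton iterations (analytic gradient and Hessian,
  backtracking line search) from a zero start, fully deterministic. The
  Hessian is cheap at ≤ 67 features, and Newton handles the strong
  collinearity between meta-path channels that makes quasi-Newton methods
  stall short of tight gradient tolerances.
* **Ridge default 1e-4.** The unpenalised MLE does not exist on linearly
  separable data; a tiny ridge guarantees a maximiser while leaving the
  optimum essentially unchanged on non-separable data. `ridge = 0`
  reproduces the literal likelihood.
* **Separability detection.** On separable data the *gradient* of the
  unpenalised likelihood vanishes asymptotically as the weights grow, so a
  gradient-norm test cannot flag non-existence. After convergence at
  `ridge = 0` the fit therefore checks the margin criterion: if the fitted
  direction separates the classes strictly, scaling it up would increase
  the likelihood without bound, and a `FitDivergedError` is raised instead
  of returning a silently truncated iterate.
* **Negative training examples** are sampled uniformly from unknown
  (weight-0) pairs at a configurable positive:negative ratio (default 1:1)
  with a seeded generator.

Final scores are posterior percentiles with non-strict comparison
(`p_i ≥ p_j`, self included): ties share the higher percentile, every pair
scores at least 1/n, and the maximum is exactly 1. The percentile is
invariant under any strictly increasing transform of the posteriors.

## Cross-validation protocol

Known positives are split into k (default 5) seeded folds of near-equal
size. Per fold, the held-out positives are zeroed in the link relation
*and its inverse*, the full RM stack is recomputed from the masked
network (a guard asserts every held-out link really is invisible), the
model is fitted on the remaining positives plus sampled unknown pairs,
and the held-out positives are scored against unknown test pairs drawn
from the same miRNA rows. `SM` is not recomputed per fold — only the
miRNA–target links are hidden.

Open points resolved here:

* **Test negatives** are all-unknown pairs restricted to the evaluated
  miRNAs, subsampled to 10× the fold's positives. They are drawn *before*
  the training negatives and capped at half the unknown pool, so that on
  densely linked networks training always retains its own negatives.
* Both per-fold mean AUC and a pooled ROC over all folds are reported.
* Training positives keep their own link in the masked network, so their
  features are computed with the link present while held-out features are
  not. This train/test feature shift is inherent to the protocol (only
  the *held-out* fold is hidden) and is the main reason cross-validated
  AUCs on planted studies sit modestly above chance rather than near the
  within-sample discrimination.

## Sequence evidence

RMLMSe appends three binary columns in fixed order (TargetScan, miRanda,
PITA). The filters are hard and strict: `Pct > 0.9`, `mirSVR > 0.6`, and
PITA top-list membership. Scores from the three tools are not
commensurable, so membership indicators, not raw scores, enter the model.
mirSVR scores are conventionally negative (more negative = stronger
predicted downregulation); the literal signed comparison is the default
and an `abs_mode` flag compares magnitudes instead — the choice is
surfaced rather than guessed. Evidence pairs whose identifiers do not
resolve to catalog entries are ignored with a logged count.

## Synthetic studies

The generator emulates the *shapes* of real inputs at desk scale (default
60 miRNAs × 120 genes × 20 diseases): a random disease hierarchy (each
non-root term gets 1–2 earlier parents), 1–4 diseases per miRNA, `SM`
built from those profiles exactly as for real data, and a symmetric
binary PPI at 5% density. Links are planted in two stages, resolving the
circularity that RM features are themselves functions of the link matrix:
a seeded 5% of cells forms an initial adjacency, RM features are computed
from it, and every remaining cell is drawn Bernoulli with its logistic
posterior under known planting weights. The study records the
planting-time features and draws, so weight recovery can be checked
against the exact regression the links came from.

The default planting weights put signal on four weakly correlated
channels (mixed signs, magnitudes 12–18, link rate ≈ 0.38). Meta-path
channels are strongly collinear in general — powers of `SM` differ
little — and planting weights spread across collinear channels would be
unidentifiable from a single study regardless of implementation quality;
the default is chosen so the planted direction is recoverable. For the
same reason the recovery experiment fits with `ridge = 0.3`, which
suppresses noise in near-null feature directions; the reported quantity
is the cosine between fitted and true weight vectors (≥ 0.9 across
studies).

What the synthetic studies do **not** show: real miRNA–target networks
have heavy-tailed degree distributions, block structure from miRNA
families, and far sparser links than the logistic planting scheme
produces; absolute AUC values on planted studies therefore say nothing
about AUC on curated data. What they do show is that every stage is
correct against independent oracles and that the pipeline recovers
planted signal above chance under a leakage-free protocol.

## Numerical choices

* Posteriors use `scipy.special.expit` and `logaddexp`; no overflow for
  any logit.
* RM quotients are clipped to [0, 1] only to absorb float round-off where
  numerator ≈ denominator.
* Percentiles use max-rank (`scipy.stats.rankdata(method="max")`),
  matching the non-strict counting definition including ties.
* All randomness (fold splits, negative sampling, generators) flows
  through `numpy.random.default_rng` seeded from explicit integers; runs
  are bit-reproducible given their configuration.

## Problem sizes

Tests and the acceptance script run on 60 × 120 planted studies (7200
candidate pairs, 64 channels), with oracle comparisons on networks of ≤ 8
nodes per type where brute-force path enumeration is exact. These sizes
give stable statistics for every property checked while keeping the whole
suite in the seconds range.

## Known limitations

* Only two node types; extending the schema (e.g. lncRNAs, diseases as
  first-class nodes) would need new catalogs but no new machinery.
* The RM stack is recomputed per fold from scratch; at the scale of real
  catalogs (≈ 500 × 13,000) this is the dominant cost and would benefit
  from sparse matrix products.
* Nodes with many neighbours accumulate more paths, which can bias
  relatedness toward hubs; no degree correction is applied.
* The positive:negative sampling scheme is a modelling choice; class
  balance affects posterior calibration (though not the percentile
  ranking for a fixed candidate set).
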