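# Methods

## Model

A nonapeptide is represented by contact-averaged pairwise potentials.
For potential `k` (a symmetric 20×20 matrix `E_k` over residue types) and
peptide position `i ∈ 1..9`:

    S_k,i = T_i(u_i) · [ Σ_{j: δ_ij = 1} E_k(u_i, v_j) ] / |{j : δ_ij = 1}|

where `u_i` is the peptide residue, `v_j` the HLA residue at position
`j`, `δ_ij` the peptide–HLA contact indicator, and `T_i(a)` the rescaled
position-specific score. The encoded vector has `9K` entries laid out in
feature-major blocks: element `9(k−1)+i` (1-based) is `S_k,i`. The
assumptions are those of the encoding itself: contacts are a fixed
per-allele template (not peptide-specific), the potential of a contact
pair depends only on residue types, and positions contribute
independently apart from the shared classifier.

Two reference encoders exist for comparison: position-major one-hot
(20 slots per position, 180 features) and per-residue descriptor tables
(`9d` features for a 20×d table, laid out like the capo scheme).

### Positional-score rescaling

Raw positional matrices score *lower = better*. They are negated and
mapped affinely, **globally over all 9×20 entries**, onto [1, 10]:

    T' = 1 + 9 · (−T − min(−T)) / (max(−T) − min(−T))

Both endpoints are attained exactly (pinned against floating rounding);
the ordering of any two entries is reversed relative to the input. The
target range is configurable but must exclude zero — a zero weight would
annihilate the contact term and lose information. The map is global
rather than per-row so that scores remain comparable across positions; a
per-row map would equalise the dynamic range of positions that genuinely
differ in importance. A constant input matrix is rejected (the map is
undefined).

### Labels

Binder iff IC50 < 500 nM, strictly; the cutoff is a parameter with that
default. IC50s must be positive and finite.

## Classification

Soft-margin SVM with RBF kernel, cost C = 1, continuous decision values;
hard calls at score > 0. Features are standardised with mean/sd learned
from the training fold only (disable with a flag). The kernel width is
not part of the printed protocol, so the default is the median-pairwise-
distance heuristic on the standardised training fold (γ = 1/(2·median²),
deterministically subsampled above 512 points); a fixed width can be
supplied instead. An `epsilon` setting (0.1) is accepted for interface
compatibility with regression-capable SVM front-ends and ignored in
classification, with a log note. The backend is scikit-learn's `SVC`.

Metrics: ACC, sensitivity, specificity and F1 follow the standard
confusion-count formulas and are computed exactly; undefined denominators
raise instead of silently returning 0. AUC is the rank-based
(Mann–Whitney) area, ties counting 1/2 — equivalently the probability
that a random binder outscores a random non-binder.

Cross-validation: repeated stratified k-fold (default 20 iterations of
5-fold). Each iteration draws a fresh stratified partition from
(seed, iteration); out-of-fold decision scores are pooled into **one AUC
per iteration**, and the mean ± sd over iterations is reported. Pooling
(rather than averaging per-fold AUCs) was an open choice; it is the
definition here because a single ranking over all held-out records is the
quantity the per-allele AUC summarises. All fold assignments and model
fits derive from the seed, so results are exactly reproducible.

The paired t-test used to compare methods is classical; zero-variance
differences are handled by convention (equal means → p = 1; unequal
means → the p → 0 limit, flagged degenerate).

## Feature selection

**Potential-subset search.** The encoded dataset splits into K blocks of
9 columns. Each block's solo cross-validated AUC is computed; blocks are
ranked (descending AUC, ties by id ascending) and every prefix of the
ranking is evaluated **with the same CV seed**, so prefix curves differ
only by features, never by fold noise. The AUC-maximising prefix is kept;
argmax ties take the shortest prefix (parsimony). Prefix evaluation uses
a single 5-fold repetition by default (configurable) — the full 20×5
protocol multiplies cost by 20 without changing the argmax in practice.

**Relief-F.** Implemented natively in the Weka dialect: every instance is
sampled; for each record the k = 10 nearest hits and, per other class,
k nearest misses are found by Manhattan distance on range-normalised
features, neighbour ties broken by record index; weights update by

    W[f] ← W[f] − Σ_hits diff/(m·k) + Σ_C P(C)/(1−P(class(R))) Σ_misses diff/(m·k)

with `diff(f, x1, x2) = |x1_f − x2_f| / (max_f − min_f)`. Constant
features get weight exactly 0. Because diffs are range-normalised, the
weights are invariant under affine rescaling of any single feature. A
class smaller than k+1 raises with a suggestion to reduce k. "Feature
importance under 5-fold cross-validation" is interpreted as averaging the
fold-wise Relief-F weight vectors over the 5 training folds; the averaged
ranking then feeds the same fixed-seed prefix search as above.

## Proteome scanning

Proteins are cut into all length-9 windows (1-based starts); windows
containing special or ambiguous letters (B, Z, J, U, O, X) are skipped
and counted, since contact potentials are undefined for them. Each
distinct peptide is scored once per allele model and the score fanned out
to all occurrences. A peptide is a promiscuous candidate iff it is
predicted positive (decision score > 0; an optional stricter threshold
exists) for at least `min_alleles` alleles and occurs — by exact 9-mer
identity, no fuzzy matching — in at least `min_strains` strains. Output
is sorted by (allele count desc, strain count desc, peptide asc) and is
independent of input hit order.

## Synthetic data

The generator emulates the *shape* of each real input: symmetric
potentials with Uniform(−2, 2) entries (lower triangle drawn, mirrored),
an HLA protein of length 275 (the approximate heavy-chain region holding
the binding groove; cosmetic, since only contacted positions matter),
3–6 contacts per peptide position, and a Normal(0, 1) positional matrix.
One global seed fans out to per-component streams by fixed offsets, so
each component regenerates independently and bit-identically.

Labels carry a planted signal *through the true encoding*: peptides are
uniform over the 20 residues; a latent score `z = β·(x_std·w) + ε` uses
the standardised encoded features, a sparse unit-norm weight vector `w`
(support = one 9-block for block-signal fixtures, otherwise a random
fifth of the features), and ε ~ Normal(0, noise_sd). IC50s follow
`log10(IC50) = a − z` with `a` solved against the empirical quantile of
`z` so the binder fraction (IC50 < 500 nM) matches the requested value.
Defaults — K = 5 potentials, n = 1000 peptides, binder fraction 0.5,
β = 5, noise sd 0.1 — are the study conditions used throughout the tests
and the acceptance script; block-selection experiments use n = 600.

What passing tests do *not* show about real data: generated peptides have
no anchor-position motif structure and IC50s no realistic affinity
distribution, so recovery results demonstrate correctness of the
machinery (encoding, CV, selection, scanning), not predictive performance
on real HLA data. One consequence worth knowing: features at the same
peptide position are correlated across potential blocks (each is a scalar
function of the same residue), so off-signal blocks score above chance
and Relief-F may rank a few correlated off-block features into the top
of the list — the signal block still ranks first and its features have
better mean rank.

## Numerical choices

* Potential symmetry is exact by construction (mirroring at parse time),
  so the symmetry check uses equality, not a tolerance.
* TSV writers print 17 significant digits and readers parse with
  round-trip float precision, making write→read the identity.
* Rescaled positional matrices pin their endpoints to exactly 1 and 10.
* Missing (`-`/`NA`) potential cells are rejected, not imputed — no
  imputation rule is defined for contact potentials.
* CV iteration seeds derive from (seed, iteration) by a fixed affine map
  mod 2³¹−1; the median-heuristic subsample is seeded by the classifier
  seed.
* Relief-F neighbour ties break by record index; ranking ties by feature
  index; all argmax ties by the smaller index.
* Degenerate inputs fail loudly: single-class training sets, constant
  positional matrices, classes too small to stratify or to supply k+1
  Relief-F neighbours, undefined sensitivities/specificities.

## Known limitations

Only length-9 peptides are supported (the encoding is position-indexed
1..9); contact maps are consumed as files, never derived from structures;
descriptor *value tables* (DPPS, FASGAI, z-scales, ISA/ECI) are not
shipped — the descriptor encoder takes any 20×d table; probability
calibration, non-RBF kernels and hyperparameter search are out of scope
(C = 1 is fixed by the protocol).
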