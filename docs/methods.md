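# Methods

## Model overview

The pipeline rests on three assumptions. First, that a drug's effect on a
cell is better summarized at the pathway level than at the gene level, so
single-sample enrichment scores over gene sets — computed separately for
expression, methylation and copy number and then concatenated — are the
feature space. Second, that drug response decomposes additively into a
global mean, a drug offset, a cell-line offset and a low-rank interaction
between drug latents and projected cell-line features. Third, that two
drugs whose predicted response profiles correlate with pathways in the same
way (high Pearson correlation of their drug–pathway correlation vectors)
are candidates for mutual replacement, independently of chemical structure
or target proximity.

## Single-sample enrichment scoring

For a sample with N measured genes, ranks are **ordinal integers 1..N**
with the largest value receiving rank N and ties broken by input order.
Ordinal (rather than average) ranks keep the member weight normalization
`Σ_{j∈G} r_j^α` exact and make scores reproducible bit-for-bit; the same
rule is used by the brute-force oracle in the test suite. The enrichment
score is the plain sum of ECDF differences — no division by the score
range — so its magnitude grows with N; this is intentional, as downstream
consumers only use Pearson correlations of the scores, which are invariant
to affine rescaling per pathway.

Numerical/degenerate-input choices:

* Genes missing (NaN) in a sample are dropped from that sample's universe
  before ranking; N is per-sample.
* A gene set must intersect the measured genes (N_G > 0) and leave a
  non-empty complement (N_G < N); violations raise errors rather than
  returning a conventional value.
* A set is eligible on a layer iff ≥ `min_overlap` (default 5) members are
  measured there. The default is a conventional floor below which
  enrichment scores of small sets are dominated by single genes; it is
  configurable because real gene-set collections vary widely in overlap
  with measured genes.
* The weight exponent α defaults to 0.25. Values are ranked as-is;
  `absolute=True` ranks by magnitude for signed layers (methylation betas
  and absolute copy numbers are non-negative, so the default applies them
  unchanged).
* Duplicate gene ids are aggregated by mean (expression, CNV) or sum
  (methylation) before scoring; the operation is idempotent.

## Recommender

Parameters and defaults, with reasons:

| parameter | default | meaning |
|---|---|---|
| `f` | 10 | latent dimension of drug vectors and projected features |
| `mu` | observed mean | global mean response, held fixed (configurable) |
| `learning_rate` | 0.01 | initial gradient step |
| `max_epochs` | 5000 | full-batch epochs budget |
| `tol` | 1e-8 | relative loss-change convergence criterion |
| `l2` | 0 | optional ridge on q and W; the plain loss has no penalty |
| `seed` | required | initializes q, W ~ normal(0, 0.1); biases start at 0 |

The loss `L = (1/2K) Σ_observed e²` excludes missing entries entirely: the
residual matrix is zeroed on unobserved cells before any gradient, so
values placed in masked cells can never influence the fit (a property the
tests check bit-for-bit). The optimizer is full-batch gradient descent with
a backtracking step: a step that would increase the loss is halved until it
does not (growing ×1.1 after each accepted epoch). A fixed step cannot
guarantee the monotone non-increasing loss trace the package promises,
which is why backtracking was chosen over a constant learning rate; the
initial step remains 0.01. Non-convergence within the epoch budget returns
the best-so-far model with a warning rather than failing.

The model is gauge-non-identifiable (scaling W up and q down leaves
predictions unchanged), so recovery is assessed on *predictions*, not on
individual parameter matrices.

### NDCG

DCG uses gain `(2^s − 1)/log2(rank + 1)`, 1-based ranks, both orderings
(model and ideal) breaking ties stably by input position — using the ideal
order to break prediction ties would silently inflate scores. Because
−log10(IC50) relevances can be negative (making `2^s − 1` negative and the
ratio unbounded), relevances are shifted by their per-cell-line minimum to
be ≥ 0 by default; `shift_relevance=False` restores the raw reading. A
constant relevance vector carries no ranking information and is defined to
score 1. Both the per-cell-line mean NDCG (reported as the headline) and a
pooled variant over all observed pairs are computed, since the literature
is split on the convention.

## Similarities

* Functional: Pearson correlations throughout; a zero-variance vector
  (constant drug profile or pathway row) yields correlation 0 with a
  warning instead of NaN, keeping matrices finite. Predicted — not
  observed — drug activity is the default input to the drug–pathway
  correlation, with the observed matrix usable by passing it explicitly.
  The functional similarity is reported raw in [−1, 1]; apply `(x+1)/2` if
  a (0, 1) view is needed for cross-measure plots. Thresholding uses raw
  values.
* Structural: the fingerprint type is not dictated by the method, so the
  package defaults to RDKit's path-based binary fingerprint (2048 bits)
  with a Morgan (circular, radius 2) alternative; the choice is recorded in
  the run config. Unparseable SMILES exclude the drug with a warning.
* Target distance: D is the minimum over all cross pairs of target genes of
  the **unweighted** shortest-path length (a shared target gives D = 0 even
  when the gene is absent from the network); S = A·e^(−bD) with A = 0.9,
  b = 1; self-similarity is 1 by convention and unreachable pairs take the
  D→∞ limit 0. PPI edges may carry a STRING-style combined score and are
  kept iff ≥ `ppi_min_score` (default 700/1000, STRING's customary
  high-confidence cutoff). Published tables derived from weighted STRING
  distances can show vastly smaller similarities (e.g. ~1e−70) than the
  integer-path reading produces; this package implements the integer-path
  reading and documents the discrepancy rather than guessing the weighting.
* Pair selection keeps unordered pairs strictly above the threshold
  (default 0.95), sorted by descending similarity, and reports the total
  n(n−1)/2 for context.

## Synthetic fixtures

The generator emulates the pipeline's input shapes and the statistical
structure each stage needs, at desk scale: 60 genes × 20 cell lines, 10
drugs, 8 gene sets of 6 genes, rank-2 latent structure, no noise and no
missingness unless requested. These sizes are the smallest at which
correlations, enrichment scores and the factorization are all
non-degenerate while the full pipeline stays sub-minute. Expression is
lognormal with the first gene set shifted up in half the samples (so
enrichment scores must separate the groups); methylation is a logistic
transform of Gaussians, confined to (0, 1); copy number is Poisson(2)
counts. Responses are drawn *exactly* from a seeded ground-truth
factorization model, optionally plus Gaussian noise and random masking, so
training can be checked as a recovery problem. The chemistry table cycles
real parseable SMILES; the PPI network is Erdős–Rényi with a planted
shared-target drug pair (distance 0) and a drug targeting an isolated gene
(disconnected pair). All draws flow through per-purpose
`numpy.random.default_rng([seed, k])` streams, so every artifact is
bit-reproducible under one seed.

What the fixtures do **not** emulate: realistic marginal distributions of
GDSC/CCLE data, batch effects, probe-level artifacts, correlated
missingness, or the scale (hundreds of drugs, ~900 cell lines, 250
pathways). Passing tests therefore demonstrate correctness of the
computations and internal consistency of the pipeline — not predictive
performance on real panels.

## Known limitations

* The trainer is full-batch and dense; panels of GDSC scale (250 × 904)
  are fine, but much larger matrices would want a minibatch or ALS variant.
* NDCG gains are exponential in relevance; after min-shifting, relevance
  ranges above ~30 would overflow double precision. Real −log10(IC50)
  ranges (a few units) are far below this.
* The functional similarity inherits any bias of the recommender: drugs
  predicted poorly get noisy pathway-correlation vectors.
* Cross-validation utilities are per-cell-line leave-out only; no default
  split is imposed.
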