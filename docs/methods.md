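# Methods

## Probe mapping

Probes are genomic intervals in BED convention (0-based, half-open).
The distance between two probes is the absolute difference of their
interval centers, `(start + end) / 2`, kept as an exact half-integer —
no rounding, so results cannot drift across platforms or file round
trips.  For each probe the nearest same-gene, same-chromosome probe of
the other platform is found; a pair is a *mutual best match* when the
relation is reciprocal.  Probes with no same-gene counterpart yield no
pair rather than a cross-gene match.

Deterministic choices where the underlying convention is genuinely
open:

* **Equidistant candidates** are resolved by smaller start coordinate,
  then lexicographically smaller probe id.  Any rule would do
  scientifically; this one is reproducible and order-independent.
* **"Within 1000 bp" is inclusive** (≤ 1000).  The applied filter is
  recorded on the mapping table (`filter_record`) so the convention is
  auditable in every output file.
* Probes spanning multiple genomic blocks are taken as the single
  spanning interval supplied in the input BED; multi-block resolution
  belongs to the upstream aligner.

The production matcher groups probes per (gene, chromosome) and runs a
vectorized nearest search; the test suite holds it to exact agreement
with an exhaustive O(n²) oracle on hundreds of random instances.

## Concordance

Per-pair Pearson correlations are computed across the samples shared
by both matrices.  Zero-variance probes have no defined correlation;
they are excluded from the rank tests (never imputed as 0) and the
exclusion count is reported.

Distances are binned < 500 / 500–1000 / > 1000 bp; both boundary values
fall in the middle bin.  Differences across bins are tested with the
tie-corrected Kruskal-Wallis H (chi-square reference, bins − 1 df),
mutual vs non-mutual with the two-sided Mann-Whitney U (normal
approximation with tie and continuity correction).  p-values are
reported at full floating precision; a printed `0` means the value
underflowed double precision, not a literal zero.

### Bilinear signal relationship

Two platforms' signals track each other with different slopes below
and above an expression threshold.  The estimator is deliberately
simple: a breakpoint grid search over the x-quantiles 5 %…95 % in 1 %
steps, ordinary least squares on each side of each candidate, total
SSE minimized.  Because interpolated quantiles rarely coincide with
observed values, the search is refined by also trying every observed x
within one grid step of the winning candidate, which makes noise-free
two-segment data exactly recoverable.  The two segments are *not*
constrained to be continuous; the gap at the breakpoint is reported as
a diagnostic (`continuity_gap`).  A fitted gap near zero on real data
supports the two-regime reading; a large gap flags that the two-line
summary is inadequate.

## Signature pipeline

Training runs four stages; every stage's constants are stored in the
model so prediction is fully train-independent:

1. **Quantile normalization.**  Each training column is forced onto the
   mean-of-sorted-columns reference; ties receive the average of the
   reference values they span.  The reference vector is stored and
   imposed on test columns at prediction time.  When a test matrix has
   a different row count (the other platform), the stored reference is
   linearly interpolated in rank space.
2. **Gene selection.**  Pearson correlation of each probe's expression
   with the 0/1 phenotype; top `n_genes` by |r|, ties broken by probe
   id.  Defaults follow the published pathway settings (150 genes /
   2 metagenes; broader programs use up to 500 genes and 3 metagenes).
3. **Metagenes.**  Selected rows are centered and scaled to unit
   variance (sample SD, ddof = 1; constant rows keep scale 1), and the
   basis is the first k left singular vectors of the standardized
   genes × samples matrix.  Sign convention: the largest-magnitude
   loading of each basis vector is positive.  Sample scores are the
   projections onto the basis.
4. **Probit regression.**  Default fitter is the Albert–Chib
   latent-variable Gibbs sampler: z_i ~ N(x_i'β, 1) truncated by the
   observed class, β | z multivariate normal under independent
   N(0, τ² = 100) priors; 2000 retained draws after 500 burn-in,
   posterior-mean coefficients and posterior SDs reported.  The proper
   prior keeps coefficients finite under complete separation, which is
   the normal situation with clean training cohorts.  The
   `penalized_mle` fitter maximizes the same posterior (ridge penalty
   `‖β‖²/2τ²`, L-BFGS-B, gradient tolerance 1e-8) and is used where
   speed matters more than posterior uncertainty.

Prediction maps Φ(β₀ + βᵀm) per sample and reports both the
probability and the linear predictor (the probit-scale score), since
downstream comparisons may prefer either scale.  Probabilities are
clipped to (1e-12, 1 − 1e-12) to stay strictly inside the open unit
interval in floating point.

**Missing genes at prediction.**  Up to 5 % of signature genes may be
absent from a test matrix (or untranslatable through a mapping); they
are dropped from the basis projection with a warning.  More than 5 %
is an error listing the genes.  Dropped rows are removed from the
basis without re-orthonormalization — at ≤ 5 % loss the distortion is
negligible and the behaviour is simple to reason about.

**Cross-platform use.**  The intended workflow is *merge first*: build
the mutual-best-match mapping, restrict both platforms' matrices to
the mapped probe universe, then train.  Every selected gene is then
translatable by construction.  Signatures trained on an unmapped
universe can still be applied cross-platform but will hit the 5 % rule
when selected probes lack mutual partners.

**LOOCV** refits the entire pipeline — normalization reference, gene
selection, metagenes, probit — on every n−1 fold before scoring the
held-out sample, eliminating selection bias.  Per-fold RNG streams are
derived from (seed, fold), so results are reproducible and independent
of fold order.

**Signature overlap** between two platforms' signatures counts genes
whose mutual-pair translation appears in the other selected list;
percent overlap = common / n_genes × 100.

## Synthetic data generator

The generator emulates two array platforms measuring the same RNA
samples, at the scale of a realistic two-platform comparison:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes on one synthetic chromosome |
| `probes_per_gene_a/_b` | 1–3 | probes per gene per platform |
| `gene_span_bp` | 5000 | gene length; probes placed uniformly inside |
| `probe_len_a/_b` | 400 / 50 | targeted-region lengths (probe-set vs single-bead style) |
| `breakpoint_latent` | 7.0 | latent value where the signal transform changes slope |
| `slope_low/high` (A) | 0.3 / 1.0 | platform-A transform slopes |
| `slope_low/high` (B) | 0.28 / 0.93 | platform-B slopes (high-expression A-vs-B ratio ≈ 1.07) |
| `noise_sd` | 0.2 | probe noise and positional-gradient SD (signal units) |
| `distance_decay_bp` | 600 | length scale of the positional gradient |
| `n_signature_genes` | 150 | genes carrying the planted effect |
| `effect_size_sd` | 2.0 | latent shift in pathway-on samples (latent SD = 1) |
| `n_control/n_pathway/n_test` | 10 / 10 / 16 | cohort sizes |

Latent per-gene abundance is N(μ_g, 1) with μ_g ~ U(4, 12).  Each
platform reports a continuous two-segment transform of the latent
value anchored at its typical signal scale (7.0 / 6.7 at the
breakpoint), plus two noise terms:

* independent probe noise, SD `noise_sd`;
* a **positional gradient**: per gene and sample a random slope along
  the gene body (SD `noise_sd`, length scale `distance_decay_bp`),
  *shared by both platforms* because it models a property of the RNA
  itself (5′/3′ degradation, isoform usage), read out by each probe at
  its signed offset from the gene midpoint.

Two probes close together read nearly the same gradient value and so
correlate strongly across samples; probes far apart diverge.  This is
the mechanism behind the distance-binned correlation ordering and the
mutual-vs-non-mutual gap that the concordance module measures.  (A
simpler design — scaling each probe's independent noise by its own
distance from a gene anchor — fails to produce the ordering: the noise
of a probe is then nearly independent of the distance to its *partner*
at short range.)

Training samples carry a 0/1 pathway activation; the 16-sample test
panel draws activation from U(0, 1), mimicking a tumor panel with
heterogeneous pathway activity — necessary for cross-platform
prediction *correlations* to be meaningful.

The truth record stores the signature genes, the intended mutual
pairing (computed by an independent per-gene brute force), the test
panel's activation levels, and an analytic correlation target per pair
(local-slope approximation) that the observed correlations track.

What the generator does **not** model: spatial array artifacts, probe
GC/affinity bias, batch effects, cross-hybridization, non-Gaussian
signal distributions, and any dependence between genes beyond the
planted signature effect.  Passing tests therefore demonstrate the
algorithms' correctness and calibration under a clean generative
model, not performance on real arrays.

## Determinism and numerics

* All randomness flows through seeded `numpy.random.Generator`
  streams; derived streams use seed sequences like (seed, fold).  The
  same seed yields byte-identical serialized models and fixture files.
* Serialized signatures are single JSON documents with full-precision
  floats; mapping tables and matrices are TSV with '#' provenance
  headers.
* Gene-selection and nearest-probe ties are broken lexicographically;
  SVD sign is fixed by the largest-loading convention; breakpoint-grid
  SSE ties keep the smallest candidate.
* Degenerate inputs fail loudly: constant x in the bilinear fit,
  single-class labels, k above matrix rank, empty merges, fewer than 2
  non-empty bins.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the generator at its
default scale (2000 genes, ~4000 probes per platform, ~5600 pairs,
10+10 training and 16 test samples).  The null-effect calibration
(20 independent cohorts, LOOCV each) uses 800 genes with the
penalized-MLE fitter — chance-level AUC does not depend on gene count
or sampler, and the smaller cohorts keep the 20-fold replication
brisk.  Unit tests use further scaled-down cohorts (hundreds of
probes) with the same structure.
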