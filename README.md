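# xplatsig

Cross-platform microarray probe mapping and portable pathway-activation
signatures.

## The problem

Gene-expression signatures predict the activation of a biological
pathway in a sample from the expression of a selected gene set.  They
are trained on one expression platform, but the samples a lab wants to
score often live on another: different arrays interrogate the same
transcript with probes of different chemistry placed at different
positions, and their signal scales are not directly comparable.

`xplatsig` implements the pieces needed to move signatures between two
platforms (the Affymetrix-vs-Illumina setting is the canonical case):

1. **Probe mapping by genomic distance.**  Given BED-style genomic
   coordinates for each platform's probes and a probe→gene annotation,
   every probe is paired with the nearest same-gene probe of the other
   platform, where distance is measured between interval centers,
   `d = |(s_A + e_A)/2 − (s_B + e_B)/2|`.  A pair is a *mutual best
   match* when each probe is the other's nearest; mutual pairs within a
   distance cap (default ≤ 1000 bp) define a one-to-one probe
   translation, and the two expression matrices are merged row-by-row
   over those pairs.
2. **Concordance analysis.**  Per-pair Pearson correlations of the two
   platforms' expression profiles, stratified by genomic distance
   (< 500 bp, 500–1000 bp, > 1000 bp; Kruskal-Wallis across bins) and
   by mutuality (Mann-Whitney U), plus a two-segment ("bilinear")
   least-squares fit of one platform's signal against the other —
   platforms track each other with different slopes below and above an
   expression threshold.
3. **Pathway signatures.**  The classic metagene/probit pipeline:
   quantile normalization to a stored reference, gene selection by
   Pearson correlation with the binary phenotype, compression of the
   selected genes into *k* metagenes (left singular vectors of the
   standardized training matrix), and a Bayesian probit regression of
   the phenotype on the metagene scores,

   P(pathway on) = Φ(β₀ + βᵀ m),

   fitted with the Albert–Chib Gibbs sampler under N(0, τ² = 100)
   priors (finite coefficients even under complete separation), with a
   ridge-penalized MLE as a fast alternative.  Leave-one-out
   cross-validation refits the entire pipeline per fold.  A signature
   trained on platform A scores platform-B samples by translating its
   probe ids through the mutual-best-match mapping.
4. **Synthetic two-platform studies.**  A generator that emulates two
   platforms measuring the same RNA: shared latent transcript
   abundances, per-platform two-segment signal transforms, a planted
   signature effect, and a positional-gradient noise model that makes
   genomically close probe pairs correlate more strongly than distant
   ones — with full ground truth for testing every step above.

## Worked example

```python
import xplatsig as xp

# a synthetic two-platform study: 2000 genes, 10+10 training samples,
# 16-sample heterogeneous test panel
bundle = xp.generate_fixture(xp.SyntheticConfig(seed=1))

# map probes across platforms and keep mutual best matches <= 1000 bp
table = xp.find_mutual_best_matches(bundle.probes_a, bundle.probes_b)
filtered = xp.filter_mapping(table, xp.MappingFilter())

# concordance of the paired measurements on the test panel
merged = xp.merge_datasets(bundle.expr_test_a, bundle.expr_test_b, table)
report = xp.pairwise_expression_correlation(merged)
h, p = xp.kruskal_wallis_across_bins(report)

# train a signature on platform A (mapped probe universe), score B
mut = filtered.mutual_pairs()
train_a = bundle.expr_train_a.loc[mut["probe_a"]]
model = xp.PathwaySignatureModel(bundle.labels, train_a,
                                 xp.SignatureParams(seed=1), platform_id="A")
result = model.fit()
print(result.summary())
cross = result.predict(bundle.expr_test_b.loc[mut["probe_b"]],
                       mapping=filtered)
```

This prints (abridged):

```
pairs: 5592 (2463 mutual, 1859 mutual within 1000 bp)
median r per bin: {'lt500': 0.951, '500to1000': 0.923, 'gt1000': 0.715}
Kruskal-Wallis H = 2364.7, p = 0

Pathway signature (metagene probit)
  platform            A
  genes selected      150
  metagenes           2
  sampler             gibbs

  coefficient       estimate  posterior sd
  intercept          -4.4986        3.9701
  metagene_1          1.6699        0.6566
  metagene_2         -0.4869        0.9130
```

Reading the numbers: of 5592 cross-platform probe pairs, 2463 are
mutual best matches and 1859 of those lie within 1000 bp — the
translation table.  The median per-pair correlation falls from 0.95
(< 500 bp apart) to 0.72 (> 1000 bp), which is why the mapping keeps
only close mutual pairs.  The fitted signature pushes pathway-on
samples to probabilities near 1 and controls near 0; scoring the
platform-B test panel through the mapping reproduces the same-platform
probabilities almost exactly (Pearson r ≈ 0.98).

The same pipeline is available from the shell:

```sh
xplatsig simulate --seed 1 --out-dir sim/
xplatsig map --bed-a sim/probes_A.bed --bed-b sim/probes_B.bed --out map.tsv
xplatsig filter --mapping map.tsv --max-distance 1000 --out map.mutual.tsv
xplatsig merge --expr-a sim/expr_train_A.tsv --expr-b sim/expr_train_B.tsv \
               --mapping map.mutual.tsv --out-prefix merged
xplatsig train --expr merged.A.tsv --labels sim/labels.tsv --seed 1 \
               --out model.json
xplatsig predict --model model.json --expr merged.B.tsv \
                 --mapping map.mutual.tsv --out preds.tsv
```

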