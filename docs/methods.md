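# Methods

## Scope and data model

`mirlink` covers the downstream half of a paired bulk RNA-seq study: it takes
feature-by-sample integer count matrices (one mRNA, one miRNA, shared sample
set), a two-group sample annotation (case vs control; the motivating design
is 4 ACM ventricular biopsies vs 3 controls), a miRNA→gene prediction table
(one row per miRNA–gene–tool triple), a validation table (miRNA–gene–source)
and optional GMT gene sets.  Everything upstream — trimming, alignment,
quantification — is out of scope; counts are the interface.

Identifiers are matched by exact string equality after whitespace trimming:
gene symbols for mRNA, miRBase mature names (`hsa-…-5p/3p`) for miRNA.  No
alias resolution is attempted, because none can be done reliably without
pinning annotation versions.

## Differential expression

For each count matrix:

* **Size factors.**  Median-of-ratios: for features positive in every sample,
  `s_j = median_f counts[f,j] / geomean_j'(counts[f,j'])`, with the numpy
  midpoint convention at ties.  If no feature is positive everywhere, a
  pseudocount variant is available.  Note the absolute factors are only
  defined up to the geometric-mean reference; ratios between samples are the
  meaningful quantity.
* **Dispersion.**  The exported estimator is the plain method of moments on
  group-centered normalized counts, `α̂ = max(floor, (v − m)/m²)` with `v` the
  unbiased pooled within-group variance (ddof = n − 2) and `m` the grand
  mean.  Inside the Wald test this raw estimate is *moderated*: the
  per-feature pooled variance is averaged with the variance implied by the
  common (median) dispersion at the feature's mean, weighting the prior with
  `dispersion_prior_df = 10` pseudo-observations (the long-standing tagwise
  default of edgeR), and converted back to a dispersion.  At n = 7 the raw
  moment estimate has ~5 degrees of freedom; plugging it into a
  normal-reference Wald test inflates the type-I error to ≈ 0.11, while with
  the true dispersion the same test is exactly calibrated (0.050 measured).
  The moderated estimator restores calibration (≈ 0.067 at nominal 0.05)
  without any per-feature likelihood machinery.  The trade-off is standard
  for empirical-Bayes shrinkage: features whose true dispersion is far from
  the common trend are pulled toward it, so outlying features are tested
  slightly anticonservatively.
* **GLM and test.**  Per feature, an NB GLM with log link,
  `log μ_fj = log s_j + b0 + b1·x_j` (x = 1 for case), fit by IRLS (working
  weights `μ/(1+αμ)`, 2×2 weighted normal equations, convergence to 1e−12 on
  the coefficients, η clipped to ±30).  `log2FC = b1/ln 2`, SE from the
  inverse Fisher information, `W = log2FC/SE` against N(0,1), two-sided.
  Features with an all-zero group are refit with a pseudocount (default 1)
  and flagged; features with total count < 10 are dropped before testing.
* **Calling rule.**  `q ≤ 0.05` (Benjamini–Hochberg step-up, own
  implementation cross-checked against a brute-force oracle and statsmodels)
  and `|log2FC| ≥ 0.5`.  The source study states several threshold variants;
  this default is the one attached to its headline counts, and a raw-p rule
  (`p < 0.05`, `|log2FC| > 1`) is selectable.

This engine is deliberately *not* bit-compatible with DESeq2: no Cox–Reid
adjusted likelihood, no independent filtering, no outlier refitting.  It is
validated by its statistical behaviour (simulated type-I error in
[0.03, 0.08]; power ≥ 0.8 for |log2FC| = 2 at base mean 100, 4 vs 3), not by
replicating another tool's output.

The CPM utility used for the fixture worked example computes per-sample
`CPM = 10⁶·count/column-sum` (column sums of the given matrix as library
size, since true library sizes are not available for a printed sub-table) and
reports `log2(mean case CPM / mean control CPM)`.

## Over-representation analysis

Upper-tail hypergeometric test per gene set: with universe size N, set size K,
selection size n and overlap k, `p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n)`;
BH-adjusted q over the collection.  The default significance rule is raw
p < 0.05 (matching the motivating study); a q-based rule is exposed because
the raw-p rule is anticonservative over large collections.  The default
universe is the set of features tested for DE (post pre-filter), the standard
background correction.  Up- and down-regulated features are tested jointly by
default; callers can subset.  Note the attained level of the discrete test
can sit well below nominal for small urns.  Live GO/KEGG downloads are out of
scope; collections are user-supplied GMT (synthetic collections are generated
for tests and the synthetic pipeline mode).

## Interactome cascade

Candidate pairs are the cross product of called DEMs and DEGs restricted to
the prediction table.  Filters apply in a fixed order, each recorded in the
run summary:

1. **Consensus**: distinct-tool count ≥ `min_tools` (default 3 of the 8-tool
   vocabulary Diana-microT, ElMMo, Microcosm, Miranda, Mirdb, Pictar, PITA,
   Targetscan — consumed as static TSV snapshots, never live queries).
2. **Validation**: pair present in the validation table under any source
   (default required).
3. **Shared target**: the gene is paired with ≥ `min_sharing` (default 2)
   distinct DEMs *within the surviving list* — i.e. sharing is a property of
   the reported candidate set, recomputed after the upstream filters.  The
   filter order matters and is regression-tested: a gene whose second pair
   fails validation loses both pairs here.
4. **Anti-correlation**: Pearson r of `log2(normalized+1)` values (default;
   raw and normalized alternatives exposed) across *all* samples, with
   two-sided p from `t = r·√((n−2)/(1−r²))` at df = n−2; keep
   `r < r_max = −0.7` and `p < p_max = 0.05`, and require opposite DE log2FC
   signs.  The log transform tempers the NB mean–variance coupling; using all
   samples (cases + controls) is the choice that makes the screen sensitive
   to regulation visible through the condition contrast.  At n = 7 the joint
   rule is equivalent to `r ≤ −0.7545` (t-quantile inversion at df = 5), so
   the p-threshold is the binding constraint there.

Edges are sorted by (r ascending, miRNA, gene) and exported as an evidence
TSV and as a bipartite GraphML (node attribute `type ∈ {mirna, gene}`).
Degenerate pairs (feature missing from a matrix, zero-variance expression)
are reported with a status and excluded downstream rather than erroring.

## Synthetic data generator

The generator emulates the data model the cascade assumes; its defaults are
the validation conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_case / n_control | 8 / 8 | samples per group (a 4 vs 3 study-scale preset exists for illustration; it is underpowered by design) |
| n_genes / n_mirnas | 2000 / 200 | desk-scale feature counts |
| baseline_mean_log_range | (1.0, 3.5) | log10 of feature mean counts, drawn uniformly |
| dispersion α | 0.1 | NB: var = μ + αμ² |
| size_factor_log_sd | 0.2 | natural-log sd of per-sample library factors |
| n_de_genes / n_de_mirnas | 40 / 8 | planted DE features, alternating signs |
| de_log2fc | 2 | planted |log2FC| |
| n_true_pairs | 16 | planted regulatory pairs |
| pair_correlation ρ | −0.9 | latent log-scale anti-correlation per pair |
| pair_latent_sd | 0.5 | log2-scale sd of the latent component |
| tool_sensitivity / tool_fp_rate | 0.95 / 0.02 | per-tool hit probabilities for true / non-true pairs |
| validated_fraction | 1.0 | coverage of the validation table |

Counts are gamma-Poisson draws with mean
`s_j · q_f · 2^(β_f x_j + z_fj)`.  The latent component `z` exists only for
planted-pair members and is built from per-module shared factors: a module is
two same-direction DE miRNAs plus their common target genes (every planted
gene therefore has exactly two partner DEMs, so the shared-target filter is
satisfiable by construction).  miRNAs load `√c` on the module factor and each
gene `ρ/√c` with `c = (1+ρ²)/2`, giving each planted pair a latent
within-condition correlation of exactly ρ; the two partner miRNAs are
mutually correlated at c as a side effect (a shared-factor construction
cannot give two partners |ρ| = 0.9 each without correlating them).  Because
paired members also shift in opposite directions between conditions, the
across-group log-scale correlation is stronger than ρ, and observed count
correlations are attenuated by counting noise — tests use margins
accordingly.

Prediction and validation tables are independent Bernoulli thinnings of the
true pairs (sensitivity per tool; validated_fraction per pair) plus
false-positive noise over non-true combinations (fp rate per tool; optional
contamination count for the validation table).  Each generator draws from its
own numpy stream seeded as `(seed, offset)`, so adding one call never
perturbs another's output; identical config implies byte-identical outputs.

What the generator does *not* emulate: sequence-level structure (seed
matches, hairpins), tissue composition (fibro-fatty replacement), correlated
library artefacts, annotation ambiguity.  Passing recovery tests therefore
demonstrates the cascade's logic and statistical behaviour under its assumed
model, not performance on real heart tissue.

## Pipeline and reproducibility

`run_pipeline` executes simulate (or load) → DE (both matrices) →
interactome → ORA from one YAML/dict config, writing every stage table, a
GraphML network, a `run.log` and a `summary.json` holding input dimensions,
DE counts (up/down), the pair count after every filter stage, enrichment
counts, the echoed config and seed.  Fixed seed implies byte-identical
outputs (all reductions run on C-contiguous arrays so in-memory and
file-loaded inputs take the same floating-point paths).  `summarize_run`
recomputes the counts from the written tables and fails loudly on any
mismatch or on a non-monotone filter cascade.

Problem sizes used in the validation suite: type-I error from 10 null
simulations of 2000 features (4 vs 3, α = 0.1); power from 500 planted
features at base mean 100; recovery from 20 seeded studies at the generator
defaults.  These sizes give stable estimates (binomial sd of the type-I
estimate ≈ 0.0015) while keeping a full run in seconds.

## Known limitations

* The Wald test relies on asymptotics; at n = 7 its calibration is inherited
  from the dispersion moderation, and features with outlying true dispersion
  are tested slightly liberally.
* The anti-correlation screen uses marginal Pearson correlation across all
  samples; it cannot distinguish direct regulation from shared condition
  response (pairs that are both DE will correlate through the group contrast
  alone).  The consensus + validation filters carry the causal burden.
* ORA inherits the composition of user-supplied gene sets; raw-p
  significance is anticonservative over many sets.
* The fixture's condition layout (4 vs 3) reflects the printed table, which
  carries one control fewer than the study recruited; the package takes the
  printed samples as-is.
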