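# Methods

## The model

The package is built around a single biological picture: strain panels
occupy a one-dimensional trade-off axis between a growth program and a
survival (stress-resistance) program. That axis shows up three times, in
three data types:

1. In **growth phenomes** as two blocks of conditions with positive
   within-block and negative between-block correlation of strain growth.
2. In **expression data** as a dominant rank-1 component whose gene
   loadings (the signature scores) separate growth-program genes
   (positive, PS) from survival-program genes (negative, NS).
3. In **pharmacology panels** as a positive association between
   survival-program expression and drug resistance.

Every analysis stage is a way of estimating or testing one facet of this
picture; the synthetic generators plant exactly these structures so that
recovery can be verified quantitatively.

## Phenome preprocessing and consensus clustering

*Missing-value filter.* Rows, then columns, with more than 10% missing
cells are removed, and the two passes repeat to a fixed point. Fixed-point
iteration makes the result insensitive to whether a bad row would have
rescued a borderline column: a column whose missing fraction drops to
≤ 10% after row removal is retained.

*Imputation.* A missing cell takes the mean of its column over the k = 10
nearest rows (root-mean-square distance over mutually observed columns;
rescaling by the shared-column count makes rows with different
missingness comparable). Rows sharing no observed column are not eligible
neighbours; when fewer than k eligible neighbours exist the column mean is
used and a warning logged.

*Standardisation.* Each condition is scaled to mean 0 and unit sample
variance (n − 1 denominator — the common statistical convention; the
choice only rescales columns by √(n/(n−1)) and does not affect
correlations or cluster structure).

*Low-rank reconstruction.* The matrix is reconstructed from its two
leading singular triplets. Rank 2 is the natural choice for a two-block
structure: one component carries overall growth, the second carries the
trade-off contrast, and higher components carry condition-specific
idiosyncrasies that the analysis deliberately discards. Singular vector
signs are pinned (largest-magnitude entry of each right singular vector
positive) so repeated runs are bit-identical.

*Consensus clustering.* Per iteration, ⌊0.8·n_conditions⌋ conditions and
⌊0.8·n_strains⌋ strains are drawn without replacement; the sampled
conditions are clustered on 1 − Spearman distance with average linkage
(one linkage tree per iteration, cut at every K in the scanned range).
The consensus index of a pair is co-clustered count / co-sampled count;
pairs never co-sampled (vanishingly rare at 1000 iterations) get index 0
and a log entry. PAC is the fraction of off-diagonal pairs with index
strictly inside (0.1, 0.9); strict bounds are immaterial at 1000
iterations but must be fixed, and strictness keeps exactly-0.1/0.9 values
unambiguous. PAC ties across K are reported as ties, not broken. An
optional flag excludes K values whose full-data cut produces singleton
clusters from the "optimal K" report.

The pipeline default clusters the rank-2 reconstruction; the raw
standardised matrix is available behind `--use-raw`, and the run log
records which entry point was used.

Average linkage itself is delegated to `scipy.cluster.hierarchy`; its
tie-breaking between equal-height merges is deterministic, which is what
reproducibility requires (ties between merge distances essentially never
occur with continuous data).

## Expression signatures

Sample columns are zero-centred (no variance scaling); absolute-scale
(count/intensity) data are gene-centred first, two-colour relative data
must not be (they are already expressed against a reference, so the
module refuses to gene-centre them). Variance-stabilising transformation
of raw counts is upstream of this package; a log2(x+1) fallback flag
exists on the CLI.

The signature is the unit-norm first left singular vector, oriented so
the largest-|score| gene is positive. A degenerate leading pair
(s₁ − s₂ ≤ 1e−9) makes it non-identifiable and is an error rather than a
silent arbitrary answer.

Robustness: n = 1000 iterations (100 at test scale) add i.i.d. N(0, 1)
noise to every value and re-extract the first eigenarray, re-orienting
each perturbed vector against the unperturbed one (flip when the dot
product is negative; flip counts are logged). A gene is *consistent* when
its sign matches the unperturbed sign in every iteration. The reported
score is the unperturbed value — the canonical, deterministic estimate —
not a perturbation average.

Dataset integration intersects gene sets, concatenates samples and
mean-centres each gene within each source batch. This location-only
adjustment removes exactly the additive per-batch, per-gene offsets the
generator plants; a full empirical-Bayes batch correction (shrinking
variances as well) is out of scope and can be substituted upstream.
Signature integration restricts to consistent genes, flips one signature
when the pair is anti-correlated (|ρ| < 0.05 is refused as unorientable),
keeps sign-concordant genes and averages scores; a final re-orientation
makes the operation symmetric in its arguments.

Gene-set characterisation uses two-sided Wilcoxon rank-sum tests for
score-distribution differences between sets, with Benjamini–Hochberg
q-values reported alongside raw p-values whenever several pairs are
tested in one call.

## Linkage mapping

The overall-growth trait is the strain score on PC1 of the standardised
phenome (correlation-matrix PCA, consistent with the preprocessing), with
the sign pinned so the trait correlates non-negatively with per-strain
mean growth — "overall growth" should increase with growth; the PCA sign
is otherwise arbitrary.

LOD = −n·ln(1 − r²)/(2 ln 10) per marker, with r the Pearson correlation
between the 0/1 genotype column and the trait. This is algebraically the
log₁₀ likelihood ratio (n/2)·log₁₀(SS_tot/SS_res) of the single-marker
least-squares regression against the intercept-only model, and the test
suite holds the two routes to 1e−9 of each other. Monomorphic markers are
skipped with a warning (NaN in the scan); missing genotypes are refused at
input (the generator never emits them; real data must be imputed
upstream). The number of segregants n is always taken from the data, not
from a constant.

The genome-wide threshold is the empirical (1 − α) quantile of the
maximum LOD over trait permutations (default 1000). α = 1 is accepted and
returns the minimum of the null distribution. Interval mapping, multi-QTL
models and relatedness corrections are out of scope; genome-wide
association with mixed models is an external step whose locus p-values
the network module consumes.

## Network connectedness

Loci and genes use 1-based inclusive coordinates (BED-dialect input is
converted at parse time); overlap means max(starts) ≤ min(ends) on the
same chromosome, so ≥ 1 bp suffices and strand is ignored. A gene's
p-value is the minimum over intersecting loci; genes hit by no locus are
omitted rather than given a pseudo-value.

Cross-condition aggregation defaults to Fisher's method (−2Σ ln p against
χ² with 2k degrees of freedom, k = number of sets scoring the gene); a
"min" rule is selectable to bracket the plausible readings, and the run
log records which was used. Zero p-values are clamped to 1e−300 so the
statistic stays finite and the χ² tail nonzero.

The edge threshold is strict (confidence > 0.4, medium confidence);
duplicate edges keep the maximum confidence and self-loops are dropped,
both logged. The null for the LCC test samples genes uniformly without
replacement from the network's nodes — the universe where an LCC is
computable — and the empirical p-value uses the add-one estimator
(1 + #{null ≥ observed})/(n + 1), which can never be zero. The size
curve resamples its null independently at every k.

## Drug scoring

Expression is gene-wise mean-centred (making scores invariant to
per-gene offsets, e.g. probe affinities), then each cell line's PS and NS
scores are medians over the respective gene sets (even counts: midpoint
of the central pair). Genes claimed by both sets after ortholog mapping —
possible with many-to-one orthology — are excluded from both to avoid
double counting. Per drug, missing resistance values are pairwise-deleted
and drugs with fewer than 10 usable cell lines skipped. The summary
reports median/quartiles of ρ per score type and a two-sided sign test of
the median against zero.

## Synthetic generators: what they emulate, and what not

Every generator is a pure function of its integer seed, and the planted
truth travels in a separate object (or `.truth.json` file) that no
analysis stage reads.

* **Phenome**: latent strain axis a_s ~ N(0,1); cell value
  ±strength·a_s (sign by condition block) + N(0, noise²); missingness is
  uniform completely-at-random at the configured rate (real phenomes have
  structured missingness, but the 10% filters only respond to rates).
  Clade labels are tilted along the axis (wild strains preferentially on
  the stress-resistant side) so composition tests have signal.
* **Expression**: rank-1 signal g·tᵀ with g ~ N(0, signature_sd²)
  re-centred, plus per-(batch, gene) offsets and i.i.d. noise; the
  absolute dialect adds a positive per-gene baseline (uniform 5–15). No
  attempt is made to model platform-specific noise (spatial artifacts,
  count overdispersion beyond this additive model).
* **Cross**: unlinked markers as fair coin flips (the LOD formula is
  per-marker, so a recombination map adds nothing to its test); trait =
  Σ effect·(genotype − ½) + N(0, noise²), making an effect the
  between-allele shift in residual-SD units at noise_sd = 1.
* **Network**: one planted module wired as a random spanning tree plus
  extra edges at high confidence over an Erdős–Rényi background; genes
  tile one synthetic chromosome (1 kb genes, 1 kb gaps, 1-based
  inclusive), making locus–gene intersections deterministic. A module
  requested at confidence ≤ 0.4 would vanish at the standard threshold
  and triggers a warning, not an error.
* **Drug panel**: a latent per-line axis u drives PS genes (+u) and NS
  genes (−u); resistance per drug = effect·(NS − PS true score) + noise,
  so resistance increases with survival-program expression by
  construction.

Passing tests on these generators demonstrates that the estimators
recover the planted structures at realistic noise levels and sample
sizes; they do not demonstrate robustness to structured missingness,
platform batch nonlinearity, linkage disequilibrium, or scale-free
network topology, none of which the generators model.

## Problem sizes and defaults

Consensus clustering: 1000 iterations × 80% resampling (the demo pipeline
uses 200). Signature robustness: 1000 perturbations at full scale, 100 in
the recovery benchmarks (recovery at |ρ| > 0.95 is already stable there).
Linkage benchmark: 1008 segregants × 1000 markers with a 1-SD planted
effect and a 1000-permutation threshold. Connectedness benchmark: a
10-gene module in a 1000-node background against 1000 null samples. Drug
benchmark: 300 cell lines × 50 drugs — the scale of public panels — where
a planted effect of 2 yields |ρ| near 1 and a null panel stays within
sampling noise of zero.

Seeds: the pipeline derives one stream per stage as
(seed + crc32(stage)) mod 2³¹, so adding a stage never perturbs the
others.

## Known limitations

* The batch adjustment is location-only; multiplicative batch effects
  require an upstream correction.
* The consensus-index denominator conditions on co-sampling, so with very
  few iterations individual indices are noisy even when clustering is
  stable.
* `impute_knn` is O(n²) in rows; phenomes of ~10⁴ strains are fine,
  single-cell-scale matrices are not its target.
* The LCC null treats all network nodes as exchangeable; degree-matched
  nulls are not implemented.
* PS/NS scoring assumes the expression matrix is on one consistent scale
  per gene; it records no scale metadata of its own.
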