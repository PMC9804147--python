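# Methods

`dyscord` implements a cross-model transcriptomic concordance analysis: given
gene-level differential-expression (DE) results from two disease models (for
example a human cortical-organoid line and a mouse cortex), it asks whether the
two models dysregulate the same genes, in the same directions, and with
correlated effect sizes; and, for annotated single-cell data, which cell
clusters carry the largest burden of dysregulation and how cell-type
composition shifts. This note records the statistical model behind each stage,
the defaults and why, and the limits of what the synthetic studies demonstrate.

## DEG calling

A gene is a DEG when its |log2 fold change| strictly exceeds `lfc_min` (default
0.25) and its significance column is strictly below its cutoff. The
significance column is the Benjamini–Hochberg adjusted FDR at `fdr_max`
(default 0.05) unless the table yields fewer than `fallback_min_degs` (default
10) FDR-qualifying genes, in which case the raw p-value at `fallback_p`
(default 0.05) is used — the standard rescue for low-powered contrasts such as
perinatal time points. Three choices the upstream description leaves open:

* all threshold inequalities are strict, so a gene at exactly 0.25 or exactly
  the p cutoff is excluded;
* the count that triggers the fallback itself applies the |log2fc| magnitude
  filter, keeping the trigger consistent with the DEG definition it gates;
* "down" uses the mirrored threshold log2fc < −0.25 (symmetry assumed, since
  only the positive threshold is conventionally quoted).

Two replicate models of the same condition (e.g. two isogenic mutant lines)
are combined by intersecting their per-direction DEG sets; a gene up in one
and down in the other lands in neither.

## Ortholog joining and the background universe

Cross-species comparisons join the two tables through a 1:1 ortholog map.
Many-to-many pairs are dropped (with a logged count) rather than expanded,
because duplicated rows would double-count genes in the contingency tables.
When no curated map is available, `default_symbol_map` matches symbols
case-insensitively, exploiting the human-UPPER / mouse-Title conventions; it is
a stand-in, and an explicit two-column map file is the principled path.

The joint universe — the denominator of all enrichment statistics — is the set
of mapped pairs whose members were *testable* in both models (e.g. total reads
> 10 in bulk, detected in ≥ 5% of cells in the single-cell pseudobulk). Each DE
table therefore carries its universe explicitly; when a universe file is
absent it defaults to the table's own gene list.

## Quadrant overlap enrichment (GME)

For each direction combination (up-up, down-down, up-down, down-up) the two
DEG sets A and B are intersected with the joint universe U and summarised as
a 2×2 table [[n11, n10], [n01, n00]], where n11 = |A∩B| and n00 counts
universe genes in neither set. The geometric mean enrichment is the
observed/expected overlap

    fold = n11 · U / ((n11 + n10)(n11 + n01)),

which equals the geometric mean of the two conditional enrichments
(n11/|A|)/(|B|/U) and (n11/|B|)/(|A|/U). Significance is a one-sided
("greater") Fisher exact test, i.e. the hypergeometric upper tail of n11 given
the marginals. Fold is reported as NaN with p = 1 when either DEG set is
empty. The Fisher conditional odds ratio is reported alongside for
transparency, since "fold" in the literature is sometimes the odds ratio: the
two differ, and the observed/expected form is the one this package calls GME.
The complement cell n00 is the standard in-neither count; a literal
alternative reading ("all genes not upregulated in dataset 2", which
double-counts) was considered and rejected as internally inconsistent.

## Fold-change regression and the threshold sweep

Effect-size agreement is an ordinary least-squares fit of model-B log2fc on
model-A log2fc over model A's pooled (both-direction) DEGs, unweighted and
without errors-in-variables correction — the estimand is the descriptive
slope/R² of the published scatter, not an attenuation-corrected effect. The
y-axis can be restricted to genes significant in model B (raw or FDR, strict
inequality); the default sweep is [none, FDR<0.5, FDR<0.05]. As the threshold
tightens, n is non-increasing and — when the shared signal is real — R² rises,
because the filter removes x-axis DEGs whose y value is pure noise. Fits with
fewer than 3 points are flagged undefined.

## Sign consistency

For a discordant gene set (e.g. genes up in model A but down in model B), the
sign test asks whether those genes' *raw* fold changes in a third model agree
with a queried direction: n_agree counts strict sign matches (zero counts as
disagreement), and significance is an exact two-sided binomial test at p = 0.5.
The binomial test is an extension beyond the bare count usually reported, and
is labelled as such in the output.

## Single-cell QC and normalization

QC runs in one sequential pass, genes first: genes detected (count > 0) in
fewer than `qc_min_cells_per_gene` (3) cells are removed; then cells are kept
when they express 200–7500 genes and at most 10% mitochondrial reads
(mito genes identified by the configurable `mito_prefix`, default "MT-"),
with all per-cell metrics computed on the gene-filtered matrix. The pass is
idempotent; it is not iterated to a fixpoint, matching the sequential
description it mirrors. Surviving counts get a log-normalized layer,
value = ln(1 + count·10000/cell_total), so per cell Σ expm1(value) = 10,000
exactly (asserted to 1e-6 relative in tests). Natural log with pseudocount 1
is the conventional reading of "log-normalized"; reported fold changes are
always base 2 regardless.

## The internal DE engine

The downsampling burden procedure needs a self-contained DE test. Per gene the
two cell groups' normalized values are compared with a two-sided Wilcoxon
rank-sum test: exact by enumeration of all C(nA+nB, nA) labelings when both
groups have ≤ 8 cells (ties handled by midranks; two-sided p =
P(|W−μ| ≥ |w_obs−μ|)), otherwise the normal approximation with tie and
continuity corrections. The effect size is log2((mA+1)/(mB+1)) of mean
depth-corrected expression (expm1 of the normalized values, i.e. counts per
10k). Genes are pre-filtered exactly as the upstream single-cell engine was
configured: tested only if detected in ≥ `min_pct` (5%) of either group's
cells *and* |log2fc| > 0.25; BH runs over the tested genes only; the recorded
universe is the detection-passing set. The engine deliberately does not refit
a hurdle regression with latent covariates (mitochondrial fraction, read
depth, batch): for real datasets, externally produced DE tables are the
authoritative input, and the internal engine's job is a valid within-dataset
comparison on synthetic data.

**Known limitation — null calibration at scale.** The fold-change pre-filter
selects genes using the same data the rank test then evaluates. Under a global
null this is anti-conservative: with perfectly calibrated p-values BH already
rejects ≥ 1 hypothesis with probability ≈ α (the Simes identity), and the
selection pushes the family-wise rate above α as groups grow (we measured
~5% at 40 cells/group rising to ~38% at 250/group on negative-binomial
nulls). In the exact-enumeration regime (groups ≤ 8) permutation p-values
are guaranteed sub-uniform, and the measured rate of any false DEG is ~2%.
The burden analysis is therefore interpreted through *relative* cluster
rankings, not absolute DEG counts — which is also why counts are averaged
over downsampling iterations rather than tested directly.

## Burden and composition

Clusters enter the burden analysis only if they have strictly more than
`burden_min_cells` (10) cells in *every* sample; the common downsampling
depth k is the minimum (eligible cluster, sample) count unless `burden_k`
pins it explicitly. Per iteration, every (cluster, sample) is downsampled to
k cells uniformly without replacement; within each cluster the mutant line's
samples are pooled against the control's; the engine counts DEGs (both
directions, |log2fc| > 0.25, FDR < 0.05); and counts are averaged over
`burden_iters` (10) iterations. One master seed spawns an independent RNG
stream per iteration, so any iteration is reproducible alone and the whole
result is bitwise deterministic. Pooling within line (rather than per-sample
pairing) mirrors the line-vs-control design; per-sample paired designs are
out of scope.

Composition compares per-cluster proportions between a line and the control:
per-sample proportions (summing to 1 per sample) give the mean ± SEM used for
reporting, while the p-value is a two-sided Fisher exact test on the pooled
[in-cluster, out-of-cluster] × [line, control] counts. Both are emitted
because they answer slightly different questions (replicate-level variability
vs pooled-count significance); neither is claimed to reproduce any published
per-cluster p-value exactly. No compositional-data transforms (log-ratio
models) are applied.

## Synthetic data

`simulate_bulk_pair` draws, per gene, a class (concordant, discordant, null;
class counts are exactly round(f·G)), a shared effect magnitude
|Normal(effect_mu, effect_sd)| with a random sign (same sign in both models
for concordant genes, opposite for discordant), and observed
log2fc = θ + Normal(0, se) per model. P-values are the exact two-sided normal
tails, so calibration properties are analytic: the population squared
correlation of the two fold-change vectors is
cov²/((Var(θ)+se_a²)(Var(θ)+se_b²)) with cov = (f_conc−f_disc)(μ²+σ²)
(`population_r2`). Defaults — G = 5000, f_conc = 0.10, f_disc = 0.05,
effect_mu = 1.5, effect_sd = 0.4, se = 0.3, 2% universe dropout, 5% ortholog
dropout — represent a well-powered bulk study with a strong shared signature
plus a smaller opposed component, the regime the comparison matrix is meant
to resolve. The generator does not simulate replicate counts and refit a DE
model; the known-SE normal model is what makes the recovery tests exact.

`simulate_sc` draws negative-binomial counts (variance = μ + dispersion·μ²,
one shared dispersion, default 0.5) with per-gene lognormal base means,
per-cell lognormal size factors, cluster-marker boosts, mitochondrial genes
pinned to a target fraction (5%, exercising QC), per-line composition
vectors, and cluster-specific planted DEGs boosted 2^δ (δ = 1) in mutant
lines. Defaults (800 genes, 4 clusters, 5 samples/line, 50–80 cells per
cluster-sample) keep every simulated experiment inside the QC envelope — at
fewer genes or lower expression, healthy cells would fail the 200-gene floor
— while staying small enough that the full study runs in seconds. What the
generator does **not** emulate: real library-size distributions and gene
panels, per-gene dispersion, doublets, ambient RNA, batch effects, or any
real dataset's cluster identities. Passing recovery tests therefore show the
*procedures* are correct and calibrated under their stated assumptions, not
that the engine matches a hurdle-model analysis of real tissue.

## Numerical and procedural choices

* BH adjustment is the step-up with monotone enforcement (sort, p·n/rank,
  reverse cumulative minimum, cap at 1), verified exactly against a
  brute-force quadratic implementation and against statsmodels.
* Fisher exact tests, the binomial test, OLS and the asymptotic rank test are
  scipy routines; the exact rank branch and BH are implemented here.
* Degenerate inputs: all-tied rank input gives p = 1; empty DEG marginals
  give NaN fold with p = 1; regression with < 3 points is flagged undefined;
  a QC pass that would empty the matrix raises instead of returning nothing.
* Downsampling with k equal to the group size returns the full group for any
  seed; sampled index sets are sorted so results do not depend on draw order.
* All randomness flows through numpy Generators seeded from explicit config
  seeds; end-to-end reports are byte-identical under a fixed seed.

## Problem sizes used in the test and acceptance runs

Bulk recovery and calibration run at the default G = 5000 (50 planted seeds,
2000 null pairs); the single-cell burden experiments use 4 clusters × 10
samples × 50–80 cells (k ≈ 30–50, 10 iterations, 12–20 seeds); the DE-engine
null check uses 100 two-sample fixtures of 8 cells per group at 200 genes.
These sizes were chosen so each statistical assertion has adequate
Monte-Carlo resolution while a full run of the suite completes in a few
minutes on one CPU.
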