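# Methods

This note documents the statistical procedures `tfnetevo` implements, the
modelling choices behind them, what the synthetic benchmark does and does not
emulate, and the numerical conventions used throughout.

## Scientific setting

Protein evolutionary rate is measured as Ka/Ks, the ratio of non-synonymous
to synonymous substitution rates between a gene and its ortholog in a close
relative (for budding yeast, *S. cerevisiae* vs *S. paradoxus*). Genome-wide,
Ka/Ks correlates strongly with expression level, codon adaptation index (CAI),
and protein-interaction (PPI) degree. Transcription factors (TFs), however,
are a functionally special subset: lowly expressed, rich in transient
interactions, and defined by their position in the regulatory network. The
package's central question is whether the TF subset follows the genome-wide
trends or its own — and whether TF evolutionary rate instead tracks
properties of the *targets* a TF regulates: their median Ka/Ks, the fraction
lost in the comparison species, their expression divergence between species,
and whether these relationships differ between activating and repressive
regulation.

## Rank-space subset-slope test

**Statistic.** All genes are ranked genome-wide on each of the two properties
under study (ascending midranks divided by N, so ranks lie in (0, 1]). The
observed statistic is the ordinary least-squares slope of y-rank on x-rank
computed over the subset members *using their genome-wide ranks*. Re-ranking
within the subset would normalize the slope into a correlation coefficient —
a goodness-of-fit measure — whereas keeping genome-wide ranks keeps the
subset's slope on the same scale as the genome-wide trend, which is the
comparison of interest.

**Null model.** Because the subset may sit off-center in either property
(TFs have low expression), a plain random-subset null would be biased. The
null is therefore a set of equally sized random gene sets whose *mean ranks*
in both properties match the subset's within a root-mean-square deviation

    RMSD(S) = sqrt(((mean_x(S) − mean_x(subset))² + (mean_y(S) − mean_y(subset))²) / 2)

with tolerance 0.01 (1% of the rank range) by default, and 10,000 samples by
default. The empirical p-value is the fraction of null slopes at least as
extreme as the observed slope. A count of zero is reported as the resolution
bound p ≤ 1/n_samples, never as zero.

**Sidedness.** The `direction` parameter selects the tail: `flatter` /
`steeper` are fixed one-sided tails (null slopes ≤ / ≥ the observed value;
the labels refer to the signed slope relative to the null, not to its
magnitude), `two_sided` doubles the smaller tail, and `auto` (the analysis
default) picks the tail on the side of the observed slope relative to the
null median. Note that `auto` selects the tail from the data, so its p-values
are not uniform under the null (P(p < α) ≈ 2α); calibration statements and
the calibration tests therefore use a fixed a-priori direction, which is the
statistically correct usage when a direction is hypothesized in advance.

**Samplers.** Two samplers generate matched sets. `rejection` draws uniform
subsets and keeps qualifiers — exactly uniform over the qualifying region,
but useless when the subset's mean ranks are far from 0.5 (a 150-gene subset
with mean expression rank 0.3 is ~10 standard errors from a uniform draw).
`swap`, the default, starts from a uniform draw, greedily swaps single
members until the tolerance is met, then performs 10·|subset|
tolerance-preserving random swaps. The mixing swaps are a symmetric
Metropolis move (uniform member out, uniform candidate in, accept iff the
constraint still holds), whose stationary distribution is uniform over the
qualifying sets reachable by single swaps; the randomizing phase
de-correlates the emitted set from the greedy path. Equivalence of the two
samplers is established empirically (two-sample KS test on null slopes where
rejection is tractable), not assumed.

**Controls.** The CAI control repeats a test with CAI ranks substituted for
Ka/Ks ranks — a one-argument change — to check whether a surprising slope is
an expression artifact. The confirmed-edge control repeats in-degree-based
tests on the network restricted to edges supported by ≥ 2 independent
binding experiments.

## Regulatory-network conventions

Raw experiment records (TF, target, experiment id, source) collapse to one
edge per (TF, target, source) with support = number of distinct experiments.
"Targets" always means distinct target genes. The binding-assay (`chip`) and
literature-curated (`curated`) dialects are never mixed within a statistic.
Per-TF profiles require ≥ 3 targets (≥ 2 on the sparser confirmed network);
the fraction of targets missing an ortholog always requires ≥ 3 targets
because ortholog loss affects only ~10% of genes. Top-20% target fractions
(conserved: Ka/Ks rank ≤ 0.2; interactive, expressed: rank ≥ 0.8) use
genome-wide rank thresholds, not within-target-set ranks.

Genes lacking an ortholog have no measurable Ka/Ks and are assigned a common
value strictly above the fastest ortholog-bearing gene (default: max × 1.1,
configurable). All downstream statistics are median- or rank-based, so
results are insensitive to the constant; a test asserts this by comparing
multipliers 1.1 and 2.0. Genes missing any other property are excluded
pairwise, and each property is ranked over the genes that carry it.

## Edge-sign inference

A TF-knockout experiment yields an X score per (deleted TF, gene): a
confidence-weighted log expression ratio of knockout vs wild type. For bound
targets with |X| strictly greater than 1, the edge is signed: X < −1 means
the target dropped when its regulator was removed (activating), X > +1 means
it rose (repressive). Edges with |X| ≤ 1 or no knockout coverage stay
unsigned and are excluded from sign-stratified statistics. The ratio
orientation is a configuration flag (`orientation`) because the convention
belongs to the source assay, not to the method. Replicate scores for one
pair are combined by the largest |X| by default (most confident call), with
a mean option.

Sign-stratified co-evolution statistics admit a TF into the activated
(repressed) stratum only with ≥ 5 same-sign targets, making the Spearman
correlations robust to residual sign errors.

## Co-regulation spread test

For each TF with ≥ 3 ortholog-bearing targets, the observed statistic is the
median absolute difference of the value (Ka/Ks, or log2 expression) over all
unordered target pairs. The expected statistic is the mean of the same
median over 100 equally sized random "target" sets, drawn *without
replacement* with selection probability proportional to regulatory in-degree
— highly regulated genes appear in any target list more often, so a uniform
null would overstate the clustering of real target sets. Significance is a
Wilcoxon rank-sum test between the per-TF observed and expected
distributions (two-sided by default; a one-sided and a paired signed-rank
variant are exposed, the latter arguably more natural given the pairing but
the rank-sum form is the package's reference behavior).

## Expression divergence between species

Counts are normalized to reads-per-million and floored at 1 RPM, which
bounds fold changes for barely covered genes; the per-ortholog-pair
statistic is log2(RPM_a/RPM_b) (logging makes the distribution approximately
normal). Targets of the top 25% fastest-evolving TFs (ranked by assigned
Ka/Ks among TFs with targets; quartile ties broken by gene id) are compared
with the remaining TFs' targets on |log2 FC| with an unpaired Welch t-test
(pooled-variance optional). Genes regulated by both groups count as
fast-TF targets; an exclusive-assignment option drops them from both.

## Enrichment statistics

Target-set term enrichment uses a one-sided Fisher's exact test per term
with ≥ 50 member genes among the union of the two target sets; fold is the
ratio of within-set annotated fractions. Raw p-values are reported with a
p < 0.05 flag and no multiple-testing correction; annotations are flat sets
(no ontology-graph propagation). PPI-partner annotation enrichment builds
the 2×2 incidence table (each undirected edge contributes both (protein,
partner) directions) and uses a 1-df chi-square test without continuity
correction, warning when any expected count falls below 5.

## Binned-median profiles

Plot support uses equal-count bins on the x variable; each bin reports the
median y (robust to outliers and to the missing-ortholog constant), a
standard error from 100 bootstrap resamples of the bin members, and the
member count. Bin edges and counts are configuration, not convention.

## Synthetic benchmark

The generator draws gene properties through a Gaussian copula: latent
standard normals with configured loadings, mapped through marginal quantile
transforms (log-normal expression and Ka/Ks, probit CAI). For two uniform
rank variables the OLS rank slope equals the Spearman correlation, so the
configured "genome slope" of Ka/Ks on expression (default −0.5; −0.3 on PPI
degree) is implemented as a latent correlation 2·sin(π·ρ/6). TFs get their
own trend multipliers (default 0.3× — flatter trends) and an expression
shift one latent SD down; the shift moves TF expression and CAI but is
removed from the Ka/Ks loading so TF rates are not mechanically inflated.
PPI degrees follow a truncated discrete power law coupled to the Ka/Ks
latent, realized as a Chung–Lu random graph. Regulatory out-degrees follow a
truncated power law (exponent 2.0); signs are Bernoulli (65% activating);
per-edge support is 1 + Binomial(experiments − 1, redetection probability).

**Activated-target coupling.** The coupling parameter is defined at the
level the analysis measures: the Spearman correlation between TF Ka/Ks and
the *median* Ka/Ks of its activated targets. Each non-TF target with an
activating edge is "owned" by one of its activating regulators; the owner's
targets are redrawn around the owner's standardized rate latent with loading

    a² = ρ² · k · κ / (m · (m − ρ²(m − 1)))

where k is the TF's activated-target count, m its owned-target count, and
κ = 1.55 a fixed correction for the extra noise of median (vs mean)
aggregation and for owned targets that subsequently lose their ortholog.
Redraws keep the genome loadings on expression and degree, so genome-wide
trends survive the coupling. Repressed targets are left uncoupled by
default. Ortholog-loss flags are drawn per gene with probability rising in
the owning TF's rate rank (base 10%); TFs themselves are never flagged.

**Knockout, counts, annotations.** X scores sit at ∓μ (activating /
repressive) plus Gaussian noise, with near-zero background elsewhere and
configurable TF coverage. Two-species counts are Poisson around expression ×
a depth factor (default 20, i.e. a 2–3M-read library at default genome
size; at much lower depth, Poisson noise on log2 fold changes becomes
expression-dependent and leaks a spurious group difference into the
divergence test because fast TFs preferentially regulate lowly expressed
TFs); species-B rates are multiplied by 2^δ with δ ~ N(0, s), where s
doubles for fast-TF targets when the divergence coupling is on. Annotation
terms are sampled with odds biased toward fast-TF targets ("niche" terms)
or away from them ("core" terms).

**What the benchmark does not emulate.** Real binding data have
condition-dependent, correlated false positives; real X scores share
replicate structure; ortholog loss is phylogenetically clustered; GO terms
overlap hierarchically; and the real genome has ~6,000 genes (defaults use
2,000 for desk-scale runtimes; sizes are configuration). Passing recovery
tests therefore demonstrates that the estimators measure what they claim
under the assumed statistical structure — not that the structure holds in
any particular real dataset.

Everything is reproducible from (config, seed): each generator stage and
each pipeline stage derives its own substream (seed-keyed generator streams
in the synthesizer; SHA-256 of (master seed, stage name) in the pipeline), so adding
a stage never perturbs another stage's randomness, and repeated runs are
byte-identical.

## Numerical conventions and problem sizes

Midranks keep rank sums exact under ties; the missing-ortholog constant ties
all flagged genes at the top midrank. Swap-sampler greedy descent uses
strict-improvement moves with a re-initialization guard; mixing uses
10·|subset| proposals. Degenerate inputs raise rather than return sentinel
values: empty rank input, zero subset x-variance, all-zero count samples,
sub-3-member subsets, overlapping enrichment sets. Default test-bench sizes
(2,000 genes, 174 TFs, 500–10,000 null samples, 50–500 replicates in the
statistical suites) were chosen so the full test battery and the acceptance
run each complete in minutes on a single core while leaving the binomial
noise of every calibration check well inside its asserted window.
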