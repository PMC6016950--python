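# Methods

## Model

A gene's evolved expression divergence between a derived and an ancestral
population is modeled as the sum of two log2 components:

* a **cis** effect `c`, linked to the gene and acting allele-specifically;
* a **trans** effect `t`, acting on the regulatory environment and hence on
  both alleles of an F1 hybrid equally.

In the parents the expected log2 expression ratio (derived/ancestral) is
`c + t`. In an F1 hybrid both alleles share one trans environment, so the
expected derived-allele read fraction at informative sites is
`f(c) = 2^c / (1 + 2^c)` and depends on `c` alone. These two identities are
what make the decomposition identifiable, and they are the two assumptions
the estimator needs: no parent-of-origin (imprinting) effects, and no
cis-by-trans interaction (the trans environment scales both alleles by the
same factor).

Estimation is deliberately simple and faithful to the measurement process:
replicates are **pooled by summation** before estimation and testing
(per-replicate values are emitted for QC only), `log2_cis` is the log ratio
of pooled allele counts, `log2_trans` is the parental log ratio minus
`log2_cis` — an exact identity, tested at 1e-12 — and
`percent_cis = |C|/(|C|+|T|)` (undefined when both are zero). No
hierarchical replicate model is fitted; with the pooled-count tests below
this matches the granularity of the data the method is designed for.

## Filters

Applied to pooled hybrid allele counts before any estimate, each recorded
per gene:

| filter | rule | rationale |
|---|---|---|
| `low_reads` | total ≤ 20 (inclusive) | allelic ratios from ≤20 reads are noise-dominated |
| `zero_allele` | either allele has 0 reads | infinite ratio; cannot be log-transformed |
| `high_fold` | allelic ratio > 32-fold (strictly) | extreme ratios are dominated by repeats/artifacts |

Parental expression is filtered at mean FPKM < 0.1 (strictly; a gene at
exactly 0.1 is retained), and genes with a zero population mean are flagged
`parental_unquantifiable` rather than given infinite ratios.

## Significance tests

**Cis.** Exact two-sided binomial test of the pooled derived-allele count
against Binomial(n, ½), two-sided by the minimum-likelihood rule (sum of all
outcomes whose point mass does not exceed the observed one); for the
symmetric null this reduces to `P(X ≤ min(k, n−k)) + P(X ≥ max(k, n−k))`.
The implementation is validated against brute-force pmf enumeration for
every n ≤ 2000.

**Trans.** A G-test (`G = 2·Σ O·ln(O/E)`, df = 1) comparing the parental
allele ratio with the hybrid ratio. Two formulations are provided:

* `independence` (default): a 2×2 likelihood-ratio test of
  [hybrid D, hybrid A; parental D*, parental A*], where the parental
  pseudo-counts are median-of-ratios-normalized counts summed over
  replicates and rounded. This propagates the sampling noise of *both*
  measurements.
* `fixed-cis`: the hybrid cis fraction is treated as known and only the two
  parental cells as random. This is the textbook reading of "expected from
  the measured cis change", but it ignores the binomial noise in the
  measured fraction and the overdispersion of parental counts; on a fully
  null 10,000-gene simulation at pooled depth 500 it mis-flags ~7% of genes
  at a nominal 1% FDR, versus ~0% for the independence form. It is kept
  behind `--gtest-mode fixed-cis` for comparability, with the default chosen
  for honest error control.

Parental counts are overdispersed relative to the multinomial sampling the
G-test assumes, so even the independence form is asymptotic, not exact; the
null simulations in the test suite bound its realized error rate.

Both families are Benjamini–Hochberg adjusted at a 1% FDR, separately per
family. Classification at α = 0.01 on the q-values: `cis_only`,
`trans_only`, `concordant`/`discordant` (both significant, by sign
agreement), `conserved` (neither) — the fifth state making the
classification a partition of all tested genes.

**Genome-wide allelic bias.** Two-sided Wilcoxon signed-rank test of the
per-gene `log2_cis` values against median zero, zeros dropped before
ranking; exact (validated by full sign-assignment enumeration for n ≤ 12)
for small n, normal approximation otherwise.

**Contingency analysis.** Genes with defined percent cis and nonzero
changes of both kinds are binned 2×2 by dominant effect (percent cis above
vs below ½) and direction agreement; each row's discordant fraction is
tested against ½ with an exact binomial test and the two rows are compared
with Fisher's exact test. The gene universe is optionally restricted to
differentially expressed genes.

## Expression quantification

Counts are normalized with median-of-ratios size factors computed over genes
positive in every sample and rescaled to geometric mean 1. FPKM uses the
*common* normalized library scale (the mean normalized library size) as its
per-million denominator: after ratio-based normalization all samples sit on
one scale, and dividing each sample by its own total would re-introduce the
compositional bias the factors removed — a population with a genuine global
expression shift would see every gene's FPKM deflated. Population log
ratios use means (not medians) of FPKM across replicates; this choice, and
every other analysis setting, is recorded in the run's resolved config.

Differential expression flags come from a declared stand-in test — Welch's t
on `log2(normalized count + 0.5)`, BH at 10% FDR — not from a count-model
engine; the method string travels in the output metadata so downstream users
cannot mistake its provenance. The 0.5 pseudocount exists only inside this
test; cis/trans estimation follows a filter-not-pad policy throughout. At
the default design (3 vs 3 replicates) the stand-in detects a 4-fold shift
at ~90% power (depth 1000, dispersion 0.05); a dedicated count model would
do somewhat better, and users needing calibrated DE inference on real data
should substitute one.

## Gene-set statistics

The expression-shift statistic is a t-of-t: Welch's two-sample t per member
gene (Welch rather than pooled-variance, since between-group variance
equality is not assumed; the choice is recorded in results), then a
one-sample t of the member t-values against zero. Members with zero
variance in both groups are dropped with a warning; a set whose retained
t-values are all zero is degenerate and reported as p = 1. Null calibration
is checked empirically: under a no-effect simulation the test rejects at
α = 0.05 at a measured rate of ~4–5%.

Bootstrap calibration draws B gene sets of the same size with replacement
from the matrix's gene universe and reports the one-sided add-one exceedance
estimate `p = (1 + #{null ≥ observed}) / (1 + B)`, in the direction of the
observed statistic; "larger than anything observed" therefore reports
`1/(1+B)`, never zero.

Sharing between two derived populations is quantified by Spearman rank
correlation of per-gene changes (genes finite in both; ties mid-ranked) and
by shared-direction counts, by default restricted to genes flagged
significant in both populations (configurable to all genes).

## Synthetic data

The generator emulates the target study design: one ancestral and up to two
derived populations with 3 parental replicates each, 2 F1 crosses with 5
hybrid replicates each, ~10^4 genes of which ~60% carry an informative
variant — proportions chosen to match a design in which roughly 9–12
thousand of ~22 thousand genes are quantifiable.

* **Effects.** A fraction `frac_null` (default 0.5) of genes has
  `c = t = 0` exactly; the rest draw independent centered normals
  (`cis_sd = trans_sd = 0.5`, a moderate regulatory divergence scale).
  The two-population generator shares `t` across populations while drawing
  `c` independently (default), emulating convergent evolution of the trans
  environment; this is the configuration under which the sharing analyses
  are validated.
* **Counts.** Per-gene baseline depth is log-normal with mean `mean_depth`
  (default 200 reads/gene/replicate, giving the pooled hybrid depth of
  ~1,000 at which recovery is validated) and log-sd `depth_spread = 0.5`.
  Counts are negative-binomial with `var = μ + φμ²`; `φ = 0` recovers
  Poisson. Default `φ = 0.01` (≈10% CV between replicates) represents
  well-controlled laboratory replicates; real tissue dissections are often
  noisier (φ of 0.05 and above), in which case trans-effect recovery
  degrades in proportion to the parental replicate variance — the
  recovery tolerances quoted below are properties of the default
  conditions, not of arbitrary data. Per-sample library size factors are
  log-normal (σ = 0.2) so the normalization code genuinely matters.
* **Hybrid allele counts.** Per replicate, a negative-binomial total is
  split binomially with success probability `f(c)`; the trans effect never
  enters the split, by the identifying assumption. Uninformative genes are
  emitted with missing counts.
* **Trio variants.** Informative genes receive ⌈Poisson(density·L/1000)⌉
  informative records (floored at one, a ~2% inflation of the mean at the
  default 2 variants/kb, so flagged genes are genuinely informative), plus
  ~Poisson(1) labeled decoys per gene — heterozygous parent, homozygous F1,
  multiallelic, missing genotype — which the informativeness filter must
  remove.
* **Reads** (optional path): drawn uniformly along each allele's sequence
  in proportion to the allele counts, with per-base substitution errors,
  each read labeled with its true allele so assignment accuracy is scored
  exactly.

What the generator does **not** model: splicing, mapping and reference bias,
GC effects, genome-divergence landscapes, imprinting, or cis-trans
interaction. Tests passing on this generator therefore demonstrate the
statistical machinery under the method's own assumptions; they do not
certify robustness to alignment artifacts on real data.

## Numerical and design choices

* Coordinates are 0-based half-open internally; VCF positions convert at the
  parser boundary. Substitution variants only; indels are skipped with a
  warning (the equal-length allele-pair representation is only well defined
  for substitutions).
* Read-to-allele assignment is by exact substring placement on both allele
  sequences: a read is assigned iff it overlaps ≥1 informative site and
  matches exactly one allele there, and is unassigned on no overlap, double
  match, or conflict. This is a desk-scale stand-in for unique-alignment
  filtering; reads carrying sequencing errors go uncounted rather than
  misassigned (with the default 0.1% error rate and 100-bp reads, ~10% of
  reads are lost this way), which biases depth, never direction.
* A cross in which one parent is genotyped via a sibling is handled as an
  ordinary parent slot — the informativeness rule is identical.
* All randomness flows from one root seed through named, order-independent
  substreams; every output is bit-reproducible given the seed, and each run
  writes its resolved configuration and package versions beside its outputs.
* Problem sizes used by the test suite and the acceptance script (5,000-gene
  recovery runs, 10,000-gene null runs, 500–1,000 calibration replicates,
  6,000-gene study simulations) were chosen as the smallest sizes at which
  the Monte-Carlo noise of each checked quantity is well below its
  tolerance.

## Known limitations

* The trans test inherits the overdispersion blind spot of count-based
  G-tests; its realized error rate is simulation-bounded, not guaranteed.
* Pooling replicates discards between-replicate information; a hierarchical
  beta-binomial model would gain power at low depth.
* Percent cis is unstable when `|C| + |T|` is small; downstream summaries
  use medians for this reason.
* The DE stand-in is calibrated but underpowered relative to count models;
  it exists to feed the contingency and sharing analyses, not to publish DE
  lists.
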