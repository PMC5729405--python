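# Methods

`bloodeqtl` maps the genetic control of blood gene expression in
family-structured cohorts with three coordinated analyses — a polygenic
mixed-model expression GWAS (eGWAS), an allele-specific expression (ASE)
caller, and regulatory-network construction — and ships a
synthetic-cohort generator whose known ground truth backs every
statistical claim the package makes.

## Expression preprocessing

Single-channel microarray intensities are modelled per array as the
convolution X = B + S of a normal background B ~ N(mu, sigma^2) and an
exponential signal S with mean alpha (the normexp model). Parameters are
fitted by method of moments: the third central moment of X belongs
entirely to the signal (m3 = 2 alpha^3), the variance splits as
sigma^2 + alpha^2 and the mean as mu + alpha. Each intensity is replaced
by the posterior mean

    E[S | X = x] = a + sigma * phi(a/sigma) / Phi(a/sigma),
    a = x - mu - sigma^2 / alpha,

evaluated on the log scale for deeply negative a/sigma so the output
stays strictly positive and monotone in x. Method of moments was chosen
over a saddle-point likelihood fit because it is closed-form and easy to
test; it is a deliberate dialect difference from limma's `normexp.fit`.

Probes are called expressed when their background-corrected intensity
exceeds 1.10x the per-array mean of negative-control probes on at least
4 arrays (both numbers configurable; the control summary can be switched
to the median). The filter runs on the background-corrected raw scale,
before the log2 transform. Quantile normalization then forces every
array onto the across-array mean of sorted values; ties receive the mean
of the reference values spanned by their rank block, which makes the
operation deterministic and idempotent.

## Genotype QC and kinship

Filters run in a fixed order: samples below 95% call rate, then SNPs
below 95% call rate, then SNPs with MAF <= 5% (the keep-rule is strictly
"MAF > 5%"), then SNPs whose exact Hardy-Weinberg p-value (conditional
tail-sum enumeration, robust at the small genotype counts typical of
desk-scale fixtures; a chi-square variant is available) falls below a
Benjamini-Hochberg q of 0.01 across SNPs. SNPs are sorted by chromosome
and position first so the removal report is independent of input order.

Genomic kinship is the per-SNP standardized estimator over autosomes,

    K_ij = (1/M) sum_k (g_ik - 2 p_k)(g_jk - 2 p_k) / (2 p_k (1 - p_k)),

with pairwise-complete averaging under missingness and monomorphic SNPs
excluded. On this scale self-relationship is ~1, half sibs ~0.25 and
full sibs ~0.5. Because allele frequencies are estimated from the cohort
itself, the off-diagonal mean is pinned near -1/(n-1) rather than 0;
tests account for this centring artefact rather than "correcting" it.

## Polygenic mixed-model eGWAS

For each probe the null model y = X beta + u + e is fitted with
u ~ N(0, sigma2_g K) and e ~ N(0, sigma2_e I); X carries an intercept
plus dummy-coded batch and sex. The kinship is eigendecomposed once
(eigenvalues clipped at zero) and shared across probes; on the rotated
basis the restricted likelihood is profiled over the variance ratio
h2 = sigma2_g / (sigma2_g + sigma2_e) with a bounded scalar optimizer
(absolute tolerance 1e-6, explicit check of the h2 = 0 boundary, total
variance floored at 1e-12 for exactly-collinear responses). With K = I
the profile is flat in h2 — the split is unidentifiable, as it should
be — while the total variance equals the OLS residual variance.

Each SNP is tested with the family-based score test at the null-model
estimates: with g~ and y~ residualized on X in the V^-1 metric,

    T = (g~' V^-1 y~)^2 / (g~' V^-1 g~)  ~  chi2(1),
    b = (g~' V^-1 y~) / (g~' V^-1 g~).

Monomorphic or covariate-collinear SNPs yield NaN rather than an error.
Missing dosages drop those samples for that SNP only, with the null
refitted on the complete subset (no imputation). The batch implementation
exploits the fact that the numerator needs only one residualized vector.

Significance is two-level Benjamini-Hochberg: a step-up pass across SNPs
within each probe and a second pass across all probe x SNP tests; an
association counts only if its p-value is at or below the largest
rejected p of both passes. Redundant significant SNPs are then pruned:
per probe, the most significant remaining SNP becomes the lead (ties
broken by smaller p, then chromosome, then position), and every other
significant SNP within 5 Mb of it on the same chromosome is retested
with the lead dosage added as a fixed covariate. A SNP whose conditional
p no longer clears the stored thresholds is redundant; survivors may
seed their own eQTL. The conditional retest applies both thresholds by
default (configurable to either alone, since the source procedure names
only "the previously calculated significance threshold"). A conditional
test that returns NaN — the candidate is collinear with its lead — is
treated as redundant.

eQTL-SNPs are local when on the probe's chromosome within 1 Mb of the
probe start, inclusive at exactly 1 Mb, distance measured to the probe
start; otherwise distant. Effect sizes are summarized as |b| divided by
the probe's sample SD (n-1 denominator). Per-chromosome enrichment uses
one-sided Fisher exact tests (enrichment and depletion separately) on
the on/off-chromosome 2x2 table, plus a chi-square comparing the
local/distant/both composition of each chromosome against the rest.

## ASE calling

Input rows are per-sample allele counts at SNP sites (ASEReadCounter
column semantics). Entries with fewer than 10 reads are dropped; sites
whose cohort-wide minor-allele read count is not strictly greater than 3
are dropped (a per-sample variant of the MAC rule is available, the
wording of the source being ambiguous); sites with more than one
observed ref or alt allele are dropped as non-biallelic. Each remaining
heterozygous entry gets an exact two-sided binomial test of
alt ~ Binomial(ref+alt, 0.5) in the "minlike" convention (sum of
probabilities of outcomes no more likely than observed). P-values are
BH-corrected within each animal at 5e-2. A site is an ASE-SNP when
significant imbalance appears in strictly more than one-third of its
heterozygous animals (the strict reading of the aggregation rule is the
default; the at-least-one-third variant is a flag). Sites with no
heterozygotes are untestable, not negative.

The test is a plain binomial: read-count overdispersion is deliberately
not modelled, matching the procedure being reproduced, and the simulator
can inject negative-binomial overdispersion to quantify the resulting
anticonservativeness. Heterozygosity comes from the genotype column of
the input — genotype calling is upstream of this package — and allelic
imbalance cannot be distinguished from parental imprinting.

Sites map strand-agnostically to every overlapping gene interval
(1-based inclusive). The detectable universe is the set of expressed
genes (>= 10 reads in some sample) overlapping at least one tested
heterozygous site. Integration with the eGWAS labels each shared gene:
local eQTL + ASE = cis-validated; distant eQTL + ASE = cis+trans
candidate, flagged further when the eQTL-SNP lies on another chromosome.

## Networks and PCIT

Significant associations become a bipartite directed graph, SNP ->
probe (optionally collapsed to genes, with multi-probe hits accumulating
as edge weight). Components are taken on the undirected skeleton; the
mean-degree summary counts undirected neighbors. Master regulators are
SNP nodes with at least 10 distinct targets.

Co-expression among one regulator's targets is filtered with PCIT
(partial correlation with an information-theory tolerance): for every
trio (x, y, z), first-order partials r_xy.z etc. are formed, the trio
tolerance eps is the mean of the three partial-to-marginal ratios, and
the edge (x, y) is discarded if for some z both |r_xy| <= |eps r_xz| and
|r_xy| <= |eps r_yz|. Trios containing a unit correlation are skipped as
degenerate. One behavioural subtlety is documented in the tests: a
conditionally independent edge is only rejected when the direct
correlations are moderate (e.g. r_xz = r_yz = 0.5 gives eps = 0.596 and
rejection of r_xy = 0.25), whereas very strong direct edges shrink the
tolerance enough that the indirect edge survives (r_xz = r_yz = 0.9,
r_xy = 0.81 is kept). This is a property of the tolerance formula, not a
bug.

## Synthetic cohorts

The generator emulates a paternal half-sib livestock cohort
("common boars"): sires and dams are diploids drawn from population
haplotypes with first-order Markov (AR(1) Gaussian copula) LD along each
chromosome; each progeny receives one recombinant gamete per parent,
with Haldane recombination fractions at 1 cM/Mb and independent
chromosomes. Dams are per-progeny by default; a dam-assignment map lets
tests build full sibs. MAFs are uniform on a configurable range.

Expression is y = mu + batch + sex + sum(beta g) + u + e per probe, with
u drawn from N(0, h2 K) using the realized genomic kinship (so the
fitting model is correctly specified) and e ~ N(0, 1 - h2): the residual
variance around the fixed genetic effects is 1 and all effect sizes are
in residual-SD units, which makes the effect/SD ratio statistic equal to
|beta| under the null of no other effects. cis-effect probes are placed
within 1 Mb of their causal SNP; trans SNPs sit on a different
chromosome than their probe. The cis-regulated genes double as the
true-ASE genes — the biologically coherent choice, since a cis variant
is exactly what produces allelic imbalance. Negative-control probes are
pure unit-variance noise at a low baseline.

Allele counts per heterozygous sample x site have negative-binomial
coverage (variance m + theta m^2; Poisson at theta = 0) split
binomially at 0.5 (null) or at the configured imbalance fraction
(true-ASE sites); homozygotes emit single-allele reads.

Defaults: 10 sires x 25 progeny (250 animals, the scale at which a 1-SD
effect is comfortably detectable), 500 SNPs on 5 chromosomes of 50 Mb,
adjacent-SNP copula correlation 0.3, polygenic h2 0.3, effects of 1
residual SD, batch effects of SD 0.5 over 3 levels, sex effects of SD
0.2, ASE coverage mean 50 with dispersion 0.1 and imbalance fraction
0.8. Where the emulated study reports no value (family sizes, LD,
coverage), these are fixed at levels a quantitative geneticist would
call realistic for a SNP-chip/RNA-seq livestock design and are not
tuned per analysis.

What the generator does not emulate: genotyping error and missingness
patterns, X-linked dosage, reference-mapping bias in allele counts
(inputs are assumed pre-masked), imprinting, probe cross-hybridization,
and LD structure richer than first-order Markov. Passing tests therefore
demonstrate correctness of the statistics under the stated model, not
robustness to these real-data artefacts.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere internally; BED export
  converts to 0-based half-open at the boundary.
- BH thresholds are implemented as "p <= largest rejected p" (step-up
  semantics), not "q <= alpha" per record, though the two agree.
- The exact binomial p-value is cached on (min(k, n-k), n), which makes
  cohort-scale ASE scans cheap.
- Lead-SNP ties break by p, then chromosome label (numeric-aware), then
  position, so pruning is invariant to record order.
- Eigenvalues of kinship matrices are clipped at zero before use; the
  same clipped matrix backs both the fast rotated REML and the
  full-matrix grid-search oracle used in tests.
- Problem sizes in the test suite and acceptance script (cohorts of
  150-500 animals, 40-300 SNPs, tens of probes, 30-200 replicates) are
  chosen as the smallest scales at which the tested guarantees are
  statistically sharp.

## Known limitations

- The REML profile assumes a single kinship component; cage/pen or
  maternal environmental covariance would be absorbed into h2.
- The per-probe refit is exact but O(probes x optimizer steps); genuinely
  large panels would want the approximate residual-reuse shortcut this
  package intentionally avoids.
- The ASE caller's binomial test is anticonservative under real
  overdispersion; the simulator quantifies but the caller does not
  correct this.
- PCIT keeps indirect edges between very strongly correlated variables
  (see above); interpret surviving edges accordingly.
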