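# Methods

## Problem setting

Blood plasma carries at most a few thousand copies of microbial DNA per
millilitre, while the reagents used to extract and amplify it carry their
own microbial DNA (the "kitome").  In 16S rRNA amplicon data from such
low-biomass samples, most amplicon sequence variants (ASVs) are therefore
contaminants, and their abundances shift with every technical variable:
sequencing run, DNA-extraction batch (DEB) and extraction day.  This
package implements a contaminant-controlled framework that separates
genuine cell-free microbial DNA (cfmDNA) from that background, using the
experimental design itself — extraction negative controls (DENCs) in
every batch, and replicate extraction of the same patients across two
batches — as the source of evidence.

## Preprocessing

Count tables are validated (non-negative integers, unique ids), ASVs
classified as eukaryota/mitochondria/chloroplast are removed, PCR
replicates of one biological sample may be merged by summing, and within
each sample-type stratum ASVs holding strictly less than 0.01% of the
stratum's reads are zeroed out.  The 0.01% floor and the 0.1%/1%
abundance-class boundaries used in reporting are distinct constants.
Rarefaction draws a multivariate hypergeometric subsample per sample,
seeded per (global seed, sample index) so a sample's rarefied counts do
not depend on which other samples are present.

## Diversity and community structure

Alpha diversity: richness (observed ASVs) and inverse Simpson
(1/Σp²).  Beta diversity: Bray-Curtis on rarefied, square-root
transformed counts (the pipeline preset), and the Aitchison distance
(Euclidean distance of CLR-transformed counts + offset 1) as the
compositional counterpart.  UPGMA (average linkage) produces an
ultrametric tree serialisable to newick; linkage ties are resolved by
scipy's deterministic cluster-creation order.

PERMANOVA partitions the Gower-centred inner-product matrix of squared
dissimilarities with sequential (Type I) sums of squares, so term order
is meaningful and interaction terms follow their main effects.  p-values
come from label permutations with the identity permutation included in
the null set and ties counted as exceedances (conservative); the floor is
1/(n_perm+1).  The repeated-measures-aware variant restricts every
permutation to shuffle labels within subject blocks only, which keeps the
within-patient correlation of replicate extractions intact under the
null.  Every generated permutation maps each sample to a sample of the
same block; this is asserted in tests over 10⁴ draws.

## Criterion (i): batch-effect screen

Because extraction day is nested in DEB which is nested in sequencing
run, a single linear model with extraction day as the only factor (one
coefficient per day, no intercept) spans all three technical variables,
and every comparison is a contrast of day means: all run pairs, all DEB
pairs, and day pairs within a shared DEB only.

Counts are TMM-normalised (doubly trimmed — 30% on M, 5% on A —
precision-weighted mean of log-ratios against an upper-quartile
reference; factors rescaled to geometric mean 1) and transformed to
log2-CPM with a 0.5 prior count.  Precision weights follow the voom
recipe on the log-CPM scale: ASV-wise OLS residual sqrt-standard
deviations are smoothed against mean log-CPM by lowess (span 0.5), the
trend is evaluated at each observation's fitted value, and the weight is
the inverse fourth power.  Sparse ASVs (fewer than 3 nonzero samples)
are excluded from trend *fitting* but still scored from the fitted
trend, and each ASV's residual df is reduced by its number of
all-zero design cells (floored at 1) — a guard against zero-variance
cells in very sparse data.

Repeated measures (the same patient extracted in two DEBs) are handled by
a consensus correlation: per ASV, the mean product of standardised
residuals over within-patient pairs, pooled across ASVs by a 15% trimmed
mean on Fisher's z scale; model fitting then uses generalised least
squares with a block-equicorrelated covariance at that rho.

Residual variances are shrunk by empirical Bayes: (d0, s0²) estimated by
moment matching of log s² against the scaled-F model (trigamma
inversion), falling back to d0=∞ with s0²=mean(s²) when the excess
variance is negative.  Moderated t = estimate/(unscaled SE · s_post),
with d0+d degrees of freedom.  p-values are BH-adjusted in one family
per technical variable (pooling that variable's contrasts across all
ASVs); an ASV with FDR ≤ 0.05 in any contrast of any variable is
flagged as batch-affected.  DENCs are excluded from this model by
default — the criterion concerns abundance differences among plasma
samples — with a config switch.

With d0 pinned to 0 the statistic reduces to the ordinary weighted
least-squares t (verified against statsmodels in the tests).

## Criterion (ii): prevalence against negative controls

For each DEB, each ASV's presence/absence 2×2 table (plasma vs
plasma-DENC) is scored one-sided, small values meaning
contaminant-direction (higher prevalence fraction in controls).  The
score is the halved two-sided chi-square (1 df, no continuity
correction) tail, oriented by the prevalence fractions; when any
expected cell is below 5 or the total below 20, the mid-P hypergeometric
tail on control presences, P(X>c)+P(X=c)/2, replaces it.  Mid-P rather
than the plain tail keeps uninformative tables (an ASV present in every
sample and every control) at 0.5 instead of 1.0, matching the chi-square
branch's convention and preserving monotonicity in each margin.
Per-batch scores are combined by their minimum (batches where the ASV is
entirely absent, or that lack controls, contribute none) and an ASV is
classified contaminant when the combined score is strictly below 0.55.
ASVs occurring only in batches without controls remain unscored and are
not classified real.

## Criterion (iii): replicate-detection agreement

Patients extracted in both batches of the replicate pair give matched
detection calls per ASV.  Cohen's kappa on the resulting 2×2 agreement
table, with the large-sample Fleiss null standard error, provides the
test; an ASV passes with kappa > 0.4 and two-sided p < 0.05 (strict).
Degenerate marginals (expected agreement 1, or a null SE of zero) yield
no test; such ASVs are treated as not applicable.

The criterion gates only ASVs whose plasma detections are confined to
the replicate batch pair; ASVs also seen in other batches are judged on
criteria (i), (ii) and (iv) alone.  Rationale: for an ASV observed in
many batches the other criteria already have power, whereas an ASV seen
only in the replicated pair has exactly one usable source of evidence —
whether it hits the same patients twice.  At realistic pair counts
(12–13) and a 10% per-sample detection dropout, the kappa test's power
is about 0.7, so gating every ASV on it would discard true signal the
other criteria accept.  The broader scope remains available as
`PipelineConfig(criterion_iii_scope="observed")`.

## Criterion (iv): taxonomy evidence

Candidates are classified into six mutually exclusive categories
crossing contaminant-blocklist membership with evidence status
(documented commensal/pathogen, no evidence, or unclassifiable at
family/genus rank).  "Likely contaminant" (blocklisted, no evidence) and
"no evidence" (classifiable but unknown to the literature) are
discarded; everything else is retained — including order-level-or-above
ASVs, which may represent novel organisms.  Matching is exact on
normalised names (case-folded, bracketed synonyms stripped), genus
first then family, with no fuzzy matching so the filter stays auditable.
A consensus-taxonomy helper truncates two classifications at their
deepest agreeing rank prefix.  Evidence lists are user-supplied TSVs
(name, rank, source).

## ddPCR quantification and GEE

A reaction with k positive of n droplets has λ = −ln(1−k/n) mean copies
per droplet; dividing by the droplet partition volume (default
8.5×10⁻⁴ µl, the platform's nominal value — configurable since it
rescales every concentration) gives copies/µl, convertible to copies per
ml of source fluid via eluate and source volumes (defaults 50 µl and
2 ml).  A target is called detected when the summed amplifiable
molecules across the duplicate reactions reach 2.  Group comparisons of
concentrations and alpha diversity use Gaussian GEE (statsmodels) with
exchangeable working correlation and robust sandwich errors, clustering
on patient; with singleton clusters the estimates equal OLS.

## Synthetic cohorts

The generator reproduces the statistical structure the framework
assumes, not reads: five DEBs (A–E) of 12 plasma + 8 DENC samples, DEB B
re-extracting DEB A's patients, two extraction days per batch, two
sequencing runs (A,B vs C,D,E).  200 contaminants (150 shared, 50
batch-specific) get log-normal base abundances (σ=1.5); shared
contaminants get per-batch log-normal multipliers (σ=1) creating the
batch effects criterion (i) detects, except that half the shared kitome
is batch-stable (σ=0.1) — ubiquitous water/plasticware taxa — so that
criterion (i) alone does not remove every contaminant and criterion (ii)
carries real weight, mirroring the observed structure in which hundreds
of ASVs pass the batch screen yet fail the prevalence test.
Batch-specific contaminants occur only in their batch's samples *and*
its DENCs.  Twenty true ASVs are planted at 0.1–1% relative abundance in
a random 60% of patients each (consistent with reported per-ASV patient
prevalences of 13–80%), never in DENCs, replicated across the A/B pair
minus a 10% per-sample detection dropout.  Reads are multinomial at
log-normal depth (median ≈ 30k reads).  Taxonomy is drawn from
configurable genus pools so blocklist matching is exercised; the default
evidence list deliberately includes dual-use genera (Pseudomonas,
Acinetobacter, Stenotrophomonas, Burkholderia) — kitome taxa with
genuine pathogen literature that the taxonomy filter alone cannot
discard.

What the generator does not emulate: sequencing error and chimeras,
taxonomy misclassification, compositional interaction between true
signal and contaminants beyond renormalisation, overdispersion beyond
the log-normal batch multipliers, and patient-level covariates.  Passing
recovery tests therefore demonstrate the *logic* of the framework under
its assumed structure, not performance on real cohorts.

Mock communities (20 evenly mixed strains under a fixed log-normal PCR
bias shared across runs) and ten-fold dilution series (target reads
proportional to concentration under a saturation plateau, contaminant
reads constant in expectation) are provided for the consistency and
limit-of-detection properties.

## Numerical choices and problem sizes

Permutation defaults: n_perm=999, p floor 1/(n_perm+1).  The type-I
error simulations in the test suite use 500 replicates of 16 samples at
199 permutations; the null/power screens use 300–500 ASVs across 3
batches of 12–15 samples over 20 seeds; end-to-end recovery uses the
default cohort above at a fixed seed.  These sizes were chosen so every
Monte-Carlo bound sits at least 3 standard errors from its threshold.
GEE convergence tolerance 1e-8, max 100 iterations.  Chi-square
prevalence scores use no continuity correction, the standard convention
for prevalence-based contaminant scoring.  All generators are `numpy.random.default_rng` seeded
explicitly; the full pipeline is byte-deterministic for a fixed seed.

## Known limitations

- The moderated-statistics stack is a faithful re-implementation, not a
  bit-exact limma port; on shared synthetic data its flag set differs
  from limma's by ~1% of ASVs at the FDR boundary.
- Criterion (iii) has limited power below ~10 replicate pairs; at 12
  pairs and 10% dropout roughly a third of true ASVs fail it, which is
  why its gating scope matters (see above).
- Prevalence scoring assumes every batch contributes DENCs; batches
  without controls are skipped, and ASVs confined to them stay unscored.
- BIOM support covers the v1 JSON dialect only.
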