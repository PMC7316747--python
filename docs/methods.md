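# Methods

`phenoharmon` studies a phenotype-definition problem that arises in
case-control GWAS of ischemic stroke: several rival clinical systems
(TOAST, CCS-causative, CCS-phenotypic) assign each patient a stroke
subtype (cardioembolic CES, large-artery LAS, small-vessel SVS), their
agreement is only moderate, and the choice of case definition changes
what a GWAS can detect. The package builds composite case definitions
from the per-system assignments — the *intersect* (all systems agree on
the subtype), the *union* (any system assigns it) and the *symmetric
difference* (union minus intersect) — and provides the statistical
machinery to compare them: association scans, SNP-heritability on the
liability scale, significant-SNP overlap curves, odds-ratio extremeness
at externally reported loci, LD clumping with cross-definition
de-duplication, and fixed-effects meta-analysis. Everything runs end to
end on synthetic cohorts whose misclassification structure is under the
user's control.

## The synthetic cohort model

**Genotypes.** Each haplotype is a latent standard-Gaussian AR(1)
process along the SNP axis (autocorrelation `ld_rho` within an LD block
of `ld_block_size` SNPs, independent across blocks and chromosomes),
thresholded at Φ⁻¹(f_j) so SNP j has allele-1 frequency exactly f_j
(drawn uniformly from `maf_range`, default 0.05–0.5). Dosage is the sum
of the two haplotype alleles. This latent-threshold construction
controls LD strength and allele frequency independently, but note that
thresholding *attenuates* correlation: a latent ρ = 0.9 yields
adjacent-SNP genotype r² ≈ 0.3–0.5 depending on the frequency mismatch
of the pair (the phi coefficient is bounded above by the frequency
match). Tests validate the generator against a direct bivariate-normal
Monte-Carlo oracle at the simulated frequencies rather than against ρ²
itself.

**Subtypes.** Each subtype s has a disjoint set of `n_causal_per_subtype`
causal SNPs with Gaussian effects on standardized dosage, rescaled so
the genetic variance of the subtype's liability is exactly
`h2_liability[s]`; environmental noise has variance 1 − h². A sample is
a case of subtype s when its liability exceeds the threshold
t_s = Φ⁻¹(1 − K_s) set by the population prevalence K_s; when several
thresholds are exceeded the subtype with the largest exceedance wins.
Cases are ascertained from a chunked population stream until each
subtype's quota fills; controls are screened against *every* threshold
(the usual super-control design), so the study prevalence P differs
from K — exactly the situation the liability conversion below is built
for. The default K = 0.10 per subtype is a simulation-scale choice:
real stroke-subtype prevalences (~10⁻³) would require pools of 10⁵–10⁶
samples per cohort for nothing the desk-scale analyses are sensitive
to, since K enters only through the conversion factor.

**Classifiers.** Each subtyping system observes the true subtype through
a confusion matrix over {subtypes, 'undetermined'}; systems are
conditionally independent given the true label. `calibrate_confusion`
bisects a single correct-assignment probability c (misassignment mass
split between 'undetermined', share `undetermined_share`, and the wrong
subtypes uniformly) until the closed-form expected Cohen's κ of two such
systems hits a target (default 0.6, in the published 0.56–0.71 range for
TOAST-vs-CCS agreement). One system (the CCS-phenotypic analogue) may
emit a secondary subtype label with probability `secondary_label_prob`;
"assigned subtype s" means s is anywhere in the label set.

*Limitation:* under conditional independence, a κ of 0.6 forces
c ≈ 0.84 and hence an undetermined fraction of only ~5%. Real subtyping
systems put over a third of cases in 'undetermined' while keeping
moderate κ, which requires their errors to be correlated by case
difficulty. The confusion-matrix model deliberately omits that
correlation; the high-undetermined regime is reachable (lower c, higher
`undetermined_share`) but then κ is low. Conclusions that depend on
correlated classifier errors are outside what these simulations can
support.

## Association scans

Case status (0/1) is regressed on dosage per SNP with fixed covariates —
intercept, sex, and the top `n_pcs` principal components of the
standardized genotypes of the analyzed subset (default 10) — using a
vectorized residualization (QR on the covariates, then per-SNP
univariate slopes). Linear regression of the binary trait is the
deliberate model choice: its betas live on the observed scale where the
conversion log(OR) = β/(μ(1−μ)), with μ the case fraction, applies, and
it mirrors the effect-size scale of the mixed-model software used in
large stroke GWAS. A per-SNP logistic option exists for cross-checks; at
desk sample sizes the two z-scores correlate >0.99. Two-sided p-values
use the normal reference (the t correction is ~0.3% at n in the
thousands). SNPs below 1% MAF in the analyzed subset are not tested and
a separate 5% MAF filter is applied for downstream comparisons. The
genomic inflation factor is median χ²/0.4549; on null cohorts
(h² = 0) the scan's type-I error at α = 0.05 is calibrated within
binomial noise and λ_gc is 1 within median-sampling noise
(sd ≈ 2.33/√m, which is why the null-calibration check uses
m = 20,000 SNPs).

Each definition's scan uses that definition's cases plus the single
shared control set; cases outside the definition are excluded entirely.

## Heritability

The genetic relationship matrix is built from QC'd SNPs — per-SNP
missingness ≤ 1%, per-sample ≤ 5%, MAF ≥ 0.10, Hardy-Weinberg χ² p ≥
0.001, optional region masks (e.g. MHC-like exclusions; the synthetic
map defines none by default) — then greedily LD-pruned in 100-SNP
windows, step 50, at r² > 0.2, with the lower-MAF SNP of an offending
pair dropped. GRM entries are (1/m) Σ_j x_ij x_kj with x standardized by
√(2f(1−f)) at sample frequencies.

Observed-scale h² is the Haseman-Elston slope: the through-origin
least-squares regression of phenotype cross-products y_i y_j
(covariate-residualized, standardized y) on off-diagonal GRM entries,
over all pairs i < j. Its standard error is a delete-one-block jackknife
over samples (200 contiguous blocks by default, computed in closed form
from row sums). A single-component REML alternative (direct likelihood
maximization on the GRM eigenbasis, curvature SE) is available as a
cross-check; the two agree within joint SE on simulated traits.

Conversion to the liability scale under case-control ascertainment uses

    h²_liab = K²(1−K)² / (P(1−P) φ(t)²) · h²_obs ,   t = Φ⁻¹(1−K),

which is exact at K = P = 0.5 (factor π/2) and ≈ 2.905 at K = 0.01,
P = 0.05. Two definitions' estimates are compared with an independent
two-sample z test, (h²_a − h²_b)/√(se²_a + se²_b); this ignores the
sample overlap between nested definitions (intersect ⊂ union), which
makes it conservative in the direction of interest — the
intersect-vs-symmetric-difference comparison is the sample-disjoint
sensitivity analysis.

At the simulation sizes used in the test suite (≈600 GRM SNPs,
1,400–1,700 samples), two small downward biases are visible and
documented rather than hidden: the MAF ≥ 0.10 GRM filter drops ~11% of
causal SNPs (maf_range starts at 0.05), and residualizing on 10 PCs of
a 600-SNP matrix absorbs a few percent of genuine polygenic signal
(≈0.05 on the liability scale; at real GWAS SNP counts the per-PC
absorption is negligible). The headline comparison — intersect h²
exceeding union h² when classifiers are noisy — is insensitive to both,
and the intersect estimate still recovers the simulated h² within two
jackknife SEs.

## Overlap analysis

z = β/se per SNP, deliberately not mean-centered so direction of effect
is preserved. At each threshold Z in 0, 0.1, …, 3 the significant set is
{SNP : |z| > Z} (strict inequality); two scans are inner-joined on SNP id
and compared by the Jaccard index |A∩B|/|A∪B| and by the Pearson
correlation of z-scores over the shared set (flagged undefined below two
shared SNPs or at zero variance). Jaccard of two empty sets is defined
as 1 — the self-comparison limit; with the threshold grid capped at 3
and genome-scale SNP counts the case never arises in practice. The
overall index over five definitions is |significant in all|/|in any|,
and is never above any pairwise index.

## Known-locus lookups

Odds ratios from every definition are harmonized to the reported effect
allele (1/OR when alleles are swapped, beta and z sign-flipped, FREQ1
mirrored); strand-ambiguous A/T and C/G SNPs are removed since strand
cannot be resolved. "Most extreme OR" is operationalized as the largest
|log OR| — the only reading symmetric in risk and protective directions;
exact ties count against the focal definition. The count of most-extreme
successes is tested against the equal-chance null p₀ = 1/(number of
definitions) with the exact two-sided minimum-likelihood binomial test
(the convention of standard statistical environments; validated against
full enumeration to 1e-12).

## Clumping and meta-analysis

Clumping is greedy by significance: the most significant unassigned SNP
with p < 1e-5 seeds a clump and absorbs unassigned SNPs within 250 kb
and r² > 0.05 with the index (in-sample LD by default; any r² source can
be supplied). Clumps whose index reaches p < 5e-8 are flagged
genome-wide. Across definitions, clumps collapse to one locus when their
indices coincide or lie within `merge_kb` and are in LD; the default
window equals the 250-kb clumping distance, and widening it (e.g. to
300 kb) reproduces the manual merge of two linked indices 260 kb apart
that the window alone would leave separate. Pairs with no LD information
are treated as unlinked and logged.

Meta-analysis is fixed-effects inverse-variance: weights 1/se², pooled
β = Σwβ/Σw, pooled se = (Σw)^{-1/2}, requiring ≥2 studies with
harmonized effect alleles. The pipeline's built-in replication
demonstration splits a cohort into alternating halves, scans both, and
pools the top discovery SNPs; at adequate power the two halves agree in
effect sign at causal SNPs in ≥95% of seeds.

## Reproducibility and numerical conventions

Identical configuration + seed gives byte-identical cohorts and pipeline
outputs; per-stage seeds derive from the master seed by stable hashing
(CRC32 of the stage name) so stages re-run independently. Positions are
1-based, intervals closed, distances in base pairs; A1 is the effect
allele throughout. Floats are serialized with a fixed %.10g format so
write→read→write is byte-identical. Zero-variance SNPs are flagged and
skipped rather than erroring a whole scan; degenerate κ (single-category
data), μ ∈ {0,1}, K or P ∈ {0,1}, and single-study meta calls raise
typed errors.

Test-suite problem sizes (chosen once): the intersect-vs-union
heritability comparison runs 25 seeds at 400 cases/subtype, 1,200
controls, 600 SNPs, h²_liab = 0.25, K = 0.10, κ ≈ 0.6; null calibration
uses one cohort with 20,000 independent SNPs; clumping is verified
against a brute-force oracle on 100 random 30-SNP scans; replication
sign-consistency uses 30 split-half cohorts. What passing shows is
internal consistency of the estimators and the direction of the
definition effects under the stated generative model — not performance
on real genotype data, with its imputation structure, cryptic
relatedness, ancestry stratification and correlated classifier errors.
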