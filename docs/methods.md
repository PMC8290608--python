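# Methods

This note documents the models, the simulator, the numerical choices, and
the limitations of `mirqtl`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Repeated-measures pre-adjustment

Each trait (one wavenumber absorbance or one predicted composition trait)
is adjusted from test-day records to a single value per cow with the model

y = Xβ + Za + e,  a ~ N(0, I σ²_anml),  e ~ N(0, I σ²_e),

where X holds an intercept, parity class (5 levels: 1, 2, 3, 4, ≥5),
days-in-milk class (nine 30-day intervals from calving; DIM is 1-based and
values past day 270 are capped into class 9), herd-by-test-day classes,
breed proportions (HOL, FR, JE; HOL absorbed into the intercept for
identifiability, since proportions sum to one), and six pairwise heterosis
proportions (het_AB = sire_A·dam_B + sire_B·dam_A). Reference levels are
dropped; columns that are identically zero (e.g. heterosis pairs for breeds
absent from the data) are removed. The animal effect is deliberately iid —
no pedigree covariance — matching the pre-adjustment stage's purpose of
removing environment, not of estimating breeding values.

REML is computed on the profiled scale: with λ = σ²_anml/σ²_e, the
block-diagonal structure of ZZ′ (records grouped by animal) reduces each
restricted-likelihood evaluation to grouped sufficient statistics
(X′X, per-animal column sums, per-group Gram matrices), so a fit costs a
p×p eigendecomposition regardless of record count. The maximiser is found
by locating a sign change of the **analytic score** dl_R/dλ on a log grid
and polishing with Brent root-finding (xtol 1e-12). We chose the scored
1-D profile over average-information updates because it cannot diverge, it
handles the λ→0 boundary by inspection (flagged `boundary`), and it pins λ
far below the noise floor of derivative-free search — which is what makes
the adjusted phenotypes invariant to adding a constant to every record at
the 1e-9 level. y is centred before fitting (mean folded back into the
intercept) for the same conditioning reason.

The adjusted phenotype is ŷ_i = â_i + mean_j(ê_ij); the module recomputes
it as mean_j(y_ij − x′β̂) and asserts agreement to 1e-9 on every call.

## GWAS engine

The association test is the standard two-stage mixed-model Wald test.
Variance components (σ²_g, σ²_e) are estimated per trait by REML under
y = 1μ + g + e, g ~ N(0, G σ²_g), on the eigenbasis of the full-panel GRM
(1-D profile over δ = σ²_e/σ²_g, bounded Brent, tolerance 1e-8), and reused
for every segment rather than re-estimated per leave-one-segment-out (LOSO)
covariance. This EMMAX-style approximation is what makes a desk-scale scan
tractable; its adequacy is checked directly by the null-trait calibration
(fraction of p < 0.01 and genomic inflation λ, both asserted within bands).

The GRM is G = WW′/m on centred dosages scaled by 1/sqrt(2pq), built from a
medium-density panel (by default every 5th variant, after a MAF ≥ 0.001
filter computed in the analysed animals). LOSO removes a 5-Mbp segment's
panel columns by the exact rank-k downdate (mG − W_sW_s′)/(m − m_s);
equality with a from-scratch rebuild to 1e-10 is part of the acceptance
checks. Segments are fixed genomic bins [k·5Mb, (k+1)·5Mb).

Per segment, all variant tests are batched through one Cholesky
factorisation of V = σ²_g·G_LOSO + σ²_e·I; effects, standard errors and
1-df chi-squares come from the projected quadratic forms. A dosage whose
OLS R² on the covariate set exceeds 0.99 is flagged `skipped-collinear`
rather than tested. p-values are computed in log space via
sf_chi2(x;1) = 2·sf_normal(√x), so −log₁₀p is finite and accurate
thousands of orders of magnitude below floating-point underflow; the stored
`p` is clamped to the smallest positive float to keep p ∈ (0, 1].

The Bonferroni threshold is α/(n_traits · n_variants). Counting QTL
regions uses distinct (chromosome, floor(pos/1 Mbp)) bins with at least one
significant variant.

## Iterative conditional tagging

Per trait: chromosomes with any variant beyond the threshold each
contribute their most significant variant (ties broken by larger χ², then
smaller position, then lexicographic id) to one shared covariate set; the
scan reruns on the chromosomes that retained significance; the loop stops
when none does (cap 25 iterations). Tags selected from the base scan carry
iteration 0. Covariates accumulate across chromosomes; variance components
are not re-estimated after conditioning (consistent with the two-stage
engine). A monotonicity guard halts if a chromosome *gains* significance
during conditioning; a final all-chromosome confirmation scan with every
tag fitted is returned alongside the tags, with a flag recording whether
any previously significant chromosome still harbours a signal.

## Candidacy tiers and co-localization

LD is the squared Pearson correlation of dosage vectors. PIV links use a
1-Mbp window centred on the tag, inclusive at both ±500-kb edges, and
require r² > 0.9. The two-tier rule is implemented with half-open LD bins
and strict thresholds exactly as printed: HIGH at (0.975, 1] & >1.5B,
(0.95, 0.975] & >2B, (0.925, 0.95] & >2.5B; otherwise MODERATE at r² > 0.9
& >B. The tier bins are read on the same squared-correlation scale as the
0.9 filter (an |r| reading is available behind the `ld_scale` flag; the
default is recorded in the run manifest).

The eQTL scan is a GLS slope test with covariance σ²_a·A + σ²_e·I, A being
the numerator relationship matrix from the tabular recursion
(a_jj = 1 + a_{s,d}/2, a_ij = (a_{i,s} + a_{i,d})/2, unknown parents
contribute zero), variance components by per-gene REML on A's eigenbasis.
Its significance threshold is Bonferroni at α = 0.05 over the number of
tests performed. Co-localization computes Pearson correlations between the
−log₁₀p vectors of trait and eQTL scans over the shared variants of 1-Mbp
and 0.5-Mbp windows centred on the trait tag (the correlation is invariant
to the logarithm base); a call requires the better correlation > 0.7 and
tag-to-top-eQTL LD r² > 0.9, both strict. Windows with fewer than 30
shared variants (a guard of ours; the threshold is configurable) are
skipped.

## Significance profiles and clustering

A locus's profile is its −log₁₀p across all wavenumber traits, scaled to
sum to one over unmasked entries (masked entries — excluded or
non-converged traits — are zeroed; an all-zero profile is an error, not a
silent NaN). Distances are Euclidean over wavenumbers unmasked in both
profiles. Complete-linkage agglomeration is implemented directly (the
merge criterion is the largest pairwise member distance) with a
deterministic lexicographic tie rule on cluster ids, and is checked in the
tests against both scipy's implementation and a brute-force O(n³) oracle.
The dendrogram exports as a merge table and as Newick; no automatic cut
height is imposed — the cut count is a user parameter. Representative-
variant selection prefers PIV links over eQTL links, then maximal LD, then
smaller p, then position.

## The synthetic generator

The generator's defaults are the study-scale conditions used throughout
the tests: 2,000 cows from 25 sires × 1,000 dams (two-generation half-sib),
3 chromosomes × 5,000 variants over 50 Mbp, 895 wavenumbers evenly spaced
on 649–3998 cm⁻¹, and ten planted QTL (3–5% of trait variance each, all in
distinct 1-Mbp regions, two of them 20 Mbp apart on one chromosome).

**Genotypes.** Each 100-kbp block carries a chain of H = 4 founder
haplotype states shared by the three breeds; a marker's alternate allele
occupies a contiguous run of states whose length is set by a Beta(0.5,
0.5)-drawn target frequency. Markers with identical runs are perfectly
correlated and nested runs correlate strongly, so adjacent-marker r² is
high within blocks (≈0.4 on average, with a long tail at 1) and near zero
across blocks; with H = 2 every polymorphic pair in a block has r² = 1 by
construction. Breeds use the states with Dirichlet-divergent frequencies,
producing Fst-like allele-frequency divergence and, in crossbred cows,
fractional breed and heterosis covariates. Offspring receive block-level
recombinant gametes (Markov switching, ≈1.5 crossovers per chromosome).
The realized MAF spectrum follows the configured Beta only coarsely — the
state-run construction quantizes frequencies — and contains few variants
below MAF ≈ 0.1; rare-variant behaviour is therefore not what this
generator stresses.

**Phenotypes.** Latent constituents (fat, protein, lactose, minor solids)
per cow are planted QTL effects × dosage + a polygenic term + a permanent-
environment term. The polygenic term is transmitted through the pedigree
(founders N(0, σ²_poly); offspring take the parent mean plus Mendelian
sampling) — so pedigree REML is the generator-matched estimator of
heritability — with a `polygenic_mode="genomic"` option that instead sums
small effects over all common markers. Records add parity, DIM-class,
herd-by-test-day, breed and heterosis effects on the constituent scale,
plus per-record constituent noise; the spectrum is the constituent vector
times Gaussian band signatures placed on the classical mid-infrared
absorptions (ester C=O and C–H stretches for fat, amide I/II/III for
protein, carbohydrate C–O for lactose), plus per-wavenumber noise inflated
5× inside the three water-noise regions. Composition traits are fixed
linear functions of the constituents. Causal variants are resolved to
sites with MAF in [0.15, 0.45] **and low breed differentiation** (dosage
R² on breed proportions < 0.1), so the planted variance share is not
silently absorbed by the structure corrections; effect sizes are derived
from the target share against the expected adjusted-trait variance
σ²_poly + σ²_pe + σ²_resid·E[1/n_records].

**Expression.** The cohort is 357 animals, 62 overlapping the phenotyped
cows and the rest drawn from the founder generation. Mediating genes sit
cis (10–50 kb) to their causal variant; expression = β_e·dosage +
pedigree polygenic (h² = 0.3) + noise, with β_e sized to 20% of expression
variance, and the trait receives its effect through the gene, so trait QTL
and eQTL share the causal variant. Decoy eQTL (no trait effect, optional
LD ceiling to a designated trait QTL) provide independent-architecture
controls, and background genes carry no eQTL at all.

**What passing tests do not show.** The generator has no genotyping error,
no missingness, no imputation uncertainty (allelic R² is 1 everywhere and
the imputation-quality filters are exercised only by dedicated fixtures),
block-uniform LD rather than fine-scale recombination, Gaussian residuals,
and only two pedigree generations. Recovery results on it bound what the
pipeline can do under its own assumptions; they say nothing about
robustness to real-data artefacts such as instrument drift (consumed here
as already standardized) or annotation error.

## Problem sizes and statistical margins

Tests and the acceptance script run the chain at reduced scale chosen for
single-CPU turnaround: the default 2,000-cow simulation for variance-
component and tagging recovery; 500-cow replicates (50×) for candidate-gene
naming and co-localization discrimination; 600-cow replicates with 12
planted loci on 100 wavenumbers (10–20×) for profile-cluster recovery; ten
null traits on a 500-cow, 15,000-variant simulation (>10⁵ tests) for
calibration. With 25 sire families, the between-family component of any
single variant's dosage makes its realized marginal non-centrality
fluctuate by roughly ±50% around the planted value, so QTL planted at 3%
of trait variance sit within reach of, but not far from, the Bonferroni
boundary at n = 2,000: tagging recall across seeds is typically 0.8–1.0,
and the dedicated two-QTL (5% + 2%) separation experiment recovers the
smaller QTL in most but not all replicates. The replicate counts and
binomial margins in the tests were sized to these measured operating
characteristics.

## Known limitations

* Variance components are not re-estimated per LOSO segment or after
  conditioning; both are documented approximations of the two-stage
  design, validated only through calibration.
* The Mahalanobis spectral filter projects onto the top k = 10 principal
  directions of the within-instrument covariance and cuts at the
  chi-square(k) 0.999 quantile; both are package defaults (the upstream
  convention is not fully specified) and are config-exposed. Re-applying
  the filter can trim a few boundary records because the covariance is
  re-estimated after removal.
* The MAF-consistency, call-rate, concordance and Mendelian-inconsistency
  filters are implemented to their printed rules but are no-ops on the
  fully observed synthetic data.
* X-chromosome handling, dominance tests, fine-mapping beyond the greedy
  conditional scheme, and formal Bayesian co-localization posteriors are
  out of scope.
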