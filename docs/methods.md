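# Methods

## Model

For sibling *j* in family *i* with paternal and maternal genotypes
g<sub>p(i)</sub>, g<sub>m(i)</sub> (counts of allele "1" with frequency
*f*), the complete-data model is

Y<sub>ij</sub> = δ g<sub>ij</sub> + η<sub>s</sub> g<sub>ij'</sub> +
(α<sub>p</sub> − η<sub>s</sub>/2) g<sub>p(i)</sub> +
(α<sub>m</sub> − η<sub>s</sub>/2) g<sub>m(i)</sub> + ε<sub>ij</sub>,

where δ is the direct effect, η<sub>s</sub> the sibling indirect effect,
and α<sub>p</sub>, α<sub>m</sub> the non-transmitted coefficients (NTCs),
which absorb parental indirect effects plus confounding from assortative
mating and stratification. Offspring genotypes are conditionally
independent of the environment given parental genotypes, so δ (and
η<sub>s</sub>) are identified without bias once parental genotypes are in
the regression. The population effect of standard GWAS is
β = δ + (α<sub>p</sub> + α<sub>m</sub>)/2. Residuals of siblings share a
family random effect: μ<sub>i</sub> ~ N(0, σ²<sub>F</sub>),
ε ~ N(0, σ²<sub>ε</sub>), giving sibling residual correlation
r = σ²<sub>F</sub>/(σ²<sub>F</sub>+σ²<sub>ε</sub>).

## Mendelian imputation

Missing parental genotypes are replaced by their exact conditional
expectations given the observed family genotypes; unobserved parental
alleles contribute *f*. Because these expectations are *nonlinear* in the
observed genotypes, they add estimation information; linear imputations
cannot. Of the 15 nonempty observation patterns of the canonical
two-offspring family, exactly 7 admit nonlinear imputation; the
classification is established in code by exact enumeration of the joint
genotype distribution under Hardy–Weinberg and Mendelian transmission
rather than a lookup table. For two-offspring patterns, the siblings' IBD
state is part of the conditioning set — without it the sibling-pair
conditional expectation happens to be linear at f = 1/2, which would
misclassify that case.

Sibling pairs (imputing the parental sum g<sub>par</sub> =
g<sub>p</sub>+g<sub>m</sub>, since parent of origin is unidentifiable from
siblings): IBD0 → g₁+g₂; IBD1 → g₁+g₂<sup>¬s</sup>+f where g₂<sup>¬s</sup>
is sibling 2's non-shared allele; IBD2 → g₁+2f. The non-shared allele is
determined by the genotypes except when both siblings are heterozygous; a
phased neighbor SNP within the same IBD1 segment at which one sibling is
homozygous and the other heterozygous identifies the shared haplotype and
resolves it (search outward, nearest informative SNP first; equidistant
disagreeing neighbors leave it unresolved). Without phase the two
possibilities are averaged: 1+2f. Resulting R² with the true parental sum:
3/4 phased (per-state contributions 1, 3/4, 1/2), between 2/3 and 3/4
unphased, 2/3 for the best linear predictor (2/3)(g₁+g₂).

Parent–offspring pairs: the allele transmitted by the missing parent is
determined unless parent and offspring are both heterozygous (phased data
resolve which offspring haplotype carries the observed parent's
transmissions, by majority vote over informative SNPs — valid genome-wide
because an offspring's maternal/paternal haplotype is a single phased
entity); the imputation is (transmitted allele)+f, or 2f unresolved.
R² = 1/2 phased versus 1/3 for the best linear predictor
(2/3 g<sub>o</sub> − 1/3 g<sub>obs parent</sub>).

Sibships of n ≥ 2 (with or without one genotyped parent) are handled by
exact posterior enumeration over the four parental alleles (HWE priors for
ungenotyped parents, genotype-consistent orderings otherwise) and each
sibling's transmission choice, conditioned on the pairwise IBD
configuration; mutually inconsistent pairwise states fall back to the
configurations satisfying the largest number of pairwise constraints. On
average 4(1−2<sup>−n</sup>) parental alleles are observed, so imputation
approaches full recovery as n grows. Mendelian-inconsistent SNPs are
imputed as missing (parent–offspring) or under the IBD0 fallback (sibling
pairs) and counted in a QC report rather than silently corrected.

All imputations satisfy cov(ĝ, g) = var(ĝ), so the regression of true on
imputed values has slope exactly 1 — the unbiasedness certificate used in
the diagnostics.

## IBD inference

A three-state HMM over each chromosome. Emissions P(g₁,g₂ | IBD, f) are
derived by enumeration over parental transmissions; genotyping error is
modelled as replacement of an individual's genotype, independently with
probability γ, by a fresh HWE draw (chosen for closed-form emissions with
full support; the default γ = 10⁻⁴ and minimum smoothed segment length
m = 0.01 cM follow the tuned values reported for this class of model).
Transitions treat the IBD state as the sum of a paternal and a maternal
sharing indicator, each flipping between adjacent SNPs with probability
2θ(1−θ), θ the Haldane recombination fraction of the map distance (two
independent meioses per parent); the stationary law is (¼, ½, ¼). Per-SNP
log-likelihoods are multiplied by inverse LD scores normalized to mean 1 —
a pseudo-likelihood correction for local LD that leaves the
emission/transition balance unchanged, so constant LD scores reproduce the
unweighted HMM exactly. The Viterbi path (tie-break toward the
higher-stationary-probability state) is authoritative downstream;
forward–backward posteriors are reported for QC. Runs shorter than m cM
whose two flanks agree are merged iteratively; chromosome-end runs are
kept. Segment lengths use midpoint boundaries in cM.

Per-SNP accuracy is driven by boundary localization, so it improves with
marker density: at one SNP per 0.02 cM with γ-level simulated errors the
decoder exceeds 99% state accuracy against recorded-crossover truth
(the test suite verifies this, plus the (¼, ½, ¼) genome-wide fractions).

## Effect estimation

Variance components are estimated once by maximum likelihood under the
null model: the total variance is profiled out analytically, leaving a
bounded 1-D optimization over r ∈ [0, 0.99] (Brent, tolerance 1e-8); the
block structure gives O(n) likelihood evaluations. SNP effects are then
GLS with the components held fixed; the Woodbury identity per family block
keeps each SNP O(n), and the reported covariance is (XᵀV⁻¹X)⁻¹. Genotype
columns are mean-centered with the estimation-sample mean. All family
types enter one regression: trios contribute (g₁, g_p, g_m), sibling pairs
(g₁[, g₂], ĝ<sub>par</sub>), single-parent families the imputed missing
parent; when only sibling families are present the design reduces to the
combined-NTC column to avoid collinearity, and parental-sum families
contribute ĝ<sub>par</sub>/2 to both parental columns in mixed designs.
Proband-only individuals are excluded from the combined regression — their
single column estimates δ+(α<sub>p</sub>+α<sub>m</sub>+η<sub>s</sub>)/2 and
would contaminate δ. For the PGI regression the variance components are
estimated jointly with the fixed effects (a PGI can explain substantial
variance, so fixing null-model components would be wrong).

Benchmarks and robustness: the sibling-difference regression estimates
δ−η<sub>s</sub>; omitting a true η<sub>s</sub> from the imputed model
biases δ̂ by −((1+2r)/(2+r))η<sub>s</sub>, always smaller in magnitude.
Under stratification, imputation with a pooled allele frequency biases the
pooled δ̂ by ≈ F<sub>st</sub>α/2; the robust estimator fits each
observed-parental-allele group separately and combines δ̂ by inverse
variance. The IBD2 group is excluded there: its imputed parental sum
g₁+2f is exactly collinear with the proband genotype, so it carries no
direct-effect information (the 7/6 efficiency factor arises from the
IBD0 and IBD1 groups). Groups under 30 families merge into the nearest
group.

Efficiency closed forms (relative to sibling differences unless noted):
direct effect 1+(1−r)/(3(1+r)) (max 4/3), average NTC 1+(1−r/2)/(2(1+r))
(max 1.5, infimum 1.125), robust split 1+(1−r)/(6(1+r)) (max 7/6);
parent–offspring versus trios: 1/2 phased (frequency-independent), and
unphased a numerically evaluated curve (exact enumeration of expected
information matrices — there is no closed form) running from 1/6 at
MAF 0.5 to 1/2 as MAF → 0. The NTC reference estimator is the
no-imputation regression on (own, sibling) genotype, whose
sibling-genotype coefficient converges to (2/3)α; α is recovered as 1.5×
that coefficient.

## Correlations between effect classes

The moment estimator subtracts the known per-SNP sampling moments from
the empirical second moments of the estimates before forming the
correlation, removing attenuation (sampling variance) and same-sample
inflation (sampling covariance). SEs are delete-one block jackknife over
(default) 100 contiguous chromosome-respecting blocks. SNPs are
unweighted by default. Corrected variances ≤ 0 raise an error rather than
returning a meaningless ratio. For estimate pairs from disjoint samples
the sampling covariance is fixed at zero.

## PGI analyses

PGIs are weighted effect-allele dosage sums; imputed parental dosages are
scored with the same weights (ceiling 4 for parental sums).
Strand-ambiguous (A/T, C/G) weight SNPs are dropped by default. Because
each SNP is imputed marginally, assortative mating — which correlates
trait-associated SNPs across the genome — inflates the NTC of a PGI
imputed from phased sibling pairs by (1+r<sub>am</sub>)/(1+r<sub>am</sub>/2),
r<sub>am</sub> the equilibrium spousal PGI correlation (estimated from
fully genotyped parent pairs, or user-supplied); the adjustment divides α̂
and its SE by this factor and leaves δ̂ untouched. Factors for other
imputation classes are not derived here; those classes are returned
unadjusted with a warning.

## Simulator

Founders carry SNPs in linkage equilibrium (frequencies Uniform(0.05,
0.5), Balding–Nichols per deme when F<sub>st</sub> > 0) on a uniform map
(1 cM ≡ 1 Mb); LD arises only through mating structure and drift, matching
the estimators' assumptions. Each generation: couples form by random or
noisy phenotype-rank matching (noise calibrated by bisection to the target
spousal correlation ±0.02, within demes), and each couple produces two
offspring via Poisson-crossover meiosis (Haldane, no interference) with
recorded crossovers — true IBD paths follow from the transmission
indicators, not from genotypes. Phenotypes sum direct, parental-IGE,
sibling-IGE, vertical-transmission (v·(Y_p+Y_m)), deme-offset and Gaussian
noise components, scaled to configured variance shares in the founder
generation; under AM and vertical transmission the variance then evolves
toward equilibrium over the simulated generations. Ascertainment retains
families with logistic probability in the proband's phenotype percentile
and is used for qualitative (sign) checks only. Allele frequencies fed to
imputation are recomputed from the final parental generation.

What the simulator does not emulate: realistic LD (no coalescent
ancestry), genotyping/phasing error in emitted haplotypes (phase is
perfect, so phased-imputation results are upper bounds for real data with
switch errors), X chromosomes, overlapping generations, and selection.
Passing tests therefore certify the estimators under their stated
assumptions, not robustness to phasing artifacts. One further artifact of
convenience: with a single ~100 cM chromosome, a few sibling pairs per
thousand are genome-wide IBD2 and are flagged by the MZ-duplicate rule
(genotype discordance < 0.1% over ≥ 1,000 SNPs); with a full 22-chromosome
genome this cannot happen.

## Problem sizes and numerical choices

Replicate experiments use 2,000 replicates of 20,000 single-SNP families
for the efficiency ratios (Monte-Carlo SE of a variance ratio ≈
ratio·√(4/R)), 20–40 replicates for mean-bias checks, and 200 replicates
for SE calibration. Genome-scale r(δ, β) checks use 3,000–5,000 sibling
pair families × 600–1,500 SNPs; at a few hundred SNPs the *realized*
effect-vector correlation of the drawn SNP set fluctuates by more than
the jackknife SE, so the boundary case (r = 1) uses the larger panel.
Monomorphic SNPs are skipped; rank-deficient designs raise errors naming
the offending column mix; Viterbi ties break toward IBD1 then the lower
state index; the family-variance optimizer is compared against the r = 0
endpoint before accepting an interior optimum.

## Known limitations

- Imputation from relatives beyond the nuclear family (grandparents,
  avuncular) is out of scope, as are reference-panel imputation and joint
  peeling over large pedigrees.
- The sibling IBD HMM assumes a correct pedigree; relationship inference
  is an upstream tool's job.
- The AM NTC adjustment covers the phased sibling-pair class only.
- The moment correlation estimator reports |r̂| > 1 as-is with a warning
  when inputs are too noisy; interpretation is the user's responsibility.
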