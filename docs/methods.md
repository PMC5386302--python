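# Methods

## Scope and assumptions

famqtl implements a two-stage family design for quantitative traits:
(1) variance-component linkage localizes a region; (2) single-variant
mixed-model association, a segregation-aware candidate filter, risk-score
conditional linkage, and gene-based rare-variant tests dissect it.
Throughout, families are assumed independent, pedigrees autosomal,
non-inbred and loop-free, markers biallelic, and traits conditionally
Gaussian given fixed effects. Traits are prepared by imputing treated
blood pressures (+15 mmHg systolic, +10 diastolic — the standard additive
correction for antihypertensive treatment), deriving pulse pressure as
the difference of the adjusted values, and residualizing on sex, age,
age², BMI and genotype PCs by ordinary least squares. Residualization
deliberately ignores relatedness: the downstream models carry the
kinship matrix, and using plain OLS keeps the trait entering linkage and
association identical. When BMI itself is analyzed it is removed from
its own covariate set. Both entry points — residualized trait, or raw
trait with covariates passed to the model — are exposed, since two-stage
and one-stage adjustment differ only in degrees-of-freedom bookkeeping
at these sample sizes.

## Multipoint IBD

The hidden state of the Lander–Green chain is the inheritance vector:
two bits per nonfounder (paternal/maternal meiosis), each recording
which of the transmitting parent's two genes was passed. Between
adjacent evaluation positions each bit flips independently with the
Haldane recombination fraction θ = ½(1 − e^(−2d)) (no interference).
The emission at a marker sums over assignments of alleles to founder
genes: P(G | v) = Σ_a Π_slots f(a_s) · Π_typed 1[genotype consistent],
with founder allele frequencies estimated from founders and smoothed
with a pseudocount of 0.5 per allele so unseen alleles keep positive
mass. Missing genotypes (any missing allele) are marginalized. A scaled
forward–backward pass gives the posterior over vectors at every grid
position (default 1 cM, markers always included), from which pairwise
expected IBD π̂ and the 0/1/2 sharing distribution follow by counting
shared founder genes. With no genotype data the posterior is the
uniform prior and π̂ reduces to the pedigree expectation (2φ for
non-inbred pairs), which is tested.

Exactness is bounded by the state space 2^(2·nonfounders). The
configuration cap is expressed in the conventional bit complexity
2·nonfounders − founders (default 16); an additional internal guard
keeps the enumerated space at ≤ 2²⁰ states. Beyond the cap, `mode="mc"`
(or `auto`) switches to likelihood-weighted conditional gene dropping:
whole inheritance-vector paths are sampled from the recombination prior
and importance-weighted by the product of marker emissions. The
estimator is unbiased; its weakness is weight degeneracy on long dense
maps, so the effective sample size is computed and a warning is issued
below ESS 200. Default 10,000 draws. On a 7-member three-generation
family the MC posterior agrees with the exact HMM to ~0.005 in π̂ at
30k draws (tested).

The exact path is verified against an independent brute-force oracle
(dense Hamming-distance transition matrices, itertools emission
enumeration) to 10⁻¹⁰ on pedigrees up to 10 bits.

## Variance-component linkage

At each position the family covariance is Π σ²_QTL + 2Φ σ²_G + I σ²_E
(Π has unit diagonal). Fixed effects are profiled by GLS; variances are
maximized by bounded L-BFGS-B on the standardized-trait scale with the
analytic profile gradient (the envelope theorem makes the β-profiled
gradient exact). Multi-start (default 3: warm start from the previous
position or a caller-provided fit, the null embedding σ²_QTL = 0, and a
fresh start at 30% QTL variance); convergence at relative tolerance
1e−12. σ²_QTL and σ²_G may sit on the zero boundary; σ²_E is bounded
below at 10⁻⁶ (standardized) for positive definiteness. LOD =
(ln L₁ − ln L₀)/ln 10; when the alternative maximizes at the null the
embedding makes the clip at zero exact, and per-family LODs (each
family's log₁₀-LR contribution at the overall MLEs, not per-family
MLEs) then sum to the total identically. The one-sided null is the
½χ²₀ + ½χ²₁ mixture; type-I error at LOD ≥ 0.588 (LRT 2.71) is verified
by simulation in the acceptance suite.

The 2-LOD support interval extends from the (leftmost) peak until the
curve crosses MLOD − 2 (linear interpolation between grid points) or the
scan ends; intervals narrower than 20 cM are widened symmetrically about
the peak, compensating at scan boundaries.

Conditional scans absorb the covariate (risk score or single SNP) into
the fixed effects of both null and alternative. An identically zero
covariate is ignored with a warning (it carries no information), and a
covariate collinear with the existing design is an error.

## Mixed-model association

The polygenic model V = σ²_G·2Φ + σ²_E·I is fitted by full ML in the
eigenbasis of 2Φ, profiling the ratio γ = σ²_G/σ²_E by a bounded
one-dimensional search (log-scale, xatol 1e−10, with the γ = 0 boundary
checked explicitly) with closed-form GLS and scale at each step. The
genotype effect is tested by LRT against χ²₁ (ML, not REML, so nested
likelihoods are comparable). Dosage is additive 0/1/2 in the minor
allele; individuals missing the genotype are dropped and the null is
refitted on the same subset so the LRT compares identical data.
Monomorphic variants are an error. Wald z² and the LRT agree to <5%
median relative difference at n = 2000 (tested).

## Rare-variant set tests

All tests share the genotype-free null fit and its projection
P = V̂⁻¹ − V̂⁻¹X(XᵀV̂⁻¹X)⁻¹XᵀV̂⁻¹. Weights are the Beta(1,25) density of
the within-study MAF (founders and nonfounders included). Two burden
p-values are reported: the headline `p_burden` from the mixed-model LRT
on the collapsed score (identical to the single-variant machinery, to
which it collapses exactly for one variant), and the score-form
`p_burden_score` from Q_burden = (Σ_j w_j S_j)², which is the statistic
SKAT-O interpolates to at ρ = 1. The two are asymptotically equal but
not bit-identical; keeping both preserves the exact algebraic
boundary identities of SKAT-O (ρ = 0 ⇒ SKAT, ρ = 1 ⇒ burden score, both
to 10⁻¹⁰) while still offering a likelihood-ratio burden test.

Mixture-of-χ² survival probabilities use Liu–Tang–Zhang moment matching
(Lee modification) left of the mean and the Kuonen saddlepoint
(Lugannani–Rice) right of it, where it is uniformly more accurate;
a single-component mixture is evaluated exactly. Quantiles invert the
moment-matched form. SKAT-O's omnibus p integrates the min-p statistic
over the shared 1-df component on 256 Gauss–Legendre nodes under the
substitution x = u² (removing the χ²₁ density singularity); agreement
with adaptive quadrature is ~10⁻³, within the approximation error of
the min-p method itself, and the result is capped at the Bonferroni
bound over the ρ grid. The default grid is
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}. Analytic SKAT p-values match
a 5,000-permutation oracle within Monte-Carlo error (acceptance suite).

Meta-analysis defaults to Fisher's method (−2Σln p ~ χ²_2k; exact
identity for one study) with sample-size-weighted Stouffer optional;
zero p-values are clipped to the smallest positive float with a warning.

## Candidate filter, risk score, LOD-drop null

A region variant is selected iff (p ≤ 0.1 OR |β| ≥ 5 mmHg) AND some
family has ≥ 2 carriers and family-specific LOD ≥ 0.1 at the peak
position. The filter is monotone in all four thresholds (property
tested). The risk score is the exact inner product of dosages with the
marginal (not joint) single-variant betas; missing dosages contribute
zero and are counted. The empirical null conditions the scan on each of
N randomly sampled LD-pruned SNPs from other chromosomes (default MAF
≥ 0.05, single SNP per scan, matching the asymmetry of the original
design in which a multi-variant risk score is compared against
single-SNP nulls); the empirical p uses the add-one rule
(1 + #{null ≥ observed})/(1 + N), which never reports zero.

Two analytic utilities summarize replication consistency: the binomial
sign test for direction consistency — the strict-greater tail
P(X > k | Bin(n, ½)), which at 16 protective of 23 tests equals 0.0173
(the inclusive tail P(X ≥ 16) ≈ 0.047 is also exposed, since both
conventions appear in practice) — and the opposite-direction
probability Φ(−β*/SE) for a standardized true effect, which for a
quarter-SD effect against a unit-SD error is 40.1%.

## The synthetic-data generator

The generator emulates a family blood-pressure cohort: ~130 families
averaging ~4 members (≈517 individuals), including one 17-member
three-generation family; a rare variant (nominal MAF 0.004) confined to
that family with a protective effect on SBP; additional rare protective
coding variants under the same peak; polygenic covariance 2Φσ²_G;
sex/age/age²/BMI covariate effects; and logistic-in-latent-SBP
antihypertensive treatment (~25% treated) that masks observed pressures
by −15/−10 mmHg, exactly inverted by the medication adjustment.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| mean SBP / DBP (mmHg) | 125.3 / 74.5 | medication-adjusted cohort means |
| σ²_G, σ²_E (SBP) | 100, 110 | residual SD ≈ 14.5, h² ≈ 0.48, inside the reported 30–60% heritability range; with covariate variance the total SD ≈ 16 |
| BMI → SBP | 0.6 mmHg per kg/m² | standard epidemiologic association (0.5–1.0) |
| carrier-family variant | β_SBP\|BMI = −24.8, β_BMI = +28 | carriers are obese (BMI ≈ 60 vs ≈ 32) yet show ~8 mmHg *lower* raw SBP (≈117 vs ≈125); because the analysis adjusts BMI, the BMI-conditional effect is necessarily much larger than the raw −8 difference |
| medication model | logistic((SBP−137)/8) | ~25% treated, treatment probability increasing in latent BP |

Founder haplotypes are drawn independently per marker from the nominal
frequencies (no background LD) and transmitted with Haldane
recombination, so outputs are Mendelian-consistent by construction
(tested) and the LD-pruning stage sees realistic *family*-induced
correlation but not population LD. The single-family variant is planted
as one founder copy and the family's drop is rejection-sampled until at
least the target carrier count (cap 1000 attempts, best draw kept with
a warning). One master seed fans out to independent pedigree/genotype/
trait streams, and all writers are byte-deterministic.

What passing tests on these data do *not* show: robustness to
population LD and haplotype structure, to ascertainment through probands
(the cohort was sleep-apnea-ascertained; only family sizes are matched),
to non-Gaussian trait tails, or to genotyping error; the family-size
distribution itself is a plausible invention, published totals aside.

## Scaled end-to-end scenario and problem sizes

The packaged end-to-end scenario (`scaled_config`) uses 40 families
(~205 individuals, sizes 4–6) with a 10-member three-generation carrier
family — bit complexity 8, exactly solvable — and four region variants
at MAF 0.08 with β between −12 and −13 mmHg. The effect sizes are
scaled up as the sample is scaled down to preserve the linkage
non-centrality of the full design (region QTL variance ≈ 20% of the
residual trait variance), the standard trade in desk-scale study
emulation; six background chromosomes (45 pruned-spacing markers each)
supply the off-region SNP pool for the LOD-drop null, run at 200 draws.
Acceptance simulations use: 500 replicates of 50 nuclear families for
linkage type-I error; 1,000 replicates of 50 families for
association/set-test calibration with a 5,000-permutation SKAT oracle on
200 unrelateds; and 25 seeded replicates of the scaled scenario for
planted-variant recovery.

A single family's LOD contribution at the peak is an intrinsically
noisy quantity (across scenario replicates the carrier family's LOD has
mean ≈ 0.3 and SD ≈ 0.5), so the segregation clause of the candidate
filter fails in a substantial minority of replicates even with a large
planted effect — a single observed family LOD of ~0.7 is one favorable
draw from such a distribution, not a typical value. The recovery test
reports this honestly rather than simulating an easier world.

## Known limitations

- No founder-phase symmetry reduction in the exact HMM: capacity is
  spent on a 2^(2·NF) enumeration, which is why the 17-member family
  falls to MC mode. Folding the (Z₂)^F symmetry would roughly double
  the feasible family size.
- The MC IBD mode is importance sampling from the prior; for long dense
  maps a sequential (particle) scheme would scale better.
- Marker–marker LD is handled only by pruning; joint modelling of LD
  clusters in the HMM emission is out of scope.
- Liu/saddlepoint mixture tails are approximations; p-values below
  ~10⁻¹² should be read as orders of magnitude.
- Binary traits, X-linked models, inbreeding loops and
  Haseman–Elston-style regression linkage are not implemented.
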