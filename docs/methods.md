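# Methods

## Genotype model and pseudo-haploid calling

Genotypes are ALT-allele counts on biallelic SNVs in the EIGENSTRAT
convention: 1-based physical positions, genetic positions in Morgans,
missing stored as 9 on disk and a sentinel in memory. A low-coverage
ancient individual is represented pseudo-haploidly: at each site one read
is drawn uniformly among reads matching the ref or alt allele and its
allele doubled, so calls are {0, 2, missing} and each individual
contributes one observed allele to population frequencies (counting two
would understate the variance of a single random draw; diploid individuals
contribute two). Transversion-only replication removes C/T and G/A allele
pairs — both strand readings of a transition — because post-mortem
cytosine deamination creates C→T (and complementary G→A) artifacts
concentrated at read termini. Coverage downsampling is binomial thinning
of pileup base counts with retention probability target/current, which
maps Poisson(λ) coverage to Poisson(λ·p) exactly. Panel merging keys sites
on (chromosome, position), recodes swapped or strand-complemented allele
pairs (genotypes 0↔2), and drops strand-ambiguous A/T and C/G sites
outright, a conservative default.

## Block jackknife

All f-statistic and weight standard errors use a weighted delete-one-block
jackknife over contiguous blocks of ≤ 0.05 M genetic span within
chromosomes (configurable; the conventional default of the f-statistic
ecosystem). Blocks are weighted by their usable-site counts through the
Busing pseudovalue formula, which reduces to the classical delete-one
jackknife for equal blocks. Sites missing in any population entering a
given statistic are dropped for that statistic only. The per-population
deviation test in the pairwise-f3 regression recomputes both f3 vectors
and the OLS line with each block deleted and uses an unweighted jackknife
over the resulting residuals (blocks from the uniform map are near-equal);
|Z| ≥ 3 is flagged.

## Admixture modelling

The admixture fit is generalised least squares on f4 profiles. With base
right R1, profile(L)ⱼ = mean over complete-case sites of
(p_L − p_R1)(p_Rⱼ₊₁ − p_R1). The error e(a) = profile(target) −
Σ aᵢ·profile(sourceᵢ) is linear in the jointly jackknifed profiles, so its
covariance C(a) is a quadratic contraction of the joint block-jackknife
covariance; the sum-to-one constraint is imposed by eliminating the last
weight (weights may leave [0, 1]; feasibility is reported, never
enforced). C is re-evaluated at the current weights and the GLS solve
iterated to a fixed point. T = e′C⁻¹e is referred to χ² with
df = |rights| − |sources|. Weight SEs come from per-deleted-block refits
with C held at its converged value — a standard shortcut that avoids an
O(blocks²) inner jackknife; CI coverage of the weights is verified against
simulation truth in the acceptance suite. A singular C (e.g. a target
identical to a source) receives the smallest escalating ridge
ε·trace(C)/dim that makes it positive definite, with a warning.

The nested-model test evaluates both models under the full model's
converged covariance: the reduced model's weights are re-solved in that
common metric, making ΔT = T_reduced − T_full an exact nested-projection
difference (non-negative by construction), referred to χ² with one degree
of freedom per dropped source. In our H0 calibration experiments the test
is mildly anti-conservative — a finite-sample effect of plugging in an
estimated covariance — which the type-I experiment quantifies at run time;
users comparing borderline nested P-values around 0.05 should bear this
in mind.

The downsampling experiment repeats per replicate: thin the target's
pileups to the requested coverage, re-call pseudo-haploid genotypes, refit
the two-way and three-way models and their nested comparison, and count
replicates with fit P ≥ 0.05 per model and nested P < 0.05. Per-replicate
seeds are derived from the experiment seed and recorded; failures are
recorded without aborting.

## Admixture-LD dating

Site weights are the source frequency contrast w_s = p_A − p_B and
residuals r_s = w_s(g_s/2 − p̄_s) with p̄ the source midpoint. Products
r_s·r_s′ for intra-chromosome pairs at genetic distance d ∈ (0, 0.2 M] are
averaged in 0.001 M bins; under a pulse admixture t generations ago the
curve decays as A₀·exp(−t·d) + c. The affine term c is always estimated
(it absorbs background LD and finite-panel bias); the fit is pair-count
weighted nonlinear least squares over 0.45–20 cM (the lower cutoff
excludes the short-range background-LD regime), with λ bounded at 0 and a
flag when the bound binds. The SE of t is a weighted delete-one-chromosome
jackknife — chromosomes are the natural exchangeable unit since all pairs
are intra-chromosomal. Calendar conversion is
years BP = sample_age_BP + t·generation_time (default 30 yr), with the SE
scaled likewise; the sample age is always an explicit parameter. For an
unadmixed genome the curve is flat and λ is weakly identified (A₀ ≈ 0);
the amplitude, not the rate, is then the informative quantity.

## PCA projection

Reference-panel PCA drops sites with > 5% missingness in the panel,
mean-imputes the rest, centres by 2p̂ and scales by √(p̂(1−p̂)), and takes
the SVD of the normalised individuals × sites matrix. Coordinates are PC
scores (U·S), so projecting a complete reference individual reproduces its
own coordinates; each axis is oriented with its largest-magnitude loading
positive for reproducible signs. A possibly pseudo-haploid, heavily
missing sample is placed by least-squares regression of its normalised
genotypes at non-missing sites on the eigenvector rows at those sites.
Plain p̂(1−p̂) scaling is used for pseudo-haploid reference individuals as
well (they are flagged); no outlier-removal iterations or Tracy–Widom
statistics.

## Sample authentication

R_Y = nY/(nX+nY) with a normal-approximation 95% CI; the CI entirely below
0.016 calls female, entirely above 0.075 calls male, otherwise ambiguous
(community-standard cutoffs, configurable). Damage profiles are
position-wise C→T rates from the 5′ end and G→A rates from the 3′ end of
reference-aligned reads.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the inference assumes,
not sequence-level realism. Population frequencies follow Balding–Nichols
drift on an admixture graph (child p ~ Beta(p(1−F)/F, (1−p)(1−F)/F) per
branch; ancestral p ~ U(0.05, 0.95); admixed populations mix sources
linearly). The canonical three-source scenario has an outgroup (F = 0.3),
three source lineages of 0.10 private drift whose ancestors split with
F = 0.05 internal branches, and six right populations differentially
related to the sources — drift magnitudes chosen once to mirror the strong
differentiation of real Northeast-Asian reference lineages, since only
drift shared with a right population is visible to f4 profiles. Local
ancestry follows a two-state Markov process with switch rates
q_{A→B} = (1−α)t and q_{B→A} = αt per Morgan: stationary ancestry fraction
α and ancestry autocovariance exp(−t·d), so the dating module's estimand
equals the simulated t; visible switches occur at rate 2α(1−α)t per
Morgan. Three-way targets stack two two-way tract processes (third source
versus the pooled pair). Reads have Poisson coverage, one true allele per
read, and terminal deamination δ·exp(−(pos−1)/5) at a uniform read
position; the genetic map is uniform at 1 cM/Mb. Everything is
regenerable bit-identically from integer seeds.

Not emulated: realistic human demography and map heterogeneity, reference
bias, contamination, sequencing error beyond deamination, linked selection.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to those real-data pathologies (the
transversion replication probes the deamination pathology only).

## Problem sizes and defaults in the validation experiments

Replicated experiments use 50,000 sites on 22 × 1 M chromosomes (~440
jackknife blocks), targets at 1× Poisson coverage, admixture 25
generations before sampling, and proportions 0.3/0.7 (recovery),
0.35/0.35/0.30 (power), 0.5/0.5 (calibration, 20,000 sites per replicate
across 200 replicates) and 0.20/0.14/0.66 (downsampling, 4× thinned to
1×) — sizes at which each experiment completes in seconds to a couple of
minutes while leaving the statistical checks well-powered.

## Known limitations

* Exact numerical equality with the reference C implementations of the
  f-statistic/qpAdm ecosystem is not promised; the estimands and the
  jackknife machinery match their published descriptions, but internals
  (site filtering, normalisation modes) differ in unstated details.
* The nested test's mild finite-sample anti-conservatism (above).
* Outgroup f3 is unnormalised (no outgroup-heterozygosity correction or
  inbreeding adjustment).
* Single-pulse dating only; multiple pulses or continuous migration bias
  λ toward an effective average. λ and A₀ are jointly weakly identified
  when decay is slow relative to the fit window (t ≲ 5).
* The packed-EIGENSTRAT dialect mirrors this package's ASCII digit
  semantics and writes null header hashes; files from other tools with
  ref-allele-count semantics should be imported via the ASCII dialect.
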