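# Methods

This note documents the statistical models implemented in `heteropool`, the
assumptions of the synthetic-data generator the pipeline is validated on,
and the numerical choices that matter.

## The problem

Hybrid breeding in a self-pollinating crop starts from a panel of inbred
parents crossed onto a tester pool to produce F1 test hybrids, which are
yield-tested across many sites in a sparse multi-environment trial (MET):
each site grows only a subset of hybrids, a fraction of entries is
duplicated within a site (p-rep design), and a common set of inbred check
cultivars appears everywhere. The analysis asks: (i) how is the parental
panel structured genetically, (ii) how much of hybrid yield variation is
additive (parent-transmitted) per site, (iii) which sites behave alike
(environment clusters), (iv) which parents contribute stable positive
additive effects, and (v) which crosses between genetic subgroups would
yield the best selected progeny — the raw material for heterotic pools.

## Synthetic data generator

Because real trial networks of this kind are proprietary, the package ships
a generator whose parameters are the ground truth for recovery tests.

* **Founders.** Balding–Nichols divergence: ancestral allele frequency
  `p ~ U(0.05, 0.95)` per marker; each of `K` subgroups draws its own
  frequency from `Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst)`. Every line is
  fully inbred: one allele draw per marker, dosage 0 or 2.
* **Genetic map.** Markers placed uniformly at random on `n_chrom`
  chromosomes of fixed cM length, sorted within chromosome.
* **Cross plan.** A quarter of the panel acts as female (seed) parents,
  mirroring a male-sterility testcross system; random distinct male×female
  pairs form the hybrids; each site receives a random hybrid subset; checks
  appear at every site. Replication fraction within a site defaults to 0.3.
  Design concurrence optimization is deliberately not emulated — it affects
  efficiency, not estimability, at this scale.
* **Phenotypes.** Per plot: site mean + random row, column and block
  effects + hybrid genetic value + AR1⊗AR1-correlated spatial noise + iid
  residual. The hybrid genetic value is male GCA + female GCA + an iid SCA
  deviation. Parental GCA vectors are drawn jointly across sites with a
  specified between-site correlation matrix — either directly Gaussian, or
  (default in the desk preset) as centered marker dosages times per-site
  marker-effect vectors whose between-site correlation equals the target;
  the marker route gives the genomic-prediction stages a true sparse signal.
  Per site, realized GCA variance in the panel is scaled exactly to
  `σ²_a/2`, so the additive variance among hybrids of independent parents
  is `σ²_a`.
* **Desk preset.** 8 sites in two environment clusters (additive
  correlation 0.8 within, −0.2 between), 200 hybrids from 40 parents in 4
  subgroups (Fst 0.15), 350 mapped SNPs on 7 chromosomes, `σ²_a = 0.5`,
  `σ²_s = 0.1`, `σ²_e = 1.0`, spatial σ² = 0.2 with ρ = 0.4 in both
  directions, row/col/block σ² = 0.05 each, site mean 6 t/ha. These sizes
  keep every REML fit sub-second while leaving all stages identifiable.
  The sparse variant (80 of 200 hybrids per site) emulates the sparse MET;
  the dense variant (`hybrids_per_site=200`) is used where between-site
  structure is the estimand, since site overlap is what carries it.
* All randomness flows from one integer seed through named SHA-256-keyed
  `numpy` generator streams; everything is bit-for-bit reproducible.

What the generator does **not** emulate: genotyping ascertainment bias,
multi-allelic markers, linkage disequilibrium within subgroups beyond what
Balding–Nichols induces, weather covariates, and non-random site allocation
of hybrids. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to every field reality.

## Population structure

Rogers' distance is computed per locus as the Euclidean distance between
the two individuals' allele-frequency vectors, which for dosages reduces to
`|d_i − d_j|/2`, averaged over loci observed in both individuals
(locus-mean variant). PCoA is classical scaling: eigendecomposition of the
double-centered `−½D²`; negative eigenvalues are reported but contribute no
axes.

The admixture model is the standard binomial likelihood
`ℓ(Q, P) = Σ_ij d_ij log(q_i·p_j) + (2−d_ij) log(1 − q_i·p_j)` with
ancestry proportions Q on the simplex and ancestral frequencies P in
[0, 1]. It is maximized by expectation–maximization on allele-origin
counts, accelerated with safeguarded SQUAREM extrapolation (an extrapolated
step is kept only if it does not lower the likelihood, so the recorded
likelihood path is monotone; plain EM creeps on this likelihood's flat
simplex-boundary ridges). Convergence: Δℓ < 1e-6, budget 2000 EM steps.
Missing genotype cells are excluded from the likelihood. The number of
populations is chosen by masked-entry cross-validation: observed cells are
split into folds, each fold is masked in turn, and the squared error of the
masked dosages against `2·QP` is minimized over K.

## Single-trial REML

Model per site: `y = Xβ + Σ Z_r u_r + e`, with fixed intercept and one
column per check cultivar; random rows, columns, blocks; and either one
hybrid-identity genetic term or the additive + SCA partition, where the
additive incidence maps each hybrid plot to its two parents (GCA) and an
optional relationship matrix (identity or genomic) covers the parents. The
residual is iid or separable AR1(row)⊗AR1(col), selected by AIC in
`compare_spatial`.

Estimation is average-information REML on the dense V matrix with three
safeguards: (i) components pinned at the 1e-8 floor whose gradient points
below zero are held fixed (active set) and the AI step is solved in the
free block with step halving; (ii) if the AI step still lowers the
restricted likelihood, the EM-REML update (an ascent step) is used instead;
(iii) if the loop exhausts 200 iterations — which happens when a tiny
component sits on the boundary, where AI overshoots and EM stalls
quadratically — a Nelder–Mead polish on log-variances finishes the
maximization. Convergence: |Δℓ| < 1e-6 and max relative component change
< 1e-5. AR1 correlations are profiled by an outer Nelder–Mead on
atanh-transformed values around the inner variance fit. Approximate
standard errors come from the inverse AI matrix.

BLUPs are `û = σ²GZᵀPy`; prediction error variances from
`σ²G − σ⁴GZᵀPZG`; reliability of effect i is `1 − PEV_i/(σ²G_ii)`, and the
mean reliability of parental additive effects is the package's site-level
heritability summary (per-effect reliabilities are also reported, since
aggregation conventions differ between programs).

## Factor-analytic MET model and environment clusters

The between-site additive covariance is modelled as `G = ΛΛᵀ + Ψ` with
site loadings Λ (order k, default 4 for a real network; 2 at desk scale,
where there are 8 sites) and site-specific variances Ψ. It is fitted to the
genotype × site table of stage-1 additive BLUPs by EM, treating both
factor scores and missing cells as latent, so sparse tables are handled
exactly; per-genotype weights can scale the sufficient statistics. The
observed-data log-likelihood is monotone by construction; tolerance 1e-8
relative, budget 20,000 iterations (each is milliseconds at desk scale).
Loadings are rotated to the lower-triangular identification with
non-negative leading diagonal.

This is a two-stage approximation to a one-stage FA mixed model: the
single largest engineering cost in the chain is avoided, at the price of
shrinkage attenuation — a site's BLUP is approximately `rel·g` plus
independent noise, so between-site correlations of BLUPs are attenuated by
`sqrt(rel_i·rel_j)`. `genetic_correlation` accepts per-site mean
reliabilities and applies the inverse correction (clipped to [−1, 1]);
with reasonably reliable stage-1 fits the uncorrected matrix already
supports clustering, and the correction is optional because it destabilizes
when a site's reliability itself is poorly estimated.

Percent additive variance explained by the first m factors is
`100·Σ_{f≤m} λ_if² / (Σ_f λ_if² + ψ_i)` per site; both the unweighted mean
and the variance-weighted aggregate over sites are reported, since either
summary convention is found in practice.

Sites are clustered by average-linkage agglomeration on `1 − r`. The
cluster count is either user-fixed (the usual practice — the analyst reads
the dendrogram) or chosen at the largest relative gap between successive
merge heights; a flat dendrogram degenerates to one cluster with a warning.

## GBLUP and marker effects

The genomic relationship matrix is the marker-based construction
`K = ZZᵀ/(2Σp(1−p))` with Z column-centered at (by default observed)
allele frequencies and missing dosages mean-imputed before centering. For a
fully inbred panel the expected diagonal is 2. Note that K built from
observed-frequency-centered markers is singular by construction (Z's
columns sum to zero), so GBLUP is solved in the V-form
`û = σ²_a K Zᵀ V⁻¹(y − Xβ̂)`, `V = Z(σ²_a K)Zᵀ + σ²_e I`, which never
inverts K; this is algebraically identical to ridge regression on markers
with `λ = σ²_e/σ²_m`, an identity the test suite verifies to 1e-8 against
an independently coded marker-level solver. Variances are REML-estimated
when not supplied. Marker effects are backsolved as
`α = ZᵀK⁻ĝ/(2Σp(1−p))` using an eigen-based pseudo-inverse with relative
rank tolerance 1e-10 (the default machine-epsilon cutoff would keep K's
null eigenvalue and amplify noise); `Zα` reproduces ĝ exactly on the range
of K. The effect profile flags the top fraction (default 10%) of markers by
|effect| with ties broken by marker order, and cross-site concordance is
summarized by sign agreement and Pearson correlation.

## Stability

Shukla's stability variance over a genotype × environment table of additive
effects: with interaction residuals
`w_ij = x_ij − x̄_i· − x̄_·j + x̄··`,

    σ²_i = G/((G−2)(E−1)) · Σ_j w_ij²  −  ΣΣ w² / ((G−1)(G−2)(E−1)).

The unbiased estimator can be negative; estimates are reported as-is with a
truncated-at-zero companion. Missing cells are additively mean-filled only
on request. Quadrants classify parents by (mean effect ≷ 0) × (√σ²_i ≷
panel median); "stable-positive" means above-threshold mean and
below-threshold interaction variance. Both thresholds are configurable —
the quadrant boundaries are an analyst's choice, not a statistical one.

## Doubled haploids and usefulness

DH progeny of a cross of two inbreds are simulated per chromosome as a
two-state Markov chain of parental phase along the ordered mapped markers,
with adjacent-marker recombination probability from Haldane's map function
`r = (1 − e^(−2d/100))/2` — the exact marker-level law of a
no-interference (Poisson) crossover process, chosen in this form because it
vectorizes over progeny. Crossover interference is out of scope. The
gamete is doubled to homozygosity, so loci where the parents share an
allele are fixed. Unmapped markers are excluded with a logged count.

Progeny are scored as `dosage·α + site mean`; the usefulness criterion is
`UC = μ + i(p)·h·σ` with μ, σ the progeny GEBV mean and SD (n−1
denominator), selection accuracy h = 1 when selecting directly on marker
scores, and `i(p) = φ(z_p)/p`, the mean of the selected upper-p normal
tail, without finite-population correction. `compare_cross_sets` simulates
every anchor×anchor and anchor×other-subgroup cross and groups UC values by
subgroup pair.

The usefulness contrast experiment constructs the mechanism that makes
inter-population crosses valuable: the anchor subgroup and one partner
subgroup are fixed for complementary favorable alleles at disjoint locus
sets of equal total effect, so intra-anchor progeny segregate at neither
set (same mean, zero variance from those loci) while inter-population
progeny segregate at both — higher σ, hence higher UC at any selected
fraction below 1.

## Validation experiment sizes

The acceptance experiments run at: 40 parents × 300 markers (algebraic
identities); 20 seeded sparse desk METs (variance recovery; the mean
estimate is compared to the generating 0.5 within two empirical standard
errors); 20 seeded dense desk METs (cluster recovery, both clusters exactly
in ≥95% of runs); 10 Balding–Nichols panels of 60 inbreds × 500 SNPs with
CV over K = 2..6 (K = 3 selected in ≥80%); 10,000 gametes (recombination
within ±0.01 of Haldane's 0.0906); and 20 seeded complementarity panels of
24 parents × 210 mapped markers with 100 DH per cross (inter beats intra in
≥90%). These sizes were chosen so the whole validation suite runs in a few
minutes on one CPU while keeping each check's Monte-Carlo error well inside
its tolerance.

## Known limitations

* Two-stage MET analysis (site BLUPs → FA) rather than a one-stage FA
  mixed model; a one-stage fit is the natural extension point.
* The admixture model ignores linkage (sites independent given ancestry),
  as the classic tools do.
* AR1 parameters are profiled by direct search, which is robust but slower
  than embedding them in the AI system.
* No dominance relationship matrix: non-additive variation is
  hybrid-identity-indexed SCA only.
* Desk-scale defaults trade power for speed; a real 24-site, 722-hybrid
  network would use the same code paths with larger inputs.
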