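# Methods

## Model

The simulator is an individual-based diploid Wright–Fisher model with
non-overlapping generations, constant census size N, and L unlinked (by
default) biallelic loci. Each locus i carries a "beneficial" allele with
trait effect aᵢ and a pleiotropic cost cᵢ attached to the same allele — the
scenario in which adaptive alleles have deleterious side effects on other
phenotypes.

Fitness combines Gaussian stabilizing selection on the trait with a
multiplicative load:

    z  = Σᵢ aᵢ · m(Gᵢ),   m(G) = {0, 2dᵢ, 2} for G = 0, 1, 2 copies
    w  = exp(−(z − θ)² / (2ω²)) · Πᵢ (1 − cᵢ ηᵢ),   ηᵢ = {0, h_c, 1}

dᵢ is the dominance of the trait effect (0.5 = additive, the default) and
h_c the dominance of the cost (0 = fully recessive, the default). Two model
assumptions matter for interpretation: the load is multiplicative across
loci (no epistasis in the cost), and the cost is independent of the trait
distance to the optimum — it represents *other* phenotypes under
(effectively) directional selection.

The experiment has two phases. Phase 1: replicate populations founded from
a single shared standing-variation pool (independent per-locus
Bernoulli(p₀) haplotypes, i.e. linkage equilibrium) adapt to an optimum
shifted by Δθ for 110 generations, and are continued a further 20
generations at the optimum to provide the unmixed control samples
(generations 110/120/130). Phase 2: ordered pairs of adapted replicates are
mixed — the immigrant contributes a binomially distributed fraction around
m = 0.15, mirroring the sampling stochasticity of a real setup — and the
mixture evolves 29 more generations under the same regime, with Pool-Seq
samples at F1, F20, F29.

Pool-Seq sampling is two-stage: the pool frequency of individuals sampled
without replacement, then binomial read counts at a fixed or
Poisson-distributed depth. Synthetic data are written as PoPoolation2 sync
files, so the inference chain consumes exactly what a real pipeline would
produce.

## Trait architecture of the default generator

Defaults (desk scale, `pipeline.replica_config`): N = 300 (N = 1250 for the
full-scale default of `SimConfig`), L = 60, coverage 40x (Poisson), m = 0.15,
3 mixture replicates, c = 0.05 per locus, h_c = 0.

The effect-size distribution is L-shaped, as typically estimated for
polygenic traits: one third of the loci are a large-effect redundant
reservoir (a = 1.0 trait units) and two thirds a weak-effect background
(a = 0.15). Large-effect variants are rare in the founder (p₀ = 0.005, a
handful of copies in a population of 300), while the background segregates
at common frequencies (p₀ = 0.08). With an optimum shift of 16 trait units
and ω = 8, the initial per-copy advantage of a large-effect allele is
roughly a·Δθ/ω² ≈ 0.2, and only about half the reservoir is needed to reach
the optimum. Because each large-effect variant starts from a handful of
copies, early drift decides which subset sweeps in which replicate — the
redundancy lottery. This reproduces the defining features of the emulated
experiment: selected loci rise from low to intermediate/high frequency
within 110 generations, largely different subsets respond in different
replicates, the populations sit near the optimum by generation 110 (near
stasis from 110 to 130), and mixtures of two adapted replicates show
immigrant-allele frequency gains of a few percent over 20 generations.

A replicate pair can be configured to share the first generations of
adaptation before branching (`Design.shared_history`; 80 of 110 by
default for one pair). This produces a lowly differentiated pair alongside
fully independent (highly differentiated) pairs, the contrast the
experimental design uses to show that the immigrant advantage grows with
differentiation.

## Inference chain

1. **Sync filtering.** Optional BED-interval masking (intervals expanded by
   a 5 bp flank, the convention for indel-adjacent masking); then biallelic
   SNP calling: a site is kept iff exactly two nucleotides reach a summed
   count of 5 across all samples (N/del ignored; ≥ 3 passing alleles → the
   site is dropped rather than reduced, because the estimators are strictly
   biallelic).
2. **Polarization.** Per parental replicate, the beneficial allele of each
   SNP is the one rising between generation 0 and 110; exact ties go to the
   lexicographically smaller base and are flagged. Conditioning keeps SNPs
   present (q₁₁₀ > 0) and below 0.9 (strict).
3. **Origin classes.** For each mixture, SNPs polarized in both parents
   with the same allele are "shared"; SNPs in only one conditioned set are
   immigrant- or recipient-beneficial. The directional analyses use the
   exclusive classes; the frequency-dependence analysis uses the immigrant
   parent's full beneficial set, whose high-frequency members are exactly
   the shared, counter-selected alleles.
4. **Statistics.** Mean polarized frequency change per class with a
   percentile bootstrap over SNPs (1000 resamples, seeded); Spearman rank
   correlation of start frequency vs change with a seeded permutation
   p-value (1000 permutations, two-sided); log-odds selection coefficients
   with Δt counted between sampled generations (F1→F20 uses Δt = 19);
   cost of pleiotropy as the (sign-flipped) mean s of the recipient
   population's beneficial alleles in the mixture, compared to the same
   class's realized s in its own parent over 0→110. Hudson pool F_ST
   (1 − H_w/H_b, no within-pool sample-size terms; Nei variant available)
   with negative values truncated and counted; PCA on centered, unscaled
   frequencies with listwise deletion of missing SNPs and a deterministic
   sign convention (largest-magnitude loading positive).

## Numerical choices

- Log-odds frequencies are clamped to [ε, 1−ε] with ε = 1/(2·coverage) by
  default; clamped estimates are flagged. The estimator diverges at 0/1 and
  observed fixation at finite depth is usually a sampling artifact.
- The factor 2 in the estimator corresponds to diploid codominant scaling
  (fitnesses 1, 1+s/2, 1+s); the consistency test recovers s ∈
  {0.01, 0.05, 0.1} within 5% over 20 generations.
- Polarization ties carry no directional information; they are flagged and
  excluded from selection summaries.
- Random streams are keyed by role (founder, per-replicate adaptation,
  continuation, per-mixture, per-sample Pool-Seq) from one master seed, so
  adding a replicate or pair never perturbs the others and every run is
  byte-reproducible.
- Mixture replicas are analyzed per replicate and pooled across the three
  replicates of a pair (and across reciprocal directions where stated).

## What the generator does and does not emulate

It emulates: redundant polygenic adaptation from standing variation with
replicate-specific selected subsets; dominance-modulated pleiotropic load;
imbalanced admixture with setup stochasticity; Pool-Seq count noise at
realistic depth; the sampled-generation design (0/110/120/130 and
F1/F20/F29).

It does not emulate: linkage and haplotype-block structure (loci are
unlinked by default, so the genome-wide hitchhiking signal of real data has
no analogue and SNP counts are far smaller), new mutation, lab-adaptation
trends shared across replicates, sequencing/mapping artifacts, or
sex-specific selection. Passing tests therefore demonstrate the directional
logic of the design and the correctness of the inference chain at desk
scale — not effect sizes for any real population.

At this scale the directional phenomena are stochastic: across random seeds
the masking asymmetry, frequency dependence, cost-below-realized and PCA
movement checks each hold in roughly 75–90% of runs; the replica report
labels a check "inconclusive" rather than forcing a verdict when its
significance threshold is not met. With fully dominant costs (h_c = 1) the
masking advantage disappears by construction, but because every carrier
then pays the cost, rare-allele dynamics can transiently overshoot in
either direction; the controls therefore test for the absence of the
positive asymmetry rather than exact zero.

## Known limitations

- Free recombination makes the late-phase dynamics (F20→F29 slowdown)
  weaker than in organisms with few crossovers per chromosome; the linked
  mode exists but is not the default.
- The redundancy lottery needs rare large-effect founder variants; at very
  small N some reservoir loci are absent from the founder draw entirely,
  which is accepted as part of founder sampling.
- Pool F_ST is computed from frequencies without finite-pool corrections;
  comparisons should stay within one design (consistent depth and pool
  size), which is how it is used here.
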