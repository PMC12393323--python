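# Methods

`strainbench` evaluates how well SNV-based strain deconvolution can track
a live biotherapeutic product (LBP) strain through a treatment cohort. It
has three parts: a seeded synthetic-cohort generator that plays the role
of ground truth, a reference deconvolution engine (plus an adapter for
external tools' outputs), and an evaluation layer that scores genotype
recovery, abundance accuracy, detection, diversity, and community
dissimilarity.

## The simulated trial

A cohort consists of `n_participants` participants (default 100), each
contributing `samples_per_participant` samples (default 4). Each
participant privately carries 1–4 *endogenous* strains of the LBP species
— strain sets of different participants are disjoint — and one shared
*simulated LBP* (sLBP) strain is spiked into every sample. Strain
genotypes are binary haplotypes over `n_sites` biallelic SNV positions
(default 10,000), drawn i.i.d. Bernoulli(0.5) per site with duplicate
genotypes rejected, so any two strains differ at about half the sites.
One sLBP genotype is drawn per study and reused across all cohorts of a
run; endogenous genotypes are redrawn per cohort.

Per sample:

- endogenous abundances are a symmetric Dirichlet(α = 1) draw over the
  participant's strains (the flat choice; α is configurable). The
  abundances therefore vary from sample to sample of one participant;
- the sLBP spike level is uniform on {0, 0.1, …, 1.0}; endogenous
  fractions are rescaled by (1 − level) so the composition stays on the
  simplex. At level 1.0 the sample is pure sLBP;
- sequencing depth (reads per SNV site) is one of {5, 10, 20, 30},
  tiled and shuffled within each participant so every participant covers
  the depth grid;
- the observed metagenotype has, at each site s,
  `alt ~ Binomial(d, p_s)` with `p_s = Σ_k π_k g_ks` and `ref = d − alt`.
  Depth is constant across sites by default ("fixed" mode, matching the
  equation of depth with SNV-site coverage); a `poisson` mode draws
  per-site depth around the nominal value instead.

Mixing at the composition level and rendering counts once is
distributionally identical to rendering per-strain counts and summing,
and simpler to verify. Seeding uses one master seed per cohort with
`numpy.random.SeedSequence` children split by (participant, sample), so
any sample is reproducible in isolation and whole cohorts are
bit-for-bit repeatable.

What the generator does *not* emulate: read-level artifacts (sequencing
error, mapping bias, chimeric reads), depth correlation along the
genome, linkage between sites beyond strain haplotypes, multi-species
backgrounds, and genotype relatedness structure (real conspecific
strains share phylogenetic signal; simulated ones are independent
coin-flips, which makes genotype matching *easier* than in real data).
Passing results on the simulation therefore demonstrate correctness of
the inference and scoring machinery under the stated read model, not
field performance on clinical metagenomes.

## The reference deconvolution engine

Given metagenotypes for all samples jointly, the engine infers K
fractional genotypes and per-sample abundance vectors maximizing the
binomial likelihood with an error floor ε:

    alt_is ~ Binomial(d_is, clip(Σ_k π_ik g_ks, ε, 1 − ε)),  ε = 0.01.

K is user-supplied (the benchmark convention is 3× the expected strain
count; 300 at full scale); surplus strains are reported at zero
abundance rather than removed.

The central numerical difficulty is a within-sample degeneracy: for any
single sample, replacing two strains by two site-wise recombinants
("chimeras") of themselves leaves the likelihood unchanged whenever
their weights are (nearly) equal, and at low depth the recombinants can
even fit the noise better. Identifiability comes only from strains being
shared across samples, which plain EM exploits too weakly — it converges
to chimeric local optima whose abundance estimates are far off. The
engine therefore works in stages:

1. **Dictionary discovery.** Samples are visited deepest-first. For each,
   a small strain support is built by greedy forward selection from the
   current dictionary: a candidate strain enters if it raises the sample
   log-likelihood by at least `support_gain` (5 nats; one mixing weight
   is one degree of freedom, so noise contributes ~0.5 nats). If no
   existing strain suffices, a *novel* binary genotype is proposed from
   the sample's residual; because such a proposal optimizes one allele
   per site, pure binomial noise is worth ~0.2 nats/site to it at any
   depth, so novel strains must clear `novel_gain_per_site` = 0.35
   nats/site. A strain truly missing at ≥10% abundance is worth ≥0.7
   nats/site, so the margin separates signal from noise without being
   tuned per depth. Weights within a support are refit by per-sample EM
   (a convex subproblem). A polarized-EM pass (below) then re-estimates
   genotypes pooling all samples, and the most widely used strain is
   taken as the *anchor* — in an LBP trial, the spiked-in strain.
2. **Residual clustering.** Each sample's anchor weight is fit and its
   residual alternate-allele profile computed. Samples sharing
   endogenous strains have correlated residuals, but binomial noise
   attenuates the correlation badly at low depth and high spike level,
   so the engine *disattenuates* it: the known per-sample noise variance
   is subtracted from the diagonal of the residual covariance before
   normalizing. Samples whose residual signal fraction falls below
   `reliability_floor` (0.2), or whose anchor weight exceeds 0.9, do not
   vote in the clustering; the rest are clustered by average-linkage
   agglomeration at correlation distance `cluster_threshold` (0.7).
   Non-voting samples are then *adopted* by the cluster their residual
   clearly correlates with (best mean correlation > 0.1 and at least
   twice the runner-up), so the joint fit still sees every sample that
   shares a cluster's strains.
3. **Pattern EM within clusters.** For each cluster, an exact EM over
   all `2^k_free` binary site-patterns of the free strains (the anchor's
   genotype is held fixed) jointly resolves the cluster's strains;
   because mixing weights differ between the cluster's samples, the
   factorization is identifiable where single-sample fits are not. The
   number of free strains grows one at a time, and a candidate count is
   kept only when it raises the *prior-corrected* marginal likelihood
   (uniform pattern prior, i.e. an independent Bernoulli(½) prior per
   strain and site) by at least 0.05 nats per site — measured gains are
   ≥0.5 nats/site for a real strain at ≥20% abundance versus ~0.001 for
   a surplus strain, so the selection is insensitive to the exact
   margin. Each fit restarts `pattern_restarts` (4) times from random
   weight draws — one start warm-seeded at the measured anchor weights,
   and one-or-two-sample clusters (weakly identifiable) get triple the
   restarts — keeping the best likelihood; from single-sample clusters
   only strains dominating that sample (weight ≥ 0.5) are trusted into
   the dictionary. Stages 2–3 run `refinement_rounds` (2) times: better
   anchor weights give cleaner residuals, hence better clusters.
4. **Dictionary hygiene.** Two algebraic facts make artifact removal
   near-exact for independent random genotypes. *Healing*: complementary
   recombinants satisfy c1 + c2 = a + h site-wise, so any pair whose sum
   minus a dictionary "parent" is a binary vector (4% slack for allele
   errors in the pair) is collapsed to the recovered strain h. The
   identity is symmetric, so cross-sample usage (summed abundance from a
   selection pass) decides direction: the parent must be used at least
   as much as both pair members. *Chimera pruning*: a strain that agrees
   site-wise with one of two better-used strains almost everywhere (5%
   slack) is dropped; for independent genotypes the statistic
   concentrates near S/4, far above either slack, so false flags are
   effectively impossible. Healing must precede pruning — in a surviving
   (c1, c2, h) triple each member is expressible from the other two, and
   pruning alone could discard the real strain.
5. **Final selection and polish.** A fixed *fractional background*
   strain (the dictionary's mean allele frequency; frozen, so it has no
   overfit freedom) is appended to absorb unresolved low-abundance
   mixtures; supports are re-selected; and a read-origin EM with a
   polarizing Jeffreys-type Beta penalty on genotype entries
   (`genotype_polarization` = 2 nats per site, exact constrained M-step)
   polishes genotypes and abundances. Because zero abundances are EM
   fixed points, the selected support pattern survives the polish. The
   polish's penalized negative log-likelihood is non-increasing by
   construction and is the objective trace reported in the result;
   selection, cleanup and polish iterate up to three times so artifacts
   the polish re-creates are pruned as well.

Tunable parameters, defaults, and what moves them:

| parameter | default | meaning |
|---|---|---|
| `n_strains` K | 300 | strains reported; benchmark sets 3× truth |
| `error_floor` ε | 0.01 | sequencing-noise floor on genotype probabilities |
| `tolerance` | 1e-6 | relative objective change declaring convergence |
| `max_iterations` | 1000 | polish EM cap; non-convergence is flagged |
| `genotype_polarization` | 2.0 | strength of the 0/1-pushing Beta penalty |
| `support_gain` | 5 nats | evidence to add an existing strain to a sample |
| `novel_gain_per_site` | 0.35 | evidence/site to propose a new genotype |
| `cluster_threshold` | 0.7 | residual correlation distance cut |
| `reliability_floor` | 0.2 | min residual signal fraction to cluster a sample |

The engine is this package's own design, built for verifiability: every
stage is exact (closed-form M-steps, enumerated patterns, algebraic
identities) rather than approximate. The `load_external_inference`
adapter accepts genotype/abundance tables from any other deconvolution
tool so the evaluation layer can score real-tool outputs identically.

## Evaluation

All genotype comparisons use Jaccard similarity over alternate-allele
site sets after discretizing fractional genotypes at 0.5 (ties to
alternate); two empty sets count as identical. The benchmark's
thresholds are constants of the study design: inferred strains mutually
≥0.95 similar are merged before identifying the sLBP strain; >0.99
near-duplicates are collapsed (survivor = larger total abundance,
abundances summed — greedy in descending abundance, lexicographic tie
break) before endogenous scoring; a true and an inferred strain match at
>0.9; presence means ≥10% inferred abundance; a false positive is >1%
inferred at true 0; a false negative is <5% inferred at true 10%.
Combinations the study does not probe (e.g. true 0 with inferred between
1% and 10%) are labeled indeterminate rather than silently binned. When
one true strain matches several inferred strains, their abundances sum —
consistent with the collapse rule's view that they are split copies.

Alpha diversity is the effective number of strains, exp(Shannon entropy,
natural log). Beta diversity is raw (unnormalized) weighted UniFrac — the
sum over branches of branch length × |abundance difference flowing
through the branch| — on a UPGMA (average-linkage) tree built from
pairwise Jaccard distances over the union of true and collapsed inferred
genotypes, so self- and cross-comparisons share one geometry. UPGMA is
the package's choice of tree construction; the tree is ultrametric, with
identical genotypes coalescing at height zero, which makes the metric
invariant to collapsing duplicates *on that tree*. (UPGMA itself is not
invariant to rebuilding the tree after duplicating a leaf — the
duplicate re-weights cluster averages — which is why one shared tree per
cohort is used.) A normalized UniFrac variant is available behind a
flag.

Core-SNV site selection keeps sites callable in ≥ ceil(0.95 · n_genomes)
genomes (131 of 137 on the reference panel size) with exactly two
observed alleles, each in ≥2 genomes; the minor-allele rule is a genome
count, not a rounded percentage.

## Problem sizes and determinism

The default `StudyConfig` reproduces the full study design (10 cohorts ×
100 participants × 4 samples, 10,000 sites, K = 300). The test suite and
the acceptance script run a scaled design — 20 participants × 4 samples
over 2,000 sites with K = 3× the true strain count, and a depth-30
variant for the cumulative-abundance correlation — which preserves every
qualitative regime of the full design (all four depths, the full spike
grid, 1–4 strains per participant) at roughly a minute of compute per
cohort. Every random draw descends from one master seed through
documented `SeedSequence` spawn keys; rerunning any entry point with the
same seed reproduces results bit-for-bit.

## Known limitations

- Strains whose cumulative abundance across the cohort is small (roughly
  below ~0.3, e.g. always under ~10% in shallow samples) are often not
  discovered; their mass is absorbed by the fractional background
  strain. The evaluation reports them as unmatched — the regime the
  study itself flags as hard.
- The engine's residual clustering presumes block structure (groups of
  samples sharing strains). Designs where strains are shared arbitrarily
  across many samples would rely on the greedy discovery stage alone.
- The recombinant-healing and chimera-pruning identities rely on
  genotypes being (near-)independent across strains; closely related
  real strains weaken both tests and the engine would then lean more on
  the usage conditions.
- Metagenotype reconstruction error is defined here as the
  depth-unweighted mean absolute residual of alternate-allele fractions
  over covered sites; external tools define their internal fit
  diagnostics differently, so those numbers are comparable only in
  trend.
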