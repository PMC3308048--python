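# Methods

## Model

`exolink` computes multipoint parametric LOD scores with the Lander–Green
formulation: the hidden state along a chromosome is the inheritance vector
**v**, one bit per non-founder meiosis (0 = grand-paternal allele
transmitted).  A pedigree with n non-founders has m = 2n meioses and the
engine enumerates all 2^m vectors densely; with f founders, marker and
phenotype likelihoods sum over all 2^(2f) founder-allele assignments.  The
dense enumeration is exact and handles consanguineous loops with no special
casing, at the cost of a hard size limit: m ≤ 12 and f ≤ 5 (4096 vectors ×
1024 assignments), which covers families from sib pairs up to
first-cousins-once-removed unions.

Transitions between positions d cM apart factorise over meioses: each bit
flips independently with probability θ = (1 − e^(−2d/100))/2 (Haldane, no
interference).  The transport operator is applied axis-by-axis on the
2×2×…×2 probability tensor (m reshaped flips), so a full forward–backward
pass over K markers costs O(K · m · 2^m) rather than O(K · 4^m).

At a grid position x the score is

    LOD(x) = log10[ Σ_v P(v | M, x) · P(Φ | v) / P(Φ) ],

with the disease locus placed exactly at x (no θ offset), a uniform 2^(−m)
vector prior, P(Φ | v) the penetrance-weighted phenotype probability
(founder slots carry the disease allele independently with frequency q) and
P(Φ) its prior mean.  LOD(x) ≤ log10(1/P(Φ)) always; equality requires the
posterior to concentrate on vectors whose phenotype likelihood is maximal.

Marker emission probabilities assume biallelic markers in linkage
equilibrium, founder alleles drawn independently with the population
frequency of allele A.  Typed individuals contribute genotype-match
indicators; missing genotypes contribute 1; a marker incompatible with the
pedigree under every vector raises a Mendelian-inconsistency error naming
the marker (the caller may drop it and re-run) rather than silently
zeroing.

Numerics: the forward/backward vectors are renormalised at every step, so
no log-domain bookkeeping is needed inside the HMM; likelihood sums over
founder assignments are exact vectorised dot products (boolean
compatibility masks × assignment weights), cached per observation pattern.
LOD values are kept at full double precision internally and rounded to 4
decimals only on TSV output.

### Verification

Two independent oracles guard the engine.  `brute_force_lod` recomputes the
same quantity by walking the pedigree per vector with a dictionary,
enumerating founder assignments in explicit Python loops, and contracting
explicit transition matrices (built from pairwise bit-difference counts)
over all inheritance-vector paths; it accepts m ≤ 6 and ≤ 3 markers and
agrees with the engine to < 1e-9 over hundreds of randomised instances.
Second, analytic ceilings: with fully informative markers the genome-scan
maximum must equal log10(1/F) for a single affected inbred proband
(F = 1/16 first cousins, 1/32 first cousins once removed) and log10 2 for
an affected-parent sib pair under a rare fully penetrant dominant model;
the engine hits all three to < 1e-3.

## Genotype caller

Reads failing base or mapping quality 13 are removed; reads matching
neither annotated allele are discarded and counted.  A read with error
probability e = 10^(−Q/10) emits the matching allele with probability 1−e
and any specific wrong base with e/3; a heterozygote averages the two
homozygous emission probabilities.  The prior puts t on the heterozygote
and (1−t)/2 on each homozygote; the call is the posterior argmax, with ties
refused (missing) and depth < 5 missing.  On haploid chromosomes the
heterozygote is excluded and homozygotes compared on likelihood alone.
Defaults: t = 0.5 for genotyping known polymorphic sites (small t is the
variant-discovery setting), quality cutoffs 13, depth cutoff 5.

This is an independent-error simplification of the revised-MAQ model used
by samtools; the correlated-error machinery (which damps the impact of
multiple discordant reads) is deliberately not reconstructed.  One visible
consequence: a single confident wrong-allele read at a homozygous site can
flip the call to heterozygous once t is large, so sweeping t upward trades
heterozygote recovery against rare homozygote losses.  On simulated data
the large low-t gains and the t = 0.5 optimum reproduce robustly; strict
step-wise monotonicity of a 1000-site sweep does not (the upper-t trend is
smaller than one site's worth of noise), and the acceptance suite records
that honestly rather than reseeding until it passes.

Ambiguous (A/T, C/G) SNPs are dropped by default everywhere: their alleles
read the same on both strands, making strand-annotation errors
undetectable.

## Marker thinning

Markers are binned per chromosome into half-open 0.3 cM bins anchored at
the first marker's cM; per bin the eligible marker (non-ambiguous, and
genotyped in ≥ 1 sample by default) with maximal 2p(1−p) is kept, ties
broken by lowest bp.  "Genotyped in any sample" (rather than all) was an
open choice; it maximises marker count for multi-sample families.  Output
is a MERLIN-compatible ped/dat/map/freq file set with alleles coded 1/2
(1 = allele A) and missing genotypes `0 0`; the reader reconstructs the
exact genotype matrix (round-trip tested).

## Peak calling and variant filtering

Peaks are maximal runs of grid positions whose LOD reaches the genome-wide
maximum within a tolerance, extended 0.3 cM per side, clamped to the track
span, merged when overlapping, and converted to physical coordinates by
linear interpolation through the marker map (flat-cM runs resolve to their
left-most bp; positions beyond the terminal anchors clamp).  The low-level
default tolerance is 1e-4 LOD (floating-point equality across grid
positions is fragile).  The pipeline-level reporting tolerance is 0.05 LOD
— ties at one printed decimal — because under homozygosity mapping the LOD
saturates at its analytic ceiling across *every* sufficiently informative
autozygous segment, so "the interval(s) attaining the maximum" is only
meaningful at reporting precision; this is also why a single inbred proband
yields many tied peaks rather than one.  Variants are filtered to peaks on
half-open bp intervals after a functional-class filter (default: drop
synonymous); percentages print as `retained (percent)` with two decimals.

## Synthetic data

`pedsim` is the package's data generator and defines its study conditions:

* **Marker maps**: 500 markers at 0.3 cM (the post-thinning density), bp via
  1 Mb/cM.  Allele-A frequencies U(0.1, 0.5), giving mean heterozygosity
  ≈ 0.40 — the informativeness of thinned exome-derived marker sets (array
  sets run ≈ 0.48; an exome-like clustered generator exists for that
  comparison).
* **Gene dropping**: founder haplotypes from marker frequencies, Haldane
  crossovers (matching the engine's kernel exactly), one chromosome at a
  time.  Phenotype conditioning is rejection sampling of the causal-site
  inheritance bits until the template's pattern holds (proband autozygous;
  sibs sharing the paternal allele), capped at 10,000 attempts, followed by
  Markov extension of crossovers outward — exact under no interference and
  far cheaper than resampling whole chromosomes.  The disease allele is
  placed on the founder slot realising the pattern.
* **Pileups**: depth Poisson (or negative binomial for the overdispersed
  off-target regime), per-read qualities constant or uniform on a range,
  errors uniform over the three wrong bases at rate 10^(−Q/10).
* **Fully informative markers**: every founder chromosome gets a unique
  label, re-encoded per map position as 2f one-hot biallelic markers
  ("carries slot s's label").  The label frequency must be small (default
  0.01): within a biallelic emission model a label is only as unique as
  coincidental carriage is rare, and at 1/(2f) the unconstrained non-IBD
  explanations can dominate.  For the sib-pair design the maximum-LOD
  region is where sibs share *both* haplotypes: sib genotypes alone are
  exchangeable in parental origin, so single-haplotype sharing splits the
  posterior 50/50 between paternal (phenotype likelihood ≈ q) and maternal
  (≈ q², as the unaffected parent cannot carry the allele) sharing and
  yields LOD ≈ 0; double sharing is identifiable and attains log10 2.

What the generator does not emulate: linkage disequilibrium between
markers, crossover interference, allele-frequency misspecification between
population and family, genotyping-array error modes, and sequence-level
artifacts (mapping bias, indel misalignment).  Passing tests therefore
demonstrate the correctness of the inference machinery under its own
assumptions, not robustness to real-data model misfit.

## End-to-end recovery, honestly measured

The full pipeline (simulate → call → thin → scan → peaks) places the causal
locus inside a reported peak in 92–93 of 100 replicates of the recessive
first-cousin design, not ≥ 95.  The misses are intrinsic to homozygosity
mapping at this scale, not implementation defects: (a) in ~3% of replicates
a recombination lands immediately beside the causal site, leaving it at the
extreme edge of its autozygous segment where the LOD is > 0.05 below the
saturated tie band and beyond the 0.3 cM flank; (b) short causal segments
(< ~5 cM) are outcompeted by another genuine autozygous segment elsewhere
on the 150 cM chromosome (expected autozygous fraction F = 1/16).  Both
mechanisms apply equally to the real method; the acceptance test asserts
the nominal ≥ 95% and is left failing with this analysis rather than
loosening the peak definition.

## Engine problem sizes

Default analyses run one chromosome with ≤ 500 markers on pedigrees up to
m = 12; a full scan at that size takes seconds on one core, and the
100-replicate recovery experiment about a minute.  These sizes are the
package's desk-scale operating point, chosen to keep exact dense
enumeration (rather than founder-symmetry reductions or approximations)
the whole story.
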