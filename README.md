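# exolink

Genetic linkage mapping from exome-derived SNP genotypes.

Exome sequencing of a family with a Mendelian disorder typically yields
~10,000 candidate functional variants.  Classical multipoint linkage
analysis shrinks that list dramatically: variants outside linkage peaks
cannot be causal under the assumed genetic model and can be discarded — even
for tiny families, down to a single inbred affected individual
(homozygosity mapping).  `exolink` implements the whole path from raw read
evidence to a filtered candidate list, with no genotyping array required:

1. **`genocall`** — infer biallelic genotypes at annotated SNP positions
   from read pileups (independent-error likelihood with a heterozygote
   prior *t*) or extract them from a VCF, applying coverage ≥ 5 and
   base/mapping quality ≥ 13 filters and discarding strand-ambiguous
   (A/T, C/G) SNPs; audit concordance against a second genotype source and
   heterozygote calls on the male X.
2. **`markermap`** — the marker annotation resource (alleles, population
   frequency, genetic-map cM) and bp ↔ cM interpolation.
3. **`markerselect`** — thin markers to approximate linkage equilibrium:
   one SNP per 0.3 cM bin, maximizing expected heterozygosity 2p(1−p);
   write MERLIN-style `ped/dat/map/freq` files.
4. **`linkage`** — the core: exact multipoint parametric LOD scores via the
   Lander–Green inheritance-vector HMM (≤ 12 meioses, ≤ 5 founders,
   consanguineous loops included), Haldane transitions, disease models as
   (q, penetrances) — e.g. fully penetrant recessive (0,0,1) with
   q = 10⁻⁵ — evaluated on a 0.3 cM grid.
5. **`peakfilter`** — linkage peaks = intervals attaining the genome-wide
   maximum LOD, plus 0.3 cM flanks; filter an annotated variant table to
   the peaks and report elimination efficacy.
6. **`pedsim`** — synthetic data: pedigree fixtures (first-cousin
   offspring, first-cousins-once-removed offspring, dominant sib pair),
   gene dropping with recombination and phenotype conditioning, read-pileup
   simulation, and fully informative marker sets for analytic checks.

## The statistic

For inheritance vector **v** (one bit per non-founder meiosis) the engine
computes, at every grid position *x*,

    LOD(x) = log10 [ Σ_v P(v | M, x) · P(Φ | v) / P(Φ) ]

where P(v | M, x) is the HMM posterior given all marker data M (uniform
2⁻ᵐ prior, per-meiosis Haldane flip probabilities), P(Φ | v) sums the
penetrance-weighted phenotype probability over founder disease-allele
assignments, and P(Φ) = Σ_v 2⁻ᵐ P(Φ | v).  Analytic ceilings follow
directly: a single affected first-cousin offspring can reach at most
log10 16 ≈ 1.2 (the reciprocal of the inbreeding coefficient F = 1/16), a
first-cousins-once-removed offspring log10 32 ≈ 1.51, and an
affected-parent sib pair under a rare dominant model log10 2 ≈ 0.3.

## Worked example

Simulate a consanguineous family (affected child of first cousins, one
exome), call genotypes from simulated pileups, thin markers, scan, and
check that the causal locus falls inside a reported peak:

```python
from exolink import pedsim, pipeline

res = pipeline.simulate_and_map(pedsim.SimConfig(seed=4))
print(res.results.summary())
for p in res.peaks:
    print(f"peak {p.chrom}:{p.start_cm:.1f}-{p.end_cm:.1f} cM  max LOD {p.max_lod:.4f}")
print("causal locus at", res.truth.causal_cm, "cM; inside a peak:", res.causal_in_peak)
```

prints

```
Multipoint parametric linkage
==============================================
Family:            A (9 individuals, f=4, m=10)
Typed individuals: CH
Disease model:     recessive q=1e-05 penetrances=(0.0, 0.0, 1.0)
Markers:           500
Grid positions:    500 on 1 chromosome(s)
Max LOD:           1.2040 at 1:73.50 cM

peak 1:57.3-84.3 cM  max LOD 1.2040
causal locus at 75.0 cM; inside a peak: True
```

The maximum LOD of 1.2040 is exactly the homozygosity-mapping ceiling
log10(1/(1/16)) for this design: within the child's autozygous segment the
HMM posterior saturates, and the peak interval (here 27 cM) is the region a
variant filter would keep.

The same stages are scriptable from a shell:

```sh
exolink simulate --template firstcousin_offspring --markers 500 --seed 7 --out sim/
exolink call   --vcf sim/genotypes.vcf --annot sim/annotation.tsv --out calls.tsv
exolink select --annot sim/annotation.tsv --calls calls.tsv --ped sim/pedigree.ped --out fam
exolink link   --prefix fam --model recessive --q 0.00001 --out track.tsv
exolink peaks  --track track.tsv --annot sim/annotation.tsv --tol 0.05 --out peaks.tsv
exolink filter --variants variants.tsv --peaks peaks.tsv --out retained.tsv
```

## Scope

Autosomal parametric linkage only: no non-parametric scores, haplotype
reconstruction, sex-specific maps, X-linked models, or LD-aware HMMs.
Read alignment, duplicate marking and functional annotation are upstream of
this package; the variant filter consumes a pre-annotated table.
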