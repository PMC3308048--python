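# File formats

## Marker annotation TSV

Tab-separated, header required, one row per biallelic SNP:

    name  chrom  bp  alleleA  alleleB  freqA  cM

`bp` is 1-based; `freqA` is the population frequency of `alleleA`; `cM` is
the sex-averaged genetic-map position and must be non-decreasing with `bp`
within a chromosome.  Rows violating the invariants are dropped and
counted; duplicate (chrom, bp) rows are an error by default.

## Genotype TSV

    marker  sample  genotype  depth  pAA  pAB  pBB

`genotype` ∈ {AA, AB, BB, missing}; AA means homozygous for `alleleA`.
Posterior columns are empty for extracted (VCF) calls.

## Pileup TSV

    marker  chrom  pos  base  Qbase  Qmap

One row per read observation.

## Linkage file set (MERLIN-style)

All four files share one marker order.

* `.ped` — one row per individual:
  `family id father mother sex affection  a1 a2  a1 a2 ...`
  with two allele columns per marker coded `1` (alleleA) / `2` (alleleB),
  missing `0 0`; parents `0` for founders; affection 0/1/2 =
  unknown/unaffected/affected.
* `.dat` — `A disease` then one `M <marker>` line per marker.
* `.map` — header `CHROM MARKER POS`, then `chrom marker cM` rows.
* `.freq` — `M <marker>` / `F <freqA> <freqB>` line pairs.

## LOD track TSV

    chrom  cM  LOD

One row per grid position; LOD written to 4 decimals.

## Peaks

BED output is 0-based half-open (`chrom start end name maxLOD`); the side
TSV carries `chrom start_cm end_cm start_bp end_bp max_lod` with 1-based
inclusive-start/exclusive-end bp bounds.

## Variant table TSV

    chrom  pos  ref  alt  class  gene

`class` is a functional-annotation string (e.g. `nonsynonymous SNV`);
filtering drops `synonymous` classes by default.
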