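"""Biallelic genotype inference at annotated marker positions.

Two entry points: a likelihood-based caller for site pileups (read bases with
base/mapping qualities) and a genotype extractor for per-sample VCFs.  Both
apply the same filters: coverage >= 5 high-quality reads, base and mapping
quality >= 13, and optional removal of strand-ambiguous (A/T, C/G) SNPs,
which are prone to strand-annotation errors and dominate discordant calls.

The caller uses an independent-error model.  A read with phred quality Q has
error probability e = 10^(-Q/10); it matches a homozygous genotype's allele
with probability 1-e and any specific wrong base with probability e/3, and a
heterozygote emits the average of the two homozygous emission probabilities.
The prior puts probability t on the heterozygote and (1-t)/2 on each
homozygote; the call is the maximum-posterior genotype.  t is a tunable knob:
small t suits rare-variant discovery, t = 0.5 maximises concordance when
genotyping known polymorphic sites.  On haploid chromosomes (male X) the
heterozygote is excluded and the two homozygotes are compared on likelihood
alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markermap import NUCLEOTIDES, MarkerMap, heterozygosity

GENOTYPES = ("AA", "AB", "BB")
MISSING = "missing"
_COUNT = {"AA": 0, "AB": 1, "BB": 2}


def is_ambiguous(allele_a: str, allele_b: str) -> bool:
    """True for strand-ambiguous SNPs: {A,T} or {C,G} allele pairs."""
    a, b = str(allele_a).upper(), str(allele_b).upper()
    if a not in NUCLEOTIDES or b not in NUCLEOTIDES:
        raise ValueError(f"non-nucleotide alleles ({allele_a!r}, {allele_b!r})")
    if a == b:
        raise ValueError("alleles must differ")
    return {a, b} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class SitePileup:
    """Read evidence at one site: (base, base quality, mapping quality)."""

    chrom: str
    pos_bp: int
    reads: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        for base, bq, mq in self.reads:
            if base not in NUCLEOTIDES:
                raise ValueError(f"bad base {base!r} at {self.chrom}:{self.pos_bp}")
            if bq < 0 or mq < 0:
                raise ValueError("negative quality")


@dataclass(frozen=True)
class CallerConfig:
    """Caller parameters; defaults follow the pipeline's operating point
    (coverage >= 5, qualities >= 13, t = 0.5 for known-site genotyping)."""

    t: float = 0.5
    min_depth: int = 5
    min_base_q: int = 13
    min_map_q: int = 13
    drop_ambiguous: bool = True
    haploid_chroms: frozenset = frozenset({"X", "chrX"})

    def __post_init__(self):
        if not (0.0 <= self.t <= 1.0):
            raise ValueError(f"heterozygote prior t={self.t} outside [0,1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one marker, with posterior provenance."""

    marker: str
    sample: str
    genotype: str  # AA / AB / BB / missing
    depth: int = 0
    posteriors: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.genotype not in GENOTYPES and self.genotype != MISSING:
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.posteriors is not None and abs(sum(self.posteriors) - 1.0) > 1e-9:
            raise ValueError("posteriors must sum to 1")

    @property
    def is_missing(self) -> bool:
        return self.genotype == MISSING

    @property
    def allele_b_count(self) -> float:
        """0/1/2 copies of allele B, NaN when missing (linkage coding)."""
        return float(_COUNT[self.genotype]) if not self.is_missing else float("nan")


@dataclass(frozen=True)
class SiteLikelihood:
    """Likelihood triple P(reads|AA), P(reads|AB), P(reads|BB) plus the
    retained depth; ``likelihoods`` is None when no read survived filtering."""

    likelihoods: tuple[float, float, float] | None
    depth: int
    n_discarded: int = 0


def genotype_likelihoods(pile: SitePileup, alleles: tuple[str, str],
                         cfg: CallerConfig = CallerConfig()) -> SiteLikelihood:
    """Independent-error likelihoods over {AA, AB, BB} for one site.

    Reads failing the base/mapping quality thresholds or matching neither
    annotated allele are discarded (the latter counted in ``n_discarded``).
    """
    a, b = alleles
    if a == b or a not in NUCLEOTIDES or b not in NUCLEOTIDES:
        raise ValueError(f"bad allele pair ({a!r}, {b!r})")
    l_aa = l_ab = l_bb = 1.0
    depth = 0
    discarded = 0
    for base, bq, mq in pile.reads:
        if bq < cfg.min_base_q or mq < cfg.min_map_q:
            continue
        if base != a and base != b:
            discarded += 1
            continue
        e = 10.0 ** (-bq / 10.0)
        p_aa = (1.0 - e) if base == a else e / 3.0
        p_bb = (1.0 - e) if base == b else e / 3.0
        l_aa *= p_aa
        l_bb *= p_bb
        l_ab *= 0.5 * (p_aa + p_bb)
        depth += 1
    if depth == 0:
        return SiteLikelihood(None, 0, discarded)
    return SiteLikelihood((l_aa, l_ab, l_bb), depth, discarded)


def call_genotype(lik: SiteLikelihood, cfg: CallerConfig = CallerConfig(),
                  ploidy: str = "diploid", marker: str = "", sample: str = "") -> GenotypeCall:
    """Maximum-posterior genotype from a likelihood triple.

    Diploid prior: P(AB) = t, P(AA) = P(BB) = (1-t)/2.  Haploid: the
    heterozygote is impossible and the homozygotes split the prior equally.
    Depth below ``min_depth`` or a posterior tie yields a missing call.
    """
    if ploidy not in ("diploid", "haploid"):
        raise ValueError(f"ploidy {ploidy!r}")
    if lik.likelihoods is None or lik.depth < cfg.min_depth:
        return GenotypeCall(marker, sample, MISSING, lik.depth)
    if ploidy == "diploid":
        prior = np.array([(1.0 - cfg.t) / 2.0, cfg.t, (1.0 - cfg.t) / 2.0])
    else:
        prior = np.array([0.5, 0.0, 0.5])
    post = prior * np.asarray(lik.likelihoods)
    total = post.sum()
    if total == 0.0:
        return GenotypeCall(marker, sample, MISSING, lik.depth)
    post = post / total
    order = np.argsort(post)
    if post[order[-1]] - post[order[-2]] <= 1e-12 * post[order[-1]]:
        return GenotypeCall(marker, sample, MISSING, lik.depth)  # refuse ties
    return GenotypeCall(marker, sample, GENOTYPES[int(order[-1])], lik.depth,
                        tuple(float(x) for x in post))


# ---------------------------------------------------------------------------
# VCF extraction


@dataclass
class ExtractionStats:
    n_markers: int = 0
    n_called: int = 0
    n_missing: int = 0
    n_indel_dropped: int = 0
    n_allele_mismatch: int = 0
    n_ambiguous_dropped: int = 0


def extract_genotypes_from_vcf(vcf_path, marker_map: MarkerMap,
                               cfg: CallerConfig = CallerConfig(),
                               sample: str | None = None):
    """Pull genotypes at annotated marker positions out of a per-sample VCF.

    Indel records are dropped; records whose REF/ALT do not match the
    annotated allele pair are dropped and counted; ambiguous SNPs are dropped
    when ``cfg.drop_ambiguous``; depth below ``min_depth`` gives a missing
    call.  Exactly one :class:`GenotypeCall` is emitted per annotated marker
    (missing when the VCF has no usable record there).

    Returns ``(calls, stats)``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ValueError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    if sample is None:
        if len(vcf.samples) != 1:
            raise ValueError("VCF has multiple samples; pass sample=")
        sample = vcf.samples[0]
    try:
        sidx = vcf.samples.index(sample)
    except ValueError:
        raise ValueError(f"sample {sample!r} not in VCF") from None

    stats = ExtractionStats(n_markers=len(marker_map))
    seen: dict[str, GenotypeCall] = {}
    for line_no, rec in enumerate(vcf, start=1):
        ann = marker_map.get(rec.CHROM, rec.POS)
        if ann is None:
            continue
        if cfg.drop_ambiguous and is_ambiguous(ann.allele_a, ann.allele_b):
            stats.n_ambiguous_dropped += 1
            continue
        alts = [a for a in rec.ALT if a != "<NON_REF>"]
        if rec.is_indel or len(rec.REF) != 1 or any(len(a) != 1 for a in alts):
            stats.n_indel_dropped += 1
            continue
        pair = {ann.allele_a, ann.allele_b}
        if alts:
            if {rec.REF, *alts} != pair:
                stats.n_allele_mismatch += 1
                continue
        elif rec.REF not in pair:
            stats.n_allele_mismatch += 1
            continue

        depth = _record_depth(rec, sidx)
        if depth is None or depth < cfg.min_depth:
            continue  # leave missing
        gt = rec.gt_types[sidx]  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        if gt == 2:
            continue
        if gt == 1:
            genotype = "AB"
        else:
            allele = rec.REF if gt == 0 else alts[0]
            genotype = "AA" if allele == ann.allele_a else "BB"
        seen[ann.name] = GenotypeCall(ann.name, sample, genotype, depth)

    calls = []
    for ann in marker_map.markers():
        if cfg.drop_ambiguous and is_ambiguous(ann.allele_a, ann.allele_b):
            continue
        call = seen.get(ann.name)
        if call is None:
            call = GenotypeCall(ann.name, sample, MISSING, 0)
            stats.n_missing += 1
        else:
            stats.n_called += 1
        calls.append(call)
    return calls, stats


def _record_depth(rec, sidx: int) -> int | None:
    try:
        dp = rec.format("DP")
        if dp is not None:
            val = int(dp[sidx][0])
            return val if val >= 0 else None
    except (KeyError, TypeError):
        pass
    dp = rec.INFO.get("DP")
    return int(dp) if dp is not None else None


# ---------------------------------------------------------------------------
# concordance auditing


@dataclass(frozen=True)
class ConcordanceReport:
    n_compared: int
    n_concordant: int
    by_class: dict = field(default_factory=dict)  # 'ambiguous'/'unambiguous' -> (n, n_conc)

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_compared


def concordance(calls_x, calls_y, marker_map: MarkerMap | None = None,
                drop_ambiguous: bool = True) -> ConcordanceReport:
    """Fraction of shared non-missing markers with identical genotypes.

    With a marker map, ambiguous SNPs are excluded when ``drop_ambiguous``
    and the report carries an ambiguous/unambiguous breakdown.
    """
    x = {c.marker: c.genotype for c in calls_x if not c.is_missing}
    y = {c.marker: c.genotype for c in calls_y if not c.is_missing}
    ambig = {}
    if marker_map is not None:
        ambig = {a.name: is_ambiguous(a.allele_a, a.allele_b) for a in marker_map.markers()}
    n = n_conc = 0
    by: dict[str, list[int]] = {"ambiguous": [0, 0], "unambiguous": [0, 0]}
    for marker in x.keys() & y.keys():
        is_amb = ambig.get(marker, False)
        if is_amb and drop_ambiguous:
            continue
        same = x[marker] == y[marker]
        n += 1
        n_conc += same
        cls = "ambiguous" if is_amb else "unambiguous"
        by[cls][0] += 1
        by[cls][1] += same
    if n == 0:
        raise ValueError("no comparable (shared, non-missing) markers")
    return ConcordanceReport(n, n_conc, {k: tuple(v) for k, v in by.items()})


def concordance_sweep(pileups: dict, truth_calls, t_values,
                      marker_map: MarkerMap, cfg: CallerConfig = CallerConfig(),
                      sample: str = "S") -> pd.DataFrame:
    """Concordance against truth as the heterozygote prior t is swept.

    ``pileups`` maps marker name -> :class:`SitePileup`.  Site likelihoods
    are computed once; only the prior changes per t.  Returns a DataFrame
    with columns ``t, concordance, n``.
    """
    t_values = list(t_values)
    if not t_values:
        raise ValueError("t_values is empty")
    for t in t_values:
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"t={t} outside [0,1]")
    ann = {a.name: a for a in marker_map.markers()}
    liks = {}
    for marker, pile in pileups.items():
        a = ann[marker]
        if cfg.drop_ambiguous and is_ambiguous(a.allele_a, a.allele_b):
            continue
        liks[marker] = genotype_likelihoods(pile, (a.allele_a, a.allele_b), cfg)
    rows = []
    for t in t_values:
        cfg_t = CallerConfig(t=t, min_depth=cfg.min_depth, min_base_q=cfg.min_base_q,
                             min_map_q=cfg.min_map_q, drop_ambiguous=cfg.drop_ambiguous,
                             haploid_chroms=cfg.haploid_chroms)
        calls = [call_genotype(lik, cfg_t, marker=m, sample=sample)
                 for m, lik in liks.items()]
        rep = concordance(calls, truth_calls, marker_map, cfg.drop_ambiguous)
        rows.append((t, rep.concordance, rep.n_compared))
    return pd.DataFrame(rows, columns=["t", "concordance", "n"])


@dataclass(frozen=True)
class HaploidRateReport:
    n_het: int
    n_total: int

    @property
    def rate(self) -> float:
        return self.n_het / self.n_total


def haploid_het_rate(calls, sex: int, marker_map: MarkerMap,
                     haploid_chroms=("X", "chrX")) -> HaploidRateReport:
    """Fraction of non-missing haploid-chromosome calls that are heterozygous.

    A QC statistic for male samples: every diploid-mode heterozygous call on
    the X is an error.
    """
    if sex != 1:
        raise ValueError("haploid X audit requires a male sample (sex=1)")
    chrom_of = {a.name: a.chrom for a in marker_map.markers()}
    on_x = [c for c in calls
            if not c.is_missing and chrom_of.get(c.marker) in set(haploid_chroms)]
    if not on_x:
        raise ValueError("no non-missing calls on haploid chromosomes")
    n_het = sum(c.genotype == "AB" for c in on_x)
    return HaploidRateReport(n_het, len(on_x))


# ---------------------------------------------------------------------------
# capture-target distance classes

DISTANCE_CLASSES = ("0", "1-200", ">200")


def classify_by_target_distance(marker_map: MarkerMap, targets, calls=None) -> pd.DataFrame:
    """Bin markers by distance (bp) to the nearest captured base.

    ``targets`` is an iterable of (chrom, start, end) half-open 0-based
    intervals (BED convention).  Classes: 0 (inside a target), 1-200
    (inclusive) and >200.  Returns a DataFrame indexed by class with columns
    ``n_markers`` and, when ``calls`` is given, ``n_called`` (markers with a
    non-missing call).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in targets:
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    if not by_chrom:
        warnings.warn("empty capture-target set: all markers classed '>200'")
    merged = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (np.array([s for s, _ in out]), np.array([e for _, e in out]))

    called = {c.marker for c in calls if not c.is_missing} if calls is not None else None
    counts = {cls: [0, 0] for cls in DISTANCE_CLASSES}
    for ann in marker_map.markers():
        pos0 = ann.pos_bp - 1  # 0-based base
        d = None
        if ann.chrom in merged:
            starts, ends = merged[ann.chrom]
            i = int(np.searchsorted(starts, pos0, side="right")) - 1
            if i >= 0 and pos0 < ends[i]:
                d = 0
            else:
                cands = []
                if i >= 0:
                    cands.append(pos0 - (ends[i] - 1))
                if i + 1 < len(starts):
                    cands.append(starts[i + 1] - pos0)
                d = min(cands)
        cls = ">200" if d is None or d > 200 else ("0" if d == 0 else "1-200")
        counts[cls][0] += 1
        if called is not None and ann.name in called:
            counts[cls][1] += 1
    df = pd.DataFrame(
        {"n_markers": {c: v[0] for c, v in counts.items()},
         "n_called": {c: v[1] for c, v in counts.items()}},
    ).loc[list(DISTANCE_CLASSES)]
    if calls is None:
        df = df.drop(columns="n_called")
    return df


# ---------------------------------------------------------------------------
# genotype table I/O and matrix conversion


def calls_to_matrix(calls) -> pd.DataFrame:
    """Genotype calls -> marker x sample matrix of allele-B copy counts
    (NaN = missing), the coding the linkage engine consumes."""
    rows = {}
    for c in calls:
        rows.setdefault(c.marker, {})[c.sample] = c.allele_b_count
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("marker")


def write_genotype_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tsample\tgenotype\tdepth\tpAA\tpAB\tpBB\n")
        for c in calls:
            p = c.posteriors or ("", "", "")
            p = "\t".join(f"{x:.6g}" if x != "" else "" for x in p)
            fh.write(f"{c.marker}\t{c.sample}\t{c.genotype}\t{c.depth}\t{p}\n")


def read_genotype_tsv(path) -> list[GenotypeCall]:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "sample": str})
    calls = []
    for row in df.itertuples():
        post = None
        if not pd.isna(row.pAA):
            post = (float(row.pAA), float(row.pAB), float(row.pBB))
            s = sum(post)
            post = tuple(x / s for x in post)
        calls.append(GenotypeCall(row.marker, row.sample, row.genotype,
                                  int(row.depth), post))
    return calls


def load_bed(path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED file into (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out
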