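"""Synthetic pedigree data: gene dropping, pileup simulation, fixtures.

This module makes the whole pipeline testable without any external data.  It
provides

* canonical pedigree fixtures — a first-cousin union with one affected
  child, a first-cousins-once-removed union with one affected child, and a
  dominant nuclear family with an affected untyped parent and two typed
  affected siblings;
* gene dropping: founder haplotypes drawn from marker allele frequencies,
  transmitted with Haldane (no-interference) recombination, the same model
  the linkage engine's transition kernel assumes, with optional conditioning
  on the template's affection pattern at a causal locus;
* read-pileup simulation on top of the dropped genotypes (Poisson or
  negative-binomial depth, phred-governed base errors);
* fully informative marker sets in which every founder chromosome carries a
  unique label, encoded as blocks of one-hot biallelic markers with allele
  frequency 1/(2f) — these realise the analytic maximum-LOD ceilings
  (log10 16 for a first-cousin offspring, log10 32 one generation further
  out, log10 2 for an affected-parent sib pair).

All randomness flows from a single seed; substreams are spawned with
``numpy``'s ``default_rng([seed, tag])`` seed-sequence derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genocall import SitePileup
from .linkage import haldane_theta
from .pedigree import AFFECTED, UNAFFECTED, UNKNOWN, DiseaseModel, Individual, Pedigree

TEMPLATES = (
    "firstcousin_offspring",
    "firstcousin_once_removed_offspring",
    "dominant_sibpair",
)

_NON_AMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


def make_pedigree_fixture(template: str) -> Pedigree:
    """Canonical family structure for a known template id.

    ``firstcousin_offspring``: 4 founders, parents of the single typed
    affected child are first cousins (m=10).
    ``firstcousin_once_removed_offspring``: 5 founders, one extra generation
    on one side (m=12).
    ``dominant_sibpair``: untyped parents (one affected), two typed affected
    sibs (m=4).
    """
    if template == "firstcousin_offspring":
        inds = [
            Individual("GF", sex=1), Individual("GM", sex=2),
            Individual("S1", sex=2), Individual("S2", sex=1),
            Individual("U1", "GF", "GM", sex=1),
            Individual("U2", "GF", "GM", sex=2),
            Individual("P1", "U1", "S1", sex=1),
            Individual("P2", "U2", "S2", sex=2),
            Individual("CH", "P1", "P2", sex=1, affection=AFFECTED, typed=True),
        ]
        return Pedigree(inds, family_id="A")
    if template == "firstcousin_once_removed_offspring":
        inds = [
            Individual("GF", sex=1), Individual("GM", sex=2),
            Individual("S1", sex=2), Individual("S2", sex=1),
            Individual("S3", sex=1),
            Individual("U1", "GF", "GM", sex=1),
            Individual("U2", "GF", "GM", sex=2),
            Individual("P1", "U1", "S1", sex=1),          # one side: cousin
            Individual("Q2", "U2", "S2", sex=2),
            Individual("P2", "S3", "Q2", sex=2),          # other side: cousin's child
            Individual("CH", "P1", "P2", sex=1, affection=AFFECTED, typed=True),
        ]
        return Pedigree(inds, family_id="T")
    if template == "dominant_sibpair":
        inds = [
            Individual("FA", sex=1, affection=AFFECTED),
            Individual("MO", sex=2, affection=UNAFFECTED),
            Individual("S1", "FA", "MO", sex=1, affection=AFFECTED, typed=True),
            Individual("S2", "FA", "MO", sex=2, affection=AFFECTED, typed=True),
        ]
        return Pedigree(inds, family_id="M")
    raise ValueError(f"unknown pedigree template {template!r}")


@dataclass
class SimConfig:
    """Study conditions for one simulated family.

    Defaults emulate the pipeline's operating regime: one chromosome of 500
    markers spaced 0.3 cM (the post-thinning density), mean read depth 20
    with Q30 bases, no genotype error, and phenotype conditioning on."""

    template: str = "firstcousin_offspring"
    n_markers: int = 500
    spacing_cm: float = 0.3
    chrom: str = "1"
    # U(0.1, 0.5) allele-A frequencies give mean heterozygosity ~0.40, the
    # post-thinning informativeness of exome-derived marker sets
    freq_low: float = 0.1
    freq_high: float = 0.5
    causal_cm: float | None = None          # default: map midpoint
    depth_mean: float = 20.0
    depth_dispersion: float | None = None   # Poisson when None, else NB size
    base_quality: int = 30
    # when set, per-read phred qualities are uniform on [lo, hi] instead of
    # the constant base_quality — real exome read pools mix qualities, and
    # that mixture is what makes the heterozygote-prior sweep gradual
    base_quality_range: tuple[int, int] | None = None
    map_quality: int = 60
    genotype_error_rate: float = 0.0
    condition_on_phenotype: bool = True
    max_attempts: int = 10_000
    seed: int = 0

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


def synthetic_marker_table(n_markers: int, spacing_cm: float = 0.3,
                           chrom: str = "1", rng: np.random.Generator | None = None,
                           freq_low: float = 0.1, freq_high: float = 0.5,
                           start_bp: int = 1_000_000, bp_per_cm: float = 1_000_000.0,
                           clustered: bool = False, cluster_size: int = 8,
                           cluster_span_cm: float = 0.05,
                           name_prefix: str = "snp") -> pd.DataFrame:
    """Annotation-format marker table on one chromosome.

    ``clustered=True`` mimics exome capture (markers bunched around gene-like
    loci, the cluster centres ``spacing_cm * cluster_size`` apart); the
    default is evenly spaced array-like markers.  Allele-A frequencies are
    uniform on [freq_low, freq_high]; allele pairs are non-ambiguous.
    """
    rng = rng or np.random.default_rng(0)
    if clustered:
        n_clusters = int(np.ceil(n_markers / cluster_size))
        centres = np.arange(n_clusters) * spacing_cm * cluster_size
        cms = np.concatenate([
            c + rng.uniform(-cluster_span_cm, cluster_span_cm, size=cluster_size)
            for c in centres
        ])[:n_markers]
        cms = np.sort(np.maximum(cms, 0.0))
    else:
        cms = np.arange(n_markers) * spacing_cm
    bps = (start_bp + cms * bp_per_cm).astype(np.int64)
    bps = np.maximum.accumulate(bps + np.arange(n_markers))  # strictly increasing
    pair_idx = rng.integers(len(_NON_AMBIGUOUS_PAIRS), size=n_markers)
    return pd.DataFrame({
        "name": [f"{name_prefix}{i:05d}" for i in range(n_markers)],
        "chrom": chrom,
        "bp": bps,
        "alleleA": [_NON_AMBIGUOUS_PAIRS[i][0] for i in pair_idx],
        "alleleB": [_NON_AMBIGUOUS_PAIRS[i][1] for i in pair_idx],
        "freqA": rng.uniform(freq_low, freq_high, size=n_markers),
        "cM": cms,
    })


@dataclass
class TruthRecord:
    """Ground truth of one gene drop."""

    bits: np.ndarray                       # (m, n_sites) inheritance bits
    slot_paths: dict                       # ind id -> (pat slots, mat slots) arrays
    genotypes: pd.DataFrame                # marker x individual allele-B counts
    causal_name: str | None = None
    causal_cm: float | None = None
    causal_bp: int | None = None
    causal_slot: int | None = None
    disease_copies: dict = field(default_factory=dict)  # ind id -> copies at causal
    n_attempts: int = 1


class ConditioningError(RuntimeError):
    pass


def _resolve_slots_at(ped: Pedigree, bits_at: np.ndarray) -> dict[str, tuple[int, int]]:
    slots: dict[str, tuple[int, int]] = {}
    for ind in ped.individuals:
        if ind.is_founder:
            slots[ind.id] = ped.founder_slots[ind.id]
        else:
            mp, mm = ped.meiosis_index[ind.id]
            slots[ind.id] = (slots[ind.father][int(bits_at[mp])],
                             slots[ind.mother][int(bits_at[mm])])
    return slots


def _affection_pattern(ped: Pedigree, template_mode: str):
    """Conditioning predicate at the causal locus -> (ok, disease slot)."""
    if template_mode == "autozygous":
        proband = next(i.id for i in ped.individuals if i.typed and i.affection == AFFECTED)

        def check(slots):
            s0, s1 = slots[proband]
            return (s0 == s1, s0)
        return check
    if template_mode == "shared_paternal":
        sibs = [i.id for i in ped.individuals if i.typed and i.affection == AFFECTED]
        if len(sibs) != 2:
            raise ValueError("shared_paternal pattern needs exactly two typed affecteds")

        def check(slots):
            a, b = slots[sibs[0]][0], slots[sibs[1]][0]
            return (a == b, a)
        return check
    if template_mode == "shared_both":
        sibs = [i.id for i in ped.individuals if i.typed and i.affection == AFFECTED]
        if len(sibs) != 2:
            raise ValueError("shared_both pattern needs exactly two typed affecteds")

        def check(slots):
            (a0, a1), (b0, b1) = slots[sibs[0]], slots[sibs[1]]
            return (a0 == b0 and a1 == b1, a0)
        return check
    raise ValueError(f"unknown conditioning pattern {template_mode!r}")


def _default_pattern(ped: Pedigree, informative: bool = False) -> str:
    """autozygous for single-proband designs; for a typed sib pair the
    disease-transmission pattern is paternal sharing, while the maximum-LOD
    configuration additionally shares the maternal haplotype (sib genotypes
    alone cannot attribute a single shared haplotype to a parent, so only
    doubly shared regions attain the analytic ceiling)."""
    typed = [i for i in ped.individuals if i.typed]
    if len(typed) == 2:
        return "shared_both" if informative else "shared_paternal"
    return "autozygous"


def _sample_descent(ped: Pedigree, cms: np.ndarray, rng: np.random.Generator,
                    condition: bool, pattern: str | None, max_attempts: int,
                    c: int | None = None):
    """Inheritance bits over all sites, optionally conditioned at the causal
    site ``c`` (default: the map midpoint).  Bits at the causal site are
    rejection-sampled until the affection pattern holds; crossovers then
    extend outward site-by-site under the Haldane model (exact conditional
    sampling)."""
    m = ped.n_meioses
    n_sites = len(cms)
    if c is None:
        c = n_sites // 2
    causal_slot = None
    attempts = 1
    if condition:
        check = _affection_pattern(ped, pattern or _default_pattern(ped))
        for attempts in range(1, max_attempts + 1):
            bits_c = rng.integers(0, 2, size=m)
            ok, causal_slot = check(_resolve_slots_at(ped, bits_c))
            if ok:
                break
        else:
            raise ConditioningError(
                f"affection pattern not met in {max_attempts} attempts")
    else:
        bits_c = rng.integers(0, 2, size=m)

    thetas = haldane_theta(np.diff(cms)) if n_sites > 1 else np.array([])
    flips = (rng.random((m, max(n_sites - 1, 0))) < thetas[None, :]).astype(np.int8)
    cum = np.zeros((m, n_sites), dtype=np.int8)
    if n_sites > 1:
        cum[:, 1:] = np.cumsum(flips, axis=1) % 2
    bits = (cum ^ cum[:, [c]]) ^ bits_c[:, None].astype(np.int8)
    return bits, c, causal_slot, attempts


def _slot_paths(ped: Pedigree, bits: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    n_sites = bits.shape[1]
    paths: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ind in ped.individuals:
        if ind.is_founder:
            s0, s1 = ped.founder_slots[ind.id]
            paths[ind.id] = (np.full(n_sites, s0, dtype=np.int8),
                             np.full(n_sites, s1, dtype=np.int8))
        else:
            mp, mm = ped.meiosis_index[ind.id]
            fa, mo = paths[ind.father], paths[ind.mother]
            paths[ind.id] = (np.where(bits[mp] == 0, fa[0], fa[1]),
                             np.where(bits[mm] == 0, mo[0], mo[1]))
    return paths


def gene_drop(ped: Pedigree, markers: pd.DataFrame, dm: DiseaseModel,
              cfg: SimConfig, rng: np.random.Generator | None = None,
              pattern: str | None = None):
    """Drop founder haplotypes through the pedigree along one chromosome.

    Founder alleles are drawn from the markers' ``freqA``; each meiosis
    recombines between adjacent markers with the Haldane probability.  With
    ``cfg.condition_on_phenotype`` the disease allele is placed on the
    founder slot that realises the template's affection pattern at the
    causal site (the marker nearest ``cfg.causal_cm``, default the map
    midpoint).  Genotype errors flip a call to a uniformly chosen different
    genotype at ``cfg.genotype_error_rate``.

    Returns ``(truth, genotypes)`` where ``genotypes`` is the marker x typed-
    sample matrix of allele-B counts after error injection.
    """
    rng = rng or cfg.rng(1)
    mk = markers.sort_values("cM", kind="mergesort").reset_index(drop=True)
    if mk["chrom"].nunique() != 1:
        raise ValueError("gene_drop works one chromosome at a time")
    cms = mk["cM"].to_numpy(dtype=float)

    c = None
    if cfg.causal_cm is not None:
        c = int(np.argmin(np.abs(cms - cfg.causal_cm)))
    bits, c, causal_slot, attempts = _sample_descent(
        ped, cms, rng, cfg.condition_on_phenotype, pattern, cfg.max_attempts, c=c)

    paths = _slot_paths(ped, bits)
    n_sites = len(cms)
    n_slots = 2 * ped.n_founders
    H = (rng.random((n_slots, n_sites)) >= mk["freqA"].to_numpy()[None, :]).astype(np.int8)
    site_idx = np.arange(n_sites)
    geno = {}
    for ind in ped.individuals:
        p, q = paths[ind.id]
        geno[ind.id] = (H[p, site_idx] + H[q, site_idx]).astype(float)
    truth_geno = pd.DataFrame(geno, index=mk["name"])

    disease_copies = {}
    if causal_slot is not None:
        for ind in ped.individuals:
            p, q = paths[ind.id]
            disease_copies[ind.id] = int(p[c] == causal_slot) + int(q[c] == causal_slot)

    typed = ped.typed_ids
    obs = truth_geno[typed].copy()
    if cfg.genotype_error_rate > 0:
        err = rng.random(obs.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=obs.shape)
        obs = obs.where(~err, (obs + shift) % 3)

    truth = TruthRecord(
        bits=bits, slot_paths=paths, genotypes=truth_geno,
        causal_name=str(mk["name"].iloc[c]), causal_cm=float(cms[c]),
        causal_bp=int(mk["bp"].iloc[c]) if "bp" in mk.columns else None,
        causal_slot=causal_slot, disease_copies=disease_copies,
        n_attempts=attempts,
    )
    return truth, obs


def simulate_pileups(markers: pd.DataFrame, genotypes: pd.DataFrame,
                     cfg: SimConfig, rng: np.random.Generator | None = None
                     ) -> dict[str, dict[str, SitePileup]]:
    """Read pileups for every (sample, marker) with a non-missing genotype.

    Depth is Poisson(``depth_mean``) (negative binomial when
    ``depth_dispersion`` is set); each read draws a true allele from the
    genotype (heterozygote: 50/50) and is mis-read to a uniformly chosen
    other base with probability 10^(-Q/10).
    """
    rng = rng or cfg.rng(2)
    mk = markers.set_index("name")
    bases = np.array(list("ACGT"))
    out: dict[str, dict[str, SitePileup]] = {}
    for sample in genotypes.columns:
        per = {}
        for name, g in genotypes[sample].items():
            if np.isnan(g):
                continue
            row = mk.loc[name]
            if cfg.depth_dispersion is None:
                depth = rng.poisson(cfg.depth_mean)
            else:
                k = cfg.depth_dispersion
                depth = rng.negative_binomial(k, k / (k + cfg.depth_mean))
            if depth == 0:
                per[name] = SitePileup(str(row["chrom"]), int(row["bp"]), ())
                continue
            if cfg.base_quality_range is None:
                quals = np.full(depth, cfg.base_quality)
            else:
                lo, hi = cfg.base_quality_range
                quals = rng.integers(lo, hi + 1, size=depth)
            b_alleles = rng.random(depth) < (g / 2.0)
            read_bases = np.where(b_alleles, row["alleleB"], row["alleleA"]).astype(object)
            errs = rng.random(depth) < 10.0 ** (-quals / 10.0)
            for i in np.nonzero(errs)[0]:
                others = [x for x in bases if x != read_bases[i]]
                read_bases[i] = others[rng.integers(3)]
            per[name] = SitePileup(
                str(row["chrom"]), int(row["bp"]),
                tuple((str(b), int(q), cfg.map_quality)
                      for b, q in zip(read_bases, quals)),
            )
        out[sample] = per
    return out


# ---------------------------------------------------------------------------
# fully informative markers (analytic-ceiling fixtures)


@dataclass
class FullyInformativeSet:
    markers: pd.DataFrame       # name chrom bp cM freqA (+ block, slot)
    genotypes: pd.DataFrame     # marker x typed-sample allele-B counts
    truth: TruthRecord


def fully_informative_markers(ped: Pedigree, n_blocks: int = 100,
                              spacing_cm: float = 0.3, chrom: str = "1",
                              seed: int = 0, rng: np.random.Generator | None = None,
                              pattern: str | None = None,
                              condition: bool = True,
                              label_freq: float = 0.01) -> FullyInformativeSet:
    """Marker blocks in which every founder chromosome is distinguishable.

    Each founder slot gets a unique label; at each of ``n_blocks`` map
    positions the labels are re-encoded as 2f one-hot biallelic markers
    (allele A = "carries slot s's label").  Descent is gene-dropped with
    Haldane recombination, conditioned (by default) on the template's
    affection pattern at the central block — autozygosity of the proband, or
    the sib pair sharing the paternal haplotype.

    The label allele frequency must be small: within the biallelic emission
    model a label is "unique" only insofar as two founder slots are unlikely
    to carry it by coincidence, so making it common re-opens exactly the
    non-IBD explanations the construction is meant to exclude (at 1/(2f)
    they can even dominate for sib-sharing designs).  The 0.01 default keeps
    coincidental carriage negligible while leaving the analytic maximum-LOD
    ceilings intact.
    """
    rng = rng or np.random.default_rng([seed, 3])
    cms = np.arange(n_blocks) * spacing_cm
    pattern = pattern or _default_pattern(ped, informative=True)
    bits, c, causal_slot, attempts = _sample_descent(
        ped, cms, rng, condition, pattern, 10_000)
    paths = _slot_paths(ped, bits)

    n_slots = 2 * ped.n_founders
    freq = float(label_freq)
    bp_per_cm = 1_000_000.0
    rows = []
    geno: dict[str, list[float]] = {s: [] for s in ped.typed_ids}
    names = []
    for k in range(n_blocks):
        for s in range(n_slots):
            name = f"b{k:04d}_s{s}"
            names.append(name)
            rows.append((name, chrom, int(1_000_000 + cms[k] * bp_per_cm) + s,
                         freq, float(cms[k]), k, s))
            for sample in ped.typed_ids:
                p, q = paths[sample]
                n_label = int(p[k] == s) + int(q[k] == s)
                geno[sample].append(2.0 - n_label)  # allele-B copy count
    markers = pd.DataFrame(rows, columns=["name", "chrom", "bp", "freqA", "cM",
                                          "block", "slot"])
    genotypes = pd.DataFrame(geno, index=pd.Index(names, name="marker"))
    truth = TruthRecord(bits=bits, slot_paths=paths,
                        genotypes=genotypes, causal_name=f"block{c}",
                        causal_cm=float(cms[c]), causal_slot=causal_slot,
                        n_attempts=attempts)
    return FullyInformativeSet(markers, genotypes, truth)


# ---------------------------------------------------------------------------
# independent Mendelian validator


def mendelian_inconsistencies(ped: Pedigree, genotypes: pd.DataFrame) -> list[tuple[str, str]]:
    """(marker, individual) pairs whose allele-B copy count is impossible
    given the parents' counts.  Independent of the descent machinery: uses
    only the transmissible-allele sets {0}, {0,1}, {1} for counts 0/1/2."""
    transmissible = {0.0: {0}, 1.0: {0, 1}, 2.0: {1}}
    bad = []
    for ind in ped.nonfounders:
        if ind.id not in genotypes.columns:
            continue
        for marker in genotypes.index:
            g = genotypes.at[marker, ind.id]
            gf = genotypes.at[marker, ind.father] if ind.father in genotypes.columns else None
            gm = genotypes.at[marker, ind.mother] if ind.mother in genotypes.columns else None
            if g is None or np.isnan(g):
                continue
            fa_set = transmissible.get(gf, {0, 1}) if gf is not None and not np.isnan(gf) else {0, 1}
            mo_set = transmissible.get(gm, {0, 1}) if gm is not None and not np.isnan(gm) else {0, 1}
            if not any(a + b == g for a in fa_set for b in mo_set):
                bad.append((str(marker), ind.id))
    return bad


# ---------------------------------------------------------------------------
# artifact writers (annotation TSV / VCF / pileup TSV / truth JSON)


def write_annotation_tsv(markers: pd.DataFrame, path) -> None:
    cols = ["name", "chrom", "bp", "alleleA", "alleleB", "freqA", "cM"]
    markers[cols].to_csv(path, sep="\t", index=False)


def write_vcf(markers: pd.DataFrame, genotypes: pd.DataFrame, path,
              depth: int = 20) -> None:
    """Minimal VCF 4.2 with GT:DP per typed sample at every non-missing site."""
    mk = markers.set_index("name")
    samples = list(genotypes.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in markers["chrom"].astype(str).unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = markers.sort_values(["chrom", "bp"])["name"]
        for name in order:
            row = mk.loc[name]
            gts = []
            any_called = False
            for s in samples:
                g = genotypes.at[name, s] if name in genotypes.index else np.nan
                if np.isnan(g):
                    gts.append("./.:0")
                else:
                    any_called = True
                    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[float(g)]
                    gts.append(f"{gt}:{depth}")
            if not any_called:
                continue
            fh.write(f"{row['chrom']}\t{int(row['bp'])}\t{name}\t{row['alleleA']}\t"
                     f"{row['alleleB']}\t.\tPASS\t.\tGT:DP\t" + "\t".join(gts) + "\n")


def write_pileup_tsv(pileups: dict[str, SitePileup], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tpos\tbase\tQbase\tQmap\n")
        for marker, pile in pileups.items():
            for base, bq, mq in pile.reads:
                fh.write(f"{marker}\t{pile.chrom}\t{pile.pos_bp}\t{base}\t{bq}\t{mq}\n")


def read_pileup_tsv(path) -> dict[str, SitePileup]:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    out = {}
    for marker, sub in df.groupby("marker", sort=False):
        reads = tuple((str(r.base), int(r.Qbase), int(r.Qmap)) for r in sub.itertuples())
        out[marker] = SitePileup(str(sub["chrom"].iloc[0]), int(sub["pos"].iloc[0]), reads)
    return out
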