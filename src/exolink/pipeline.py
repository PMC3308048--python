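"""End-to-end convenience: simulate a family, genotype it, map it, filter.

Chains the pipeline stages on synthetic data: gene-dropped genotypes ->
read-pileup simulation -> likelihood-based genotype calling -> marker
thinning -> multipoint LOD -> linkage peaks -> causal-locus containment.
Used by the recovery tests and the worked examples.

Peaks are reported with ``peak_tol_lod = 0.05``: positions whose LOD rounds
to the genome-wide maximum at one printed decimal are tied with it.  Under
homozygosity mapping the LOD saturates at its analytic ceiling across every
sufficiently informative autozygous segment, so the "interval(s) attaining
the maximum" are only meaningful at reporting precision — this is why a
single inbred proband yields several tied peaks rather than one.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import genocall, markerselect, pedsim
from .linkage import LinkageModel
from .markermap import MarkerMap
from .pedigree import DiseaseModel

PEAK_TOL_LOD = 0.05


@dataclass
class PipelineResult:
    truth: pedsim.TruthRecord
    calls_matrix: pd.DataFrame
    selected: pd.DataFrame
    results: "object"            # LinkageResults
    peaks: list
    causal_in_peak: bool


def simulate_and_map(cfg: pedsim.SimConfig,
                     dm: DiseaseModel | None = None,
                     peak_tol_lod: float = PEAK_TOL_LOD,
                     flank_cm: float = 0.3) -> PipelineResult:
    """Run the full pipeline on one simulated family.

    The disease model defaults to fully penetrant recessive (dominant for
    the sib-pair template) with allele frequency 1e-5.
    """
    ped = pedsim.make_pedigree_fixture(cfg.template)
    if dm is None:
        dm = (DiseaseModel.dominant() if cfg.template == "dominant_sibpair"
              else DiseaseModel.recessive())
    markers = pedsim.synthetic_marker_table(
        cfg.n_markers, cfg.spacing_cm, cfg.chrom, cfg.rng(0),
        cfg.freq_low, cfg.freq_high)
    truth, obs = pedsim.gene_drop(ped, markers, dm, cfg)
    pileups = pedsim.simulate_pileups(markers, obs, cfg)

    marker_map = MarkerMap.from_frame(markers)
    ann = {a.name: a for a in marker_map.markers()}
    ccfg = genocall.CallerConfig()
    calls = []
    for sample, per in pileups.items():
        for name, pile in per.items():
            a = ann[name]
            lik = genocall.genotype_likelihoods(pile, (a.allele_a, a.allele_b), ccfg)
            calls.append(genocall.call_genotype(lik, ccfg, marker=name, sample=sample))
    matrix = genocall.calls_to_matrix(calls)

    scfg = markerselect.SelectionConfig()
    selected = markerselect.select_markers(
        markerselect.bin_markers(marker_map, scfg), matrix, scfg)

    res = LinkageModel(ped, selected, matrix, dm).fit()
    peaks = res.peaks(flank_cm=flank_cm, tol=peak_tol_lod, marker_map=marker_map)
    inside = any(p.contains_cm(cfg.chrom, truth.causal_cm) for p in peaks)
    return PipelineResult(truth, matrix, selected, res, peaks, inside)
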