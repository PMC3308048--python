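"""Linkage-peak intervals and variant elimination.

A linkage peak is a maximal run of grid positions attaining the genome-wide
maximum LOD score (within a small tolerance), extended by a flank (default
0.3 cM) on either side.  Variants whose position falls outside every peak
cannot be the causal mutation under the assumed genetic model and are
discarded; the fraction eliminated is the pipeline's headline efficacy
number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .linkage import LodTrack
from .markermap import MarkerMap


@dataclass(frozen=True)
class PeakInterval:
    """One linkage peak in genetic and (when a map is given) physical space.

    cM bounds are inclusive; bp bounds follow the half-open convention
    (start inclusive, end exclusive) and are written 0-based to BED."""

    chrom: str
    start_cm: float
    end_cm: float
    max_lod: float
    start_bp: int | None = None
    end_bp: int | None = None

    def contains_bp(self, chrom: str, pos_bp: int) -> bool:
        if self.start_bp is None:
            raise ValueError("peak has no physical coordinates")
        return chrom == self.chrom and self.start_bp <= pos_bp < self.end_bp

    def contains_cm(self, chrom: str, pos_cm: float) -> bool:
        return chrom == self.chrom and self.start_cm <= pos_cm <= self.end_cm


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos_bp: int
    ref: str
    alt: str
    func_class: str = ""
    gene: str = ""

    def __post_init__(self):
        if self.pos_bp < 1:
            raise ValueError("variant position must be >= 1")


@dataclass(frozen=True)
class FilterSummary:
    n_variants_total: int
    n_in_peaks: int
    n_peaks: int
    max_lod: float

    @property
    def fraction_eliminated(self) -> float:
        return 1.0 - self.n_in_peaks / self.n_variants_total


def find_peaks(track: LodTrack, flank_cm: float = 0.3, tol: float = 1e-4,
               marker_map: MarkerMap | None = None) -> list[PeakInterval]:
    """Peaks = runs of grid positions with LOD >= genome-wide max - tol,
    each extended ``flank_cm`` per side (clamped to the track's span) and
    merged when overlapping.  bp bounds are interpolated through the marker
    map when one is provided."""
    df = track.df.dropna(subset=["LOD"])
    if len(df) == 0:
        raise ValueError("empty LOD track")
    m_star = float(df["LOD"].max())
    peaks: list[PeakInterval] = []
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom].sort_values("cM")
        cms = sub["cM"].to_numpy(dtype=float)
        lods = sub["LOD"].to_numpy(dtype=float)
        hit = lods >= m_star - tol
        if not hit.any():
            continue
        lo, hi = cms[0], cms[-1]
        # maximal runs of consecutive hits
        edges = np.flatnonzero(np.diff(np.concatenate(([0], hit.view(np.int8), [0]))))
        intervals = []
        for s, e in zip(edges[::2], edges[1::2]):
            start = max(cms[s] - flank_cm, lo)
            end = min(cms[e - 1] + flank_cm, hi)
            intervals.append([start, end, float(lods[s:e].max())])
        intervals.sort()
        merged = [intervals[0]]
        for start, end, ml in intervals[1:]:
            if start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] = max(merged[-1][2], ml)
            else:
                merged.append([start, end, ml])
        for start, end, ml in merged:
            sbp = ebp = None
            if marker_map is not None:
                sbp = int(marker_map.cm_to_bp(str(chrom), start))
                ebp = int(marker_map.cm_to_bp(str(chrom), end)) + 1
            peaks.append(PeakInterval(str(chrom), float(start), float(end),
                                      ml, sbp, ebp))
    return peaks


def default_class_filter(v: VariantRecord) -> bool:
    """Keep exonic variants that are not synonymous substitutions (the
    candidate set for a Mendelian causal mutation)."""
    cls = v.func_class.strip().lower().replace("_", " ")
    return cls not in {"synonymous", "synonymous snv"}


def filter_variants(variants, peaks: list[PeakInterval],
                    class_filter: Callable[[VariantRecord], bool] | None = None):
    """Restrict a variant list to linkage peaks.

    The class filter (default: drop synonymous) defines the candidate set;
    the summary's total counts candidates, of which those inside a peak (bp
    half-open) are retained.  Returns ``(retained, FilterSummary)``.
    """
    class_filter = class_filter or default_class_filter
    candidates = [v for v in variants if class_filter(v)]
    retained = [v for v in candidates
                if any(p.contains_bp(v.chrom, v.pos_bp) for p in peaks)]
    max_lod = max((p.max_lod for p in peaks), default=float("nan"))
    summary = FilterSummary(len(candidates), len(retained), len(peaks), max_lod)
    return retained, summary


def format_retained(n_in: int, n_total: int) -> str:
    """Render 'retained (percent)' the way the efficacy table prints it:
    604 of 10,982 -> '604 (5.50)'."""
    pct = 100.0 * n_in / n_total if n_total else 0.0
    return f"{n_in} ({pct:.2f})"


def efficacy_report(summaries: dict[str, FilterSummary],
                    models: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-family elimination-efficacy table.

    Columns: model, number of linkage peaks, max LOD, number of candidate
    variants, and retained count with percentage.
    """
    if not summaries:
        raise ValueError("no summaries")
    rows = []
    for fam, s in summaries.items():
        rows.append({
            "family": fam,
            "model": (models or {}).get(fam, ""),
            "n_peaks": s.n_peaks,
            "max_lod": s.max_lod,
            "n_variants": s.n_variants_total,
            "retained (%)": format_retained(s.n_in_peaks, s.n_variants_total),
        })
    return pd.DataFrame(rows).set_index("family")


# ---------------------------------------------------------------------------
# I/O


def write_peaks_bed(peaks: list[PeakInterval], path) -> None:
    """0-based half-open BED of peak physical intervals."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            if p.start_bp is None:
                raise ValueError("peaks lack physical coordinates")
            fh.write(f"{p.chrom}\t{p.start_bp - 1}\t{p.end_bp - 1}\t"
                     f"peak{i + 1}\t{p.max_lod:.4f}\n")


def write_peaks_tsv(peaks: list[PeakInterval], path) -> None:
    rows = [{"chrom": p.chrom, "start_cm": p.start_cm, "end_cm": p.end_cm,
             "start_bp": p.start_bp, "end_bp": p.end_bp, "max_lod": p.max_lod}
            for p in peaks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    """Variant table: columns ``chrom pos ref alt class gene``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns={"class": "func_class"})
    return [
        VariantRecord(str(row["chrom"]), int(row["pos"]), str(row["ref"]),
                      str(row["alt"]), str(row.get("func_class", "")),
                      str(row.get("gene", "")))
        for _, row in df.iterrows()
    ]
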