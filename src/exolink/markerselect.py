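"""Marker thinning for linkage equilibrium and linkage-file output.

The Lander-Green HMM assumes markers in linkage equilibrium, so dense
genotype sets are thinned to one SNP per genetic-map bin (default 0.3 cM),
keeping in each bin the eligible marker with the highest expected
heterozygosity 2p(1-p).  The selection is written as a MERLIN-style
ped/dat/map/freq file set.

File dialect (tab/space separated, one marker order everywhere):

* ``.ped``  — ``fam id father mother sex affection`` then two allele columns
  per marker coded 1 (allele A) / 2 (allele B), missing ``0 0``.
* ``.dat``  — ``A disease`` then one ``M <marker>`` line per marker.
* ``.map``  — header ``CHROM MARKER POS`` then ``chrom marker cM`` rows.
* ``.freq`` — ``M <marker>`` / ``F <freqA> <freqB>`` line pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genocall import is_ambiguous
from .markermap import MarkerMap, heterozygosity
from .pedigree import Individual, Pedigree


@dataclass(frozen=True)
class SelectionConfig:
    bin_cm: float = 0.3
    require_genotype: bool = True

    def __post_init__(self):
        if self.bin_cm <= 0:
            raise ValueError("bin_cm must be positive")


@dataclass(frozen=True)
class LinkageFileSet:
    ped: Path
    dat: Path
    map: Path
    freq: Path


def bin_markers(marker_map: MarkerMap, cfg: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Assign every marker to a half-open cM bin.

    Bins are [k·bin, (k+1)·bin) anchored at each chromosome's first marker
    cM, so a marker exactly on a boundary falls in the higher bin.  Returns
    the annotation table plus a ``bin`` column.
    """
    parts = []
    for chrom in marker_map.chromosomes:
        g = marker_map.chrom_frame(chrom).copy()
        anchor = float(g["cM"].iloc[0])
        # nudge for float error so an exact-boundary marker lands upstairs
        g["bin"] = np.floor((g["cM"] - anchor) / cfg.bin_cm + 1e-9).astype(int)
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def select_markers(binned: pd.DataFrame, calls_matrix: pd.DataFrame | None,
                   cfg: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """One marker per (chromosome, bin): the eligible marker maximising
    2p(1-p), ties broken by lowest bp.

    Eligible = non-ambiguous alleles and, when ``cfg.require_genotype``, at
    least one non-missing call in ``calls_matrix`` (marker x sample counts).
    Bins with no eligible marker are simply empty; no eligible marker
    anywhere is an error.
    """
    df = binned.copy()
    df["het"] = [heterozygosity(p) for p in df["freqA"]]
    ambiguous = df.apply(lambda r: is_ambiguous(r["alleleA"], r["alleleB"]), axis=1)
    eligible = ~ambiguous
    if cfg.require_genotype:
        if calls_matrix is None:
            raise ValueError("require_genotype needs a calls matrix")
        typed = calls_matrix.notna().any(axis=1)
        eligible &= df["name"].map(typed).fillna(False).astype(bool)
    df = df[eligible]
    if len(df) == 0:
        raise ValueError("no eligible markers genome-wide")
    # max het, ties -> lowest bp: sort then take first per bin
    df = df.sort_values(["chrom", "bin", "het", "bp"],
                        ascending=[True, True, False, True], kind="mergesort")
    sel = df.groupby(["chrom", "bin"], sort=False).head(1)
    return sel.sort_values(["chrom", "bp"], kind="mergesort").drop(columns="het") \
              .reset_index(drop=True)


def write_linkage_files(ped: Pedigree, selected: pd.DataFrame,
                        calls_matrix: pd.DataFrame, prefix) -> LinkageFileSet:
    """Write the MERLIN-style ped/dat/map/freq set for a marker selection.

    ``selected`` needs columns ``name chrom cM alleleA alleleB freqA``;
    genotype counts come from ``calls_matrix`` (NaN and untyped individuals
    written as ``0 0``).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for col in ("alleleA", "alleleB"):
        if selected[col].isna().any():
            raise ValueError("selected marker with undefined allele")
    names = selected["name"].tolist()

    fs = LinkageFileSet(
        ped=prefix.with_suffix(".ped"), dat=prefix.with_suffix(".dat"),
        map=prefix.with_suffix(".map"), freq=prefix.with_suffix(".freq"),
    )
    code = {0.0: "1 1", 1.0: "1 2", 2.0: "2 2"}
    with open(fs.ped, "w") as fh:
        for ind in ped.individuals:
            row = [ped.family_id, ind.id, ind.father or "0", ind.mother or "0",
                   str(ind.sex), str(ind.affection)]
            for name in names:
                g = np.nan
                if ind.typed and ind.id in calls_matrix.columns and name in calls_matrix.index:
                    g = calls_matrix.at[name, ind.id]
                row.append("0 0" if pd.isna(g) else code[float(g)])
            fh.write("\t".join(row) + "\n")
    with open(fs.dat, "w") as fh:
        fh.write("A\tdisease\n")
        for name in names:
            fh.write(f"M\t{name}\n")
    with open(fs.map, "w") as fh:
        fh.write("CHROM\tMARKER\tPOS\n")
        for r in selected.itertuples():
            fh.write(f"{r.chrom}\t{r.name}\t{r.cM:.6f}\n")
    with open(fs.freq, "w") as fh:
        for r in selected.itertuples():
            fh.write(f"M {r.name}\nF {r.freqA:.6f} {1.0 - r.freqA:.6f}\n")
    return fs


def read_linkage_files(prefix):
    """Read a ped/dat/map/freq set back into engine inputs.

    Returns ``(pedigree, markers, genotypes)`` with ``markers`` holding
    ``name chrom cM freqA`` and ``genotypes`` the marker x individual
    allele-B count matrix (individuals with any typed marker).
    """
    prefix = Path(prefix)
    dat = pd.read_csv(prefix.with_suffix(".dat"), sep=r"\s+", header=None,
                      names=["type", "name"])
    names = dat[dat["type"] == "M"]["name"].tolist()
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", skiprows=1,
                     header=None, names=["chrom", "name", "cM"],
                     dtype={"chrom": str})
    freqs = {}
    with open(prefix.with_suffix(".freq")) as fh:
        current = None
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "M":
                current = parts[1]
            elif parts[0] == "F":
                freqs[current] = float(parts[1])
    markers = mp[mp["name"].isin(names)].copy()
    markers["freqA"] = markers["name"].map(freqs)

    inds, geno = [], {}
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            fam, iid, fa, mo, sex, aff = parts[:6]
            alleles = parts[6:]
            counts = []
            for k in range(len(names)):
                a1, a2 = alleles[2 * k], alleles[2 * k + 1]
                counts.append(np.nan if a1 == "0" or a2 == "0"
                              else (int(a1) - 1) + (int(a2) - 1))
            typed = any(not np.isnan(c) for c in counts)
            inds.append(Individual(iid, fa if fa != "0" else None,
                                   mo if mo != "0" else None, int(sex),
                                   int(aff), typed=typed))
            if typed:
                geno[iid] = counts
    ped = Pedigree(inds, family_id=fam)
    genotypes = pd.DataFrame(geno, index=pd.Index(names, name="marker"))
    return ped, markers.reset_index(drop=True), genotypes
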