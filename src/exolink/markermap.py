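"""Marker annotation resource: positions, alleles, frequencies, genetic map.

A :class:`MarkerMap` holds, per chromosome, an ordered table of biallelic SNP
markers with physical (bp, 1-based) and genetic (cM, sex-averaged) positions
plus population allele frequencies.  It is the coordinate backbone for the
whole pipeline: genotype extraction matches VCF records against it, marker
thinning bins by its cM positions, and linkage peaks are converted back to
physical intervals through it.

Physical/genetic interconversion is piecewise linear between annotated
anchors; positions beyond the terminal anchors clamp to the terminal cM/bp
(no extrapolation, so coordinates never go negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NUCLEOTIDES = frozenset("ACGT")

ANNOTATION_COLUMNS = ["name", "chrom", "bp", "alleleA", "alleleB", "freqA", "cM"]


class AnnotationFormatError(ValueError):
    """Raised for structurally invalid annotation files."""


@dataclass(frozen=True)
class MarkerAnnotation:
    """One biallelic SNP marker.

    Attributes
    ----------
    name : str
        Marker identifier (e.g. an rs number).
    chrom : str
        Chromosome label.
    pos_bp : int
        Physical position, 1-based.
    allele_a, allele_b : str
        The two nucleotide alleles.
    freq_a : float
        Population frequency of ``allele_a`` in [0, 1].
    pos_cm : float
        Genetic map position in centimorgans (sex-averaged).
    """

    name: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str
    freq_a: float
    pos_cm: float

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.name}: alleles must differ")
        if not (0.0 <= self.freq_a <= 1.0):
            raise ValueError(f"{self.name}: freq_a {self.freq_a} outside [0,1]")

    @property
    def heterozygosity(self) -> float:
        return heterozygosity(self.freq_a)


def heterozygosity(freq_a: float) -> float:
    """Expected heterozygosity 2·p·(1−p) of a biallelic marker.

    Used as the informativeness score when thinning markers.  Symmetric in
    p ↔ 1−p, maximal (0.5) at p = 0.5.
    """
    p = float(freq_a)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"allele frequency {p} outside [0,1]")
    return 2.0 * p * (1.0 - p)


class MarkerMap:
    """Ordered per-chromosome collection of :class:`MarkerAnnotation`.

    Markers are strictly increasing in bp within each chromosome and their cM
    positions are non-decreasing with bp.  Construct via
    :func:`load_annotation` or :meth:`from_frame`.
    """

    def __init__(self, df: pd.DataFrame, n_dropped: int = 0):
        # canonical column order, sorted by (chrom, bp)
        self.df = df.sort_values(["chrom", "bp"], kind="mergesort").reset_index(drop=True)
        self.n_dropped = n_dropped
        self._by_chrom = {c: g.reset_index(drop=True) for c, g in self.df.groupby("chrom", sort=False)}
        self._index = {(r.chrom, r.bp): i for i, r in enumerate(self.df.itertuples())}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, on_duplicate: str = "error") -> "MarkerMap":
        """Build a map from a DataFrame with the annotation columns.

        Rows violating the row-level invariants (equal alleles, frequency
        outside [0,1], non-nucleotide alleles, non-positive bp) are dropped
        and counted in ``n_dropped``.  Duplicate (chrom, bp) pairs raise by
        default; ``on_duplicate='drop'`` keeps the first.
        """
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise AnnotationFormatError(f"annotation missing columns: {missing}")
        if len(df) == 0:
            raise AnnotationFormatError("empty annotation file")
        df = df[ANNOTATION_COLUMNS].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["name"] = df["name"].astype(str)
        for col in ("alleleA", "alleleB"):
            df[col] = df[col].astype(str).str.upper()
        df["bp"] = pd.to_numeric(df["bp"], errors="coerce")
        df["freqA"] = pd.to_numeric(df["freqA"], errors="coerce")
        df["cM"] = pd.to_numeric(df["cM"], errors="coerce")

        ok = (
            df["bp"].notna()
            & (df["bp"] >= 1)
            & df["freqA"].between(0.0, 1.0)
            & df["cM"].notna()
            & df["alleleA"].isin(NUCLEOTIDES)
            & df["alleleB"].isin(NUCLEOTIDES)
            & (df["alleleA"] != df["alleleB"])
        )
        n_dropped = int((~ok).sum())
        df = df[ok].copy()
        if len(df) == 0:
            raise AnnotationFormatError("no valid annotation rows after filtering")
        df["bp"] = df["bp"].astype(np.int64)

        dup = df.duplicated(subset=["chrom", "bp"], keep="first")
        if dup.any():
            if on_duplicate == "error":
                row = df[dup].iloc[0]
                raise AnnotationFormatError(
                    f"duplicate marker position {row.chrom}:{row.bp}"
                )
            elif on_duplicate == "drop":
                n_dropped += int(dup.sum())
                df = df[~dup]
            else:
                raise ValueError(f"on_duplicate={on_duplicate!r}")

        df = df.sort_values(["chrom", "bp"], kind="mergesort")
        # cM must be non-decreasing in bp within a chromosome
        for chrom, g in df.groupby("chrom"):
            if (np.diff(g["cM"].to_numpy()) < 0).any():
                raise AnnotationFormatError(
                    f"cM positions not monotone with bp on chromosome {chrom}"
                )
        return cls(df.reset_index(drop=True), n_dropped=n_dropped)

    # -- basic queries -------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def __len__(self) -> int:
        return len(self.df)

    def chrom_frame(self, chrom: str) -> pd.DataFrame:
        try:
            return self._by_chrom[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def get(self, chrom: str, pos_bp: int) -> MarkerAnnotation | None:
        """Marker at an exact (chrom, bp) position, or None."""
        i = self._index.get((chrom, int(pos_bp)))
        if i is None:
            return None
        return self._row_to_marker(self.df.iloc[i])

    def markers(self, chrom: str | None = None):
        """Iterate markers (optionally one chromosome) in map order."""
        df = self.df if chrom is None else self.chrom_frame(chrom)
        for row in df.itertuples():
            yield MarkerAnnotation(
                row.name, row.chrom, int(row.bp), row.alleleA, row.alleleB,
                float(row.freqA), float(row.cM),
            )

    @staticmethod
    def _row_to_marker(row: pd.Series) -> MarkerAnnotation:
        return MarkerAnnotation(
            row["name"], row["chrom"], int(row["bp"]), row["alleleA"],
            row["alleleB"], float(row["freqA"]), float(row["cM"]),
        )

    # -- coordinate interconversion -----------------------------------------

    def bp_to_cm(self, chrom: str, pos_bp) -> float | np.ndarray:
        """Genetic position by linear interpolation between annotated anchors.

        Positions beyond the first/last anchor clamp to the terminal cM.
        Accepts a scalar or array of bp positions.
        """
        g = self.chrom_frame(chrom)
        # np.interp clamps beyond the ends, which is the behaviour we want
        out = np.interp(np.asarray(pos_bp, dtype=float),
                        g["bp"].to_numpy(dtype=float), g["cM"].to_numpy(dtype=float))
        return float(out) if np.ndim(pos_bp) == 0 else out

    def cm_to_bp(self, chrom: str, pos_cm) -> int | np.ndarray:
        """Physical position by inverse interpolation of the genetic map.

        Within a flat-cM run (zero-recombination segment) the left-most bp is
        returned, so annotated markers round-trip exactly; beyond the terminal
        anchors the terminal bp is returned.
        """
        g = self.chrom_frame(chrom)
        cm = g["cM"].to_numpy(dtype=float)
        bp = g["bp"].to_numpy(dtype=float)
        x = np.atleast_1d(np.asarray(pos_cm, dtype=float))
        # left-most anchor of any flat run: searchsorted(side='left')
        idx = np.searchsorted(cm, x, side="left")
        out = np.empty_like(x)
        for k, (xi, i) in enumerate(zip(x, idx)):
            if i >= len(cm):
                out[k] = bp[-1]
            elif cm[i] == xi or i == 0:
                out[k] = bp[min(i, len(bp) - 1)]
            else:
                lo, hi = i - 1, i
                frac = (xi - cm[lo]) / (cm[hi] - cm[lo])
                out[k] = bp[lo] + frac * (bp[hi] - bp[lo])
        result = np.rint(out).astype(np.int64)
        return int(result[0]) if np.ndim(pos_cm) == 0 else result


def load_annotation(path, on_duplicate: str = "error") -> MarkerMap:
    """Load the 7-column tab-separated annotation file.

    Columns (header required): ``name chrom bp alleleA alleleB freqA cM``.
    Invalid rows are dropped and counted on the returned map; duplicated
    (chrom, bp) positions raise unless ``on_duplicate='drop'``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise AnnotationFormatError(f"empty annotation file: {path}") from None
    return MarkerMap.from_frame(df, on_duplicate=on_duplicate)
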