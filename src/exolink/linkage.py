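"""Multipoint parametric linkage on small pedigrees (Lander-Green HMM).

The engine enumerates inheritance vectors — one bit per non-founder meiosis,
0 = grand-paternal allele transmitted, 1 = grand-maternal — and treats the
vector as the hidden state of an HMM along each chromosome.  Transitions
factorise over meioses: between two positions d cM apart each bit flips
independently with probability θ given by the Haldane map function.  Marker
emission probabilities sum over founder-allele assignments (each founder
allele is the A allele independently with the marker's population
frequency), and the parametric LOD at a grid position x is

    LOD(x) = log10[ Σ_v P(v | marker data, x) · P(Φ | v) / P(Φ) ]

with a uniform 2^-m prior on vectors, P(Φ | v) the phenotype likelihood
under the single-locus disease model and P(Φ) its prior mean (the unlinked
phenotype probability).  The disease locus is placed exactly at the
evaluation point.  Computation is exact for pedigrees with at most 12
meioses and 5 founders; consanguineous loops need no special treatment.

``LinkageModel`` / ``LinkageResults`` wrap the computation in a
model-fitted-to-data interface; the module-level functions expose the same
primitives directly.  ``brute_force_lod`` recomputes the LOD by explicit
summation over all inheritance-vector paths and founder assignments and
serves as an independent oracle for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import (AFFECTED, UNAFFECTED, UNKNOWN, DiseaseModel, Pedigree)

__all__ = [
    "haldane_theta", "GridSpec", "LodTrack", "MendelianError",
    "marker_likelihood", "phenotype_likelihood", "unlinked_phenotype_prob",
    "multipoint_lod", "brute_force_lod", "LinkageModel", "LinkageResults",
]


class MendelianError(ValueError):
    """Observed genotypes are impossible under the pedigree at some marker."""

    def __init__(self, marker: str, chrom: str = ""):
        self.marker = marker
        self.chrom = chrom
        super().__init__(f"Mendelian inconsistency at marker {marker!r}"
                         + (f" on {chrom}" if chrom else ""))


def haldane_theta(d_cm: float) -> float:
    """Recombination fraction θ = (1 − exp(−2d/100))/2 for a distance in cM.

    Haldane's map function: crossovers are Poisson with no interference.
    θ = 0 at zero distance and approaches 1/2 for unlinked loci.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError(f"negative genetic distance {d_cm}")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.ndim(d_cm) == 0 else theta


@dataclass(frozen=True)
class GridSpec:
    """LOD evaluation grid: evenly spaced positions spanning the markers.

    ``spacing_cm`` (default 0.3) sets the step; the grid runs from the first
    to the last marker on each chromosome, with no extrapolation beyond the
    terminal markers.  Explicit per-chromosome positions override spacing.
    """

    spacing_cm: float = 0.3
    positions: dict[str, np.ndarray] | None = None

    def for_chrom(self, chrom: str, cm_first: float, cm_last: float) -> np.ndarray:
        if self.positions is not None and chrom in self.positions:
            pos = np.asarray(self.positions[chrom], dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError("grid positions must be strictly increasing")
            return pos
        if cm_last <= cm_first:
            return np.array([cm_first])
        return np.arange(cm_first, cm_last + 1e-9, self.spacing_cm)


class LodTrack:
    """LOD scores on a cM grid, one row per (chromosome, position)."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    @property
    def max_lod(self) -> float:
        return float(self.df["LOD"].max())

    def chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["LOD"] = out["LOD"].round(4)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "LodTrack":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df[["chrom", "cM", "LOD"]])


# ---------------------------------------------------------------------------
# dense inheritance-vector machinery


class _Engine:
    """Per-pedigree arrays for vectorised likelihoods over all vectors."""

    def __init__(self, ped: Pedigree):
        ped.check_engine_limits()
        self.ped = ped
        self.m = ped.n_meioses
        self.n_slots = 2 * ped.n_founders
        self.n_vec = 1 << self.m
        self.n_assign = 1 << self.n_slots

        vecs = np.arange(self.n_vec)
        bits = ((vecs[:, None] >> np.arange(max(self.m, 1))[None, :]) & 1).astype(np.int8)

        # founder-slot index of each individual's paternal/maternal allele,
        # per inheritance vector (shape n_vec)
        pat: dict[str, np.ndarray] = {}
        mat: dict[str, np.ndarray] = {}
        for ind in ped.individuals:
            if ind.is_founder:
                s0, s1 = ped.founder_slots[ind.id]
                pat[ind.id] = np.full(self.n_vec, s0, dtype=np.int8)
                mat[ind.id] = np.full(self.n_vec, s1, dtype=np.int8)
            else:
                mp, mm = ped.meiosis_index[ind.id]
                bp = bits[:, mp]
                bm = bits[:, mm]
                pat[ind.id] = np.where(bp == 0, pat[ind.father], mat[ind.father])
                mat[ind.id] = np.where(bm == 0, pat[ind.mother], mat[ind.mother])
        self.pat, self.mat = pat, mat

        # enumerate founder-allele assignments: bit s of assignment a is the
        # allele (0 = allele A) carried by founder slot s
        assigns = np.arange(self.n_assign)
        self.F = ((assigns[:, None] >> np.arange(self.n_slots)[None, :]) & 1).astype(np.int8)
        self.popcount = self.F.sum(axis=1)
        self._geno_cache: dict[str, np.ndarray] = {}
        self._compat_cache: dict[tuple[str, int], np.ndarray] = {}
        self._lik_cache: dict[tuple, np.ndarray] = {}

    def genotype_counts(self, ind_id: str) -> np.ndarray:
        """(n_assign, n_vec) int8: copies of allele B carried, per assignment
        and inheritance vector."""
        g = self._geno_cache.get(ind_id)
        if g is None:
            g = self.F[:, self.pat[ind_id]] + self.F[:, self.mat[ind_id]]
            self._geno_cache[ind_id] = g
        return g

    def assignment_weights(self, prob_allele_b: float) -> np.ndarray:
        p1 = float(prob_allele_b)
        return p1 ** self.popcount * (1.0 - p1) ** (self.n_slots - self.popcount)

    def marker_likelihoods(self, genotypes: dict[str, int], freq_a: float) -> np.ndarray:
        """P(observed genotypes at one marker | v) for every vector v.

        ``genotypes`` maps individual id -> allele-B copy count (0/1/2);
        missing individuals simply contribute nothing.
        """
        obs = tuple(sorted(
            (ind_id, int(g)) for ind_id, g in genotypes.items()
            if g is not None and not (isinstance(g, float) and np.isnan(g))
        ))
        if not obs:
            return np.ones(self.n_vec)
        key = (float(freq_a), obs)
        lik = self._lik_cache.get(key)
        if lik is None:
            compat: np.ndarray | None = None
            for ind_id, g in obs:
                ck = (ind_id, g)
                c = self._compat_cache.get(ck)
                if c is None:
                    c = self.genotype_counts(ind_id) == g
                    self._compat_cache[ck] = c
                compat = c if compat is None else (compat & c)
            lik = self.assignment_weights(1.0 - freq_a) @ compat
            self._lik_cache[key] = lik
        return lik

    def phenotype_likelihoods(self, dm: DiseaseModel) -> np.ndarray:
        """P(Φ | v) for every vector: sum over founder disease-allele
        assignments (each slot carries the disease allele w.p. q)."""
        w = self.assignment_weights(dm.freq)
        pen = np.asarray(dm.penetrances)
        prod: np.ndarray | None = None
        for ind in self.ped.individuals:
            if ind.affection == UNKNOWN:
                continue
            copies = self.genotype_counts(ind.id)
            term = pen[copies] if ind.affection == AFFECTED else 1.0 - pen[copies]
            prod = term if prod is None else prod * term
        if prod is None:
            return np.ones(self.n_vec)
        return w @ prod


def _transport(dist: np.ndarray, theta: float, m: int) -> np.ndarray:
    """Apply the factorised transition kernel to a distribution over vectors:
    each meiosis bit flips independently with probability θ."""
    if theta == 0.0 or m == 0:
        return dist
    x = dist.reshape((2,) * m)
    for ax in range(m):
        x = (1.0 - theta) * x + theta * np.flip(x, axis=ax)
    return x.reshape(-1)


def _as_vector_index(v, m: int) -> int:
    """Inheritance vector as int (bit j = meiosis j) or bit sequence."""
    if isinstance(v, (int, np.integer)):
        iv = int(v)
    else:
        bits = list(v)
        if len(bits) != m:
            raise ValueError(f"inheritance vector length {len(bits)} != m={m}")
        iv = sum(int(b) << j for j, b in enumerate(bits))
    if not (0 <= iv < (1 << m)):
        raise ValueError(f"inheritance vector index {iv} out of range for m={m}")
    return iv


def marker_likelihood(ped: Pedigree, v, genotypes: dict[str, int], freq_a: float) -> float:
    """P(one marker's observed genotypes | inheritance vector v).

    Sums over all founder-allele assignments, each founder allele being
    allele A independently with probability ``freq_a``; typed individuals
    contribute an indicator that their induced genotype matches, missing
    genotypes contribute 1.  Incompatible data yields 0.
    """
    eng = _Engine(ped)
    return float(eng.marker_likelihoods(genotypes, freq_a)[_as_vector_index(v, eng.m)])


def phenotype_likelihood(ped: Pedigree, v, dm: DiseaseModel) -> float:
    """P(observed affection statuses | inheritance vector v) under the
    parametric disease model (disease locus at the vector's position)."""
    eng = _Engine(ped)
    return float(eng.phenotype_likelihoods(dm)[_as_vector_index(v, eng.m)])


def unlinked_phenotype_prob(ped: Pedigree, dm: DiseaseModel) -> float:
    """Prior probability P(Φ) of the phenotype configuration: the mean of
    P(Φ|v) under the uniform 2^-m vector prior."""
    eng = _Engine(ped)
    p = float(eng.phenotype_likelihoods(dm).mean())
    if p == 0.0:
        raise ValueError("phenotype configuration impossible under the disease model")
    return p


def _marker_tables(markers: pd.DataFrame, genotypes: pd.DataFrame):
    """Validate/normalise the marker and genotype tables."""
    need = {"name", "chrom", "cM", "freqA"}
    missing = need - set(markers.columns)
    if missing:
        raise ValueError(f"marker table missing columns {sorted(missing)}")
    mk = markers.copy()
    mk["chrom"] = mk["chrom"].astype(str)
    geno = genotypes.copy()
    return mk, geno


def multipoint_lod(
    ped: Pedigree,
    markers: pd.DataFrame,
    genotypes: pd.DataFrame,
    dm: DiseaseModel,
    grid: GridSpec | None = None,
) -> LodTrack:
    """Multipoint parametric LOD track over a cM grid.

    Parameters
    ----------
    markers : DataFrame with columns ``name chrom cM freqA`` (markers need
        not be pre-sorted; ties in cM are allowed and treated as θ=0).
    genotypes : DataFrame indexed by marker name, one column per typed
        individual id, entries 0/1/2 = copies of allele B, NaN = missing.
    dm : disease model (allele frequency + penetrances).
    grid : evaluation grid; default 0.3 cM spacing spanning first to last
        marker per chromosome.

    Raises
    ------
    MendelianError
        If some marker's genotypes are impossible under the pedigree.
    """
    grid = grid or GridSpec()
    mk, geno = _marker_tables(markers, genotypes)
    eng = _Engine(ped)
    phi = eng.phenotype_likelihoods(dm)
    p_phi = float(phi.mean())
    if p_phi == 0.0:
        raise ValueError("phenotype configuration impossible under the disease model")

    rows = []
    for chrom, sub in mk.groupby("chrom", sort=False):
        sub = sub.sort_values("cM", kind="mergesort")
        cms = sub["cM"].to_numpy(dtype=float)
        names = sub["name"].tolist()
        freqs = sub["freqA"].to_numpy(dtype=float)

        lks = []
        for name, fa in zip(names, freqs):
            if name in geno.index:
                obs = geno.loc[name].dropna().to_dict()
            else:
                obs = {}
            lk = eng.marker_likelihoods(obs, fa)
            if lk.max() == 0.0:
                raise MendelianError(name, chrom)
            lks.append(lk)

        n_mark = len(lks)
        # forward: alpha[k] ∝ P(v at marker k, markers 0..k)
        alpha = []
        cur = np.full(eng.n_vec, 1.0 / eng.n_vec)
        for k in range(n_mark):
            if k > 0:
                cur = _transport(cur, haldane_theta(cms[k] - cms[k - 1]), eng.m)
            cur = cur * lks[k]
            cur = cur / cur.sum()
            alpha.append(cur)
        # backward: beta[k] ∝ P(markers k..K-1 | v at marker k)
        beta = [None] * n_mark
        nxt = lks[n_mark - 1] / lks[n_mark - 1].sum()
        beta[n_mark - 1] = nxt
        for k in range(n_mark - 2, -1, -1):
            carried = _transport(beta[k + 1], haldane_theta(cms[k + 1] - cms[k]), eng.m)
            cur = lks[k] * carried
            beta[k] = cur / cur.sum()

        positions = grid.for_chrom(chrom, cms[0], cms[-1])
        left_idx = np.searchsorted(cms, positions, side="right") - 1
        for x, i in zip(positions, left_idx):
            i = max(int(i), 0)
            gamma = _transport(alpha[i], haldane_theta(max(x - cms[i], 0.0)), eng.m)
            if i + 1 < n_mark:
                right = _transport(beta[i + 1], haldane_theta(cms[i + 1] - x), eng.m)
                gamma = gamma * right
            post = gamma / gamma.sum()
            lod = np.log10(float(post @ phi) / p_phi)
            rows.append((chrom, float(x), float(lod)))

    return LodTrack(pd.DataFrame(rows, columns=["chrom", "cM", "LOD"]))


# ---------------------------------------------------------------------------
# brute-force oracle


def _slots_for_vector(ped: Pedigree, bits: dict[int, int]) -> dict[str, tuple[int, int]]:
    slots: dict[str, tuple[int, int]] = {}
    for ind in ped.individuals:
        if ind.is_founder:
            slots[ind.id] = ped.founder_slots[ind.id]
        else:
            mp, mm = ped.meiosis_index[ind.id]
            slots[ind.id] = (
                slots[ind.father][bits[mp]],
                slots[ind.mother][bits[mm]],
            )
    return slots


def _bf_marker_likelihood(ped, slots, genotypes, freq_a):
    n_slots = 2 * ped.n_founders
    total = 0.0
    for assign in itertools.product((0, 1), repeat=n_slots):
        w = 1.0
        for a in assign:
            w *= (1.0 - freq_a) if a == 1 else freq_a
        ok = True
        for ind_id, g in genotypes.items():
            if g is None or (isinstance(g, float) and np.isnan(g)):
                continue
            s0, s1 = slots[ind_id]
            if assign[s0] + assign[s1] != int(g):
                ok = False
                break
        if ok:
            total += w
    return total


def _bf_phenotype_likelihood(ped, slots, dm):
    n_slots = 2 * ped.n_founders
    total = 0.0
    for assign in itertools.product((0, 1), repeat=n_slots):
        w = 1.0
        for a in assign:
            w *= dm.freq if a == 1 else (1.0 - dm.freq)
        lik = 1.0
        for ind in ped.individuals:
            if ind.affection == UNKNOWN:
                continue
            s0, s1 = slots[ind.id]
            pen = dm.penetrances[assign[s0] + assign[s1]]
            lik *= pen if ind.affection == AFFECTED else (1.0 - pen)
        total += w * lik
    return total


def brute_force_lod(
    ped: Pedigree,
    markers: pd.DataFrame,
    genotypes: pd.DataFrame,
    dm: DiseaseModel,
    grid: GridSpec | None = None,
) -> LodTrack:
    """LOD track by explicit summation over all inheritance-vector paths.

    Independent oracle for :func:`multipoint_lod`: descent is re-derived per
    vector by walking the pedigree, founder assignments are enumerated
    explicitly, and the path sum uses dense transition matrices built from
    pairwise bit differences.  Refuses instances beyond 6 meioses or 3
    markers per chromosome.
    """
    ped.check_engine_limits()
    m = ped.n_meioses
    if m > 6:
        raise ValueError(f"brute-force oracle limited to m<=6 (got {m})")
    grid = grid or GridSpec()
    mk, geno = _marker_tables(markers, genotypes)

    n_vec = 1 << m
    vecs = np.arange(n_vec)
    ham = np.zeros((n_vec, n_vec), dtype=int)
    for a in range(n_vec):
        for b in range(n_vec):
            ham[a, b] = bin(a ^ b).count("1")

    slot_maps = []
    for v in range(n_vec):
        bits = {j: (v >> j) & 1 for j in range(m)}
        slot_maps.append(_slots_for_vector(ped, bits))

    phi = np.array([_bf_phenotype_likelihood(ped, s, dm) for s in slot_maps])
    p_phi = phi.mean()
    if p_phi == 0.0:
        raise ValueError("phenotype configuration impossible under the disease model")

    def tmat(d_cm: float) -> np.ndarray:
        th = haldane_theta(d_cm)
        if th == 0.0:
            return np.eye(n_vec)
        return th ** ham * (1.0 - th) ** (m - ham)

    rows = []
    letters = "abcdefgh"
    for chrom, sub in mk.groupby("chrom", sort=False):
        sub = sub.sort_values("cM", kind="mergesort")
        if len(sub) > 3:
            raise ValueError("brute-force oracle limited to <=3 markers per chromosome")
        cms = sub["cM"].to_numpy(dtype=float)
        lks = []
        for row in sub.itertuples():
            obs = geno.loc[row.name].dropna().to_dict() if row.name in geno.index else {}
            lks.append(np.array([
                _bf_marker_likelihood(ped, s, obs, float(row.freqA)) for s in slot_maps
            ]))

        positions = grid.for_chrom(chrom, cms[0], cms[-1])
        for x in positions:
            # ordered chain of positions with the grid point inserted
            chain: list[tuple[float, np.ndarray | None]] = [
                (c, lk) for c, lk in zip(cms, lks)
            ]
            chain.append((float(x), None))
            chain.sort(key=lambda t: (t[0], t[1] is None))
            ops, script = [], []
            x_letter = None
            prior = np.full(n_vec, 1.0 / n_vec)
            for k, (pos, lk) in enumerate(chain):
                lt = letters[k]
                if k == 0:
                    ops.append(prior)
                    script.append(lt)
                else:
                    ops.append(tmat(pos - chain[k - 1][0]))
                    script.append(letters[k - 1] + lt)
                if lk is None:
                    x_letter = lt
                else:
                    ops.append(lk)
                    script.append(lt)
            marg = np.einsum(",".join(script) + "->" + x_letter, *ops)
            post = marg / marg.sum()
            rows.append((chrom, float(x), float(np.log10(post @ phi / p_phi))))

    return LodTrack(pd.DataFrame(rows, columns=["chrom", "cM", "LOD"]))


# ---------------------------------------------------------------------------
# model / results interface


class LinkageModel:
    """Parametric multipoint linkage model for one family.

    Binds a pedigree, a marker table (name/chrom/cM/freqA, optionally bp), a
    genotype matrix and a disease model; :meth:`fit` runs the inheritance-
    vector HMM and returns a :class:`LinkageResults`.

    Examples
    --------
    >>> model = LinkageModel(ped, markers, genotypes, DiseaseModel.recessive())
    >>> res = model.fit(grid_cm=0.3)
    >>> res.max_lod
    """

    def __init__(self, pedigree: Pedigree, markers: pd.DataFrame,
                 genotypes: pd.DataFrame, disease_model: DiseaseModel):
        pedigree.check_engine_limits()
        self.pedigree = pedigree
        self.markers = markers
        self.genotypes = genotypes
        self.disease_model = disease_model

    @classmethod
    def from_linkage_files(cls, prefix: str, disease_model: DiseaseModel) -> "LinkageModel":
        """Build from a MERLIN-style ped/dat/map/freq file set."""
        from .markerselect import read_linkage_files
        ped, markers, genotypes = read_linkage_files(prefix)
        return cls(ped, markers, genotypes, disease_model)

    def fit(self, grid_cm: float = 0.3, grid: GridSpec | None = None) -> "LinkageResults":
        grid = grid or GridSpec(spacing_cm=grid_cm)
        track = multipoint_lod(self.pedigree, self.markers, self.genotypes,
                               self.disease_model, grid)
        return LinkageResults(self, track)


class LinkageResults:
    """Fitted LOD track plus derived quantities (max LOD, peaks, summary)."""

    def __init__(self, model: LinkageModel, track: LodTrack):
        self.model = model
        self.track = track

    @property
    def max_lod(self) -> float:
        return self.track.max_lod

    def peaks(self, flank_cm: float = 0.3, tol: float = 1e-4, marker_map=None):
        """Linkage-peak intervals: maximal runs attaining the genome-wide
        maximum LOD, extended by ``flank_cm`` on either side."""
        from .peakfilter import find_peaks
        mm = marker_map
        if mm is None and "bp" in self.model.markers.columns:
            mm = _map_from_marker_table(self.model.markers)
        return find_peaks(self.track, flank_cm=flank_cm, tol=tol, marker_map=mm)

    def summary(self) -> str:
        ped = self.model.pedigree
        dm = self.model.disease_model
        df = self.track.df
        imax = df["LOD"].idxmax()
        lines = [
            "Multipoint parametric linkage",
            "=" * 46,
            f"Family:            {ped.family_id} ({len(ped)} individuals, "
            f"f={ped.n_founders}, m={ped.n_meioses})",
            f"Typed individuals: {', '.join(ped.typed_ids) or 'none'}",
            f"Disease model:     {dm.mode or 'custom'} q={dm.freq:g} "
            f"penetrances={dm.penetrances}",
            f"Markers:           {len(self.model.markers)}",
            f"Grid positions:    {len(df)} on "
            f"{df['chrom'].nunique()} chromosome(s)",
            f"Max LOD:           {self.max_lod:.4f} at "
            f"{df.loc[imax, 'chrom']}:{df.loc[imax, 'cM']:.2f} cM",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """LOD track per chromosome (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        for chrom in self.track.df["chrom"].unique():
            sub = self.track.chrom(chrom)
            ax.plot(sub["cM"] + offset, sub["LOD"], label=str(chrom))
            offset += sub["cM"].max() + 5.0
        ax.set_xlabel("position (cM, chromosomes concatenated)")
        ax.set_ylabel("LOD")
        ax.axhline(0, color="grey", lw=0.5)
        return ax


def _map_from_marker_table(markers: pd.DataFrame):
    """Minimal bp<->cM interpolator built from a marker table with bp."""
    from .markermap import MarkerMap
    df = pd.DataFrame({
        "name": markers["name"],
        "chrom": markers["chrom"].astype(str),
        "bp": markers["bp"],
        "alleleA": "A",
        "alleleB": "C",
        "freqA": markers["freqA"],
        "cM": markers["cM"],
    })
    return MarkerMap.from_frame(df)
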