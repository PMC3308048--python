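"""Pedigree graph and parametric disease model.

The linkage engine enumerates inheritance vectors, one bit per non-founder
meiosis, so pedigree size is capped at 12 meioses (4096 vectors) and 5
founders (1024 founder-allele assignments).  Consanguineous loops are allowed
— they need no special handling because meiosis indicators encode descent
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MAX_MEIOSES = 12
MAX_FOUNDERS = 5

UNKNOWN, UNAFFECTED, AFFECTED = 0, 1, 2  # linkage-file affection coding


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None = None
    mother: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    affection: int = UNKNOWN
    typed: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass(frozen=True)
class DiseaseModel:
    """Single-locus parametric model: allele frequency and penetrances.

    ``penetrances[g]`` is the probability of being affected given g copies of
    the disease allele.  Fully penetrant recessive = (0, 0, 1), fully
    penetrant dominant = (0, 1, 1).
    """

    freq: float
    penetrances: tuple[float, float, float]
    mode: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.freq < 1.0):
            raise ValueError(f"disease allele frequency {self.freq} outside (0,1)")
        if any(not (0.0 <= f <= 1.0) for f in self.penetrances):
            raise ValueError(f"penetrances {self.penetrances} outside [0,1]")

    @classmethod
    def recessive(cls, freq: float = 1e-5) -> "DiseaseModel":
        return cls(freq, (0.0, 0.0, 1.0), "recessive")

    @classmethod
    def dominant(cls, freq: float = 1e-5) -> "DiseaseModel":
        return cls(freq, (0.0, 1.0, 1.0), "dominant")


class PedigreeError(ValueError):
    pass


class Pedigree:
    """A family: individuals with parent links, sex, affection, typed flag.

    Individuals are re-ordered topologically (parents before children) at
    construction; cyclic parentage or a missing/half-specified parent pair is
    rejected.  Founder allele *slots* are numbered 0..2f-1 (two per founder,
    paternal slot first); meioses are numbered 0..m-1, two per non-founder in
    topological order (paternal meiosis first).
    """

    def __init__(self, individuals: list[Individual], family_id: str = "FAM1"):
        self.family_id = family_id
        by_id = {}
        for ind in individuals:
            if ind.id in by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(f"{ind.id}: both or neither parent must be given")
            by_id[ind.id] = ind
        for ind in individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in by_id:
                    raise PedigreeError(f"{ind.id}: unknown parent {parent!r}")

        # topological sort (Kahn); detects cycles
        order: list[Individual] = []
        placed: set[str] = set()
        pending = list(individuals)
        while pending:
            progressed = False
            remaining = []
            for ind in pending:
                if ind.is_founder or (ind.father in placed and ind.mother in placed):
                    order.append(ind)
                    placed.add(ind.id)
                    progressed = True
                else:
                    remaining.append(ind)
            if not progressed:
                raise PedigreeError("cyclic parentage")
            pending = remaining

        self.individuals = order
        self.by_id = {ind.id: ind for ind in order}
        self.founders = [ind for ind in order if ind.is_founder]
        self.nonfounders = [ind for ind in order if not ind.is_founder]

        self.founder_slots: dict[str, tuple[int, int]] = {
            ind.id: (2 * k, 2 * k + 1) for k, ind in enumerate(self.founders)
        }
        # meiosis 2j = paternal, 2j+1 = maternal for the j-th non-founder
        self.meiosis_index: dict[str, tuple[int, int]] = {
            ind.id: (2 * j, 2 * j + 1) for j, ind in enumerate(self.nonfounders)
        }

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    @property
    def n_meioses(self) -> int:
        return 2 * len(self.nonfounders)

    def check_engine_limits(self) -> None:
        if self.n_meioses > MAX_MEIOSES:
            raise PedigreeError(
                f"{self.n_meioses} meioses exceeds engine limit {MAX_MEIOSES}"
            )
        if self.n_founders > MAX_FOUNDERS:
            raise PedigreeError(
                f"{self.n_founders} founders exceeds engine limit {MAX_FOUNDERS}"
            )

    @property
    def typed_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals if ind.typed]

    def __len__(self) -> int:
        return len(self.individuals)

    def __repr__(self) -> str:
        return (
            f"<Pedigree {self.family_id}: {len(self)} individuals, "
            f"f={self.n_founders}, m={self.n_meioses}>"
        )
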