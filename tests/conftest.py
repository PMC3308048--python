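import numpy as np
import pandas as pd
import pytest

from exolink.markermap import MarkerMap
from exolink.pedigree import AFFECTED, Individual, Pedigree


def annotation_frame():
    """Six markers on two chromosomes, one ambiguous (A/T) pair."""
    return pd.DataFrame({
        "name": ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"],
        "chrom": ["1", "1", "1", "1", "2", "2"],
        "bp": [100, 200, 300, 400, 100, 250],
        "alleleA": ["A", "C", "A", "G", "C", "A"],
        "alleleB": ["C", "T", "T", "A", "G", "G"],
        "freqA": [0.5, 0.2, 0.4, 0.9, 0.5, 0.3],
        "cM": [1.0, 2.0, 2.0, 4.0, 0.5, 1.5],
    })


@pytest.fixture
def annotation_df():
    return annotation_frame()


@pytest.fixture
def marker_map(annotation_df):
    return MarkerMap.from_frame(annotation_df)


@pytest.fixture
def annotation_file(tmp_path, annotation_df):
    path = tmp_path / "annot.tsv"
    annotation_df.to_csv(path, sep="\t", index=False)
    return path


def sib_pair_pedigree(affected=True):
    """Outbred nuclear family, two typed children (f=2, m=4)."""
    aff = AFFECTED if affected else 0
    return Pedigree([
        Individual("FA", sex=1), Individual("MO", sex=2),
        Individual("K1", "FA", "MO", sex=1, affection=aff, typed=True),
        Individual("K2", "FA", "MO", sex=2, affection=aff, typed=True),
    ])


def trio_pedigree():
    return Pedigree([
        Individual("FA", sex=1, typed=True), Individual("MO", sex=2, typed=True),
        Individual("K1", "FA", "MO", sex=1, affection=AFFECTED, typed=True),
    ])


def three_sib_pedigree():
    """f=2, m=6: the largest family the brute-force oracle accepts."""
    return Pedigree([
        Individual("FA", sex=1), Individual("MO", sex=2),
        Individual("K1", "FA", "MO", sex=1, affection=AFFECTED, typed=True),
        Individual("K2", "FA", "MO", sex=2, affection=AFFECTED, typed=True),
        Individual("K3", "FA", "MO", sex=1, typed=True),
    ])


def random_small_instance(rng: np.random.Generator):
    """A random pedigree/markers/genotypes/model instance small enough for
    the brute-force oracle (m <= 6, <= 3 markers)."""
    from exolink.pedigree import DiseaseModel
    from exolink.pedsim import SimConfig, gene_drop

    ped = [sib_pair_pedigree(), trio_pedigree(), three_sib_pedigree()][int(rng.integers(3))]
    n_mark = int(rng.integers(1, 4))
    cms = np.sort(rng.uniform(0.0, 20.0, size=n_mark))
    markers = pd.DataFrame({
        "name": [f"m{i}" for i in range(n_mark)],
        "chrom": "1",
        "bp": (1000 + cms * 1000).astype(int) + np.arange(n_mark),
        "alleleA": "A", "alleleB": "C",
        "freqA": rng.uniform(0.1, 0.9, size=n_mark),
        "cM": cms,
    })
    if rng.random() < 0.5:
        dm = DiseaseModel.recessive(10.0 ** rng.uniform(-5, -1))
    else:
        dm = DiseaseModel.dominant(10.0 ** rng.uniform(-5, -1))
    cfg = SimConfig(condition_on_phenotype=False, seed=int(rng.integers(2**31)))
    _, obs = gene_drop(ped, markers, dm, cfg, rng=rng)
    # random missingness
    mask = rng.random(obs.shape) < 0.2
    obs = obs.mask(mask)
    grid_positions = np.sort(rng.uniform(cms[0], max(cms[-1], cms[0] + 1e-6),
                                         size=int(rng.integers(1, 4))))
    grid_positions = np.unique(grid_positions)
    return ped, markers, obs, dm, grid_positions
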