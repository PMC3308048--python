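import numpy as np
import pandas as pd
import pytest

from exolink import linkage as lk
from exolink import pedsim
from exolink.linkage import GridSpec, LinkageModel
from exolink.pedigree import (AFFECTED, DiseaseModel, Individual, Pedigree,
                              PedigreeError)

from conftest import random_small_instance, sib_pair_pedigree, trio_pedigree


def _vector_of(ped, template_pattern, seed=0):
    """An inheritance vector realising a conditioning pattern at one site."""
    bits, _, slot, _ = pedsim._sample_descent(
        ped, np.array([0.0]), np.random.default_rng(seed), True,
        template_pattern, 10_000)
    return sum(int(b) << j for j, b in enumerate(bits[:, 0])), slot


class TestHaldane:
    def test_values(self):
        assert lk.haldane_theta(0.0) == 0.0
        assert lk.haldane_theta(0.3) == pytest.approx(0.00299102, abs=1e-7)
        assert lk.haldane_theta(1e6) == pytest.approx(0.5)

    def test_negative_distance(self):
        with pytest.raises(ValueError):
            lk.haldane_theta(-1.0)


class TestMarkerLikelihood:
    def test_unrelated_homozygote_is_p_squared(self):
        ped = Pedigree([Individual("X", typed=True)])
        assert lk.marker_likelihood(ped, 0, {"X": 0}, 0.3) == pytest.approx(0.09)
        assert lk.marker_likelihood(ped, 0, {"X": 2}, 0.3) == pytest.approx(0.49)
        assert lk.marker_likelihood(ped, 0, {"X": 1}, 0.3) == pytest.approx(2 * 0.3 * 0.7)

    def test_autozygous_homozygote_is_p(self):
        ped = pedsim.make_pedigree_fixture("firstcousin_offspring")
        v, _ = _vector_of(ped, "autozygous")
        assert lk.marker_likelihood(ped, v, {"CH": 0}, 0.3) == pytest.approx(0.3)

    def test_autozygous_heterozygote_impossible(self):
        ped = pedsim.make_pedigree_fixture("firstcousin_offspring")
        v, _ = _vector_of(ped, "autozygous")
        assert lk.marker_likelihood(ped, v, {"CH": 1}, 0.3) == 0.0

    def test_missing_genotypes_contribute_one(self):
        ped = sib_pair_pedigree()
        assert lk.marker_likelihood(ped, 5, {}, 0.3) == 1.0


class TestPhenotypeLikelihood:
    def test_outbred_affected_recessive_is_q_squared(self):
        ped = Pedigree([Individual("X", affection=AFFECTED, typed=True)])
        dm = DiseaseModel.recessive(1e-5)
        for v in [0]:
            assert lk.phenotype_likelihood(ped, v, dm) == pytest.approx(1e-10)

    def test_autozygous_affected_recessive_near_q(self):
        ped = pedsim.make_pedigree_fixture("firstcousin_offspring")
        v, _ = _vector_of(ped, "autozygous")
        q = 1e-5
        got = lk.phenotype_likelihood(ped, v, DiseaseModel.recessive(q))
        # exactly q + (terms of order q^2) by enumeration
        assert got == pytest.approx(q, rel=1e-3)

    def test_zero_penetrance_means_impossible_affected(self):
        ped = Pedigree([Individual("X", affection=AFFECTED, typed=True)])
        dm = DiseaseModel(1e-3, (0.0, 0.0, 0.0))
        assert lk.phenotype_likelihood(ped, 0, dm) == 0.0

    def test_all_unknown_phenotypes_give_one(self):
        ped = Pedigree([Individual("FA", sex=1), Individual("MO", sex=2),
                        Individual("K", "FA", "MO", typed=True)])
        assert lk.phenotype_likelihood(ped, 0, DiseaseModel.recessive()) == 1.0
        assert lk.unlinked_phenotype_prob(ped, DiseaseModel.recessive()) == 1.0


class TestUnlinkedPhenotypeProb:
    def test_first_cousin_offspring_inbreeding_coefficient(self):
        """P(affected)/q -> F = 1/16 as q -> 0 for a first-cousin child
        under a fully penetrant recessive model."""
        ped = pedsim.make_pedigree_fixture("firstcousin_offspring")
        q = 1e-5
        p_phi = lk.unlinked_phenotype_prob(ped, DiseaseModel.recessive(q))
        assert p_phi / q == pytest.approx(1 / 16, rel=2e-3)

    def test_first_cousin_once_removed_is_one_thirtysecond(self):
        ped = pedsim.make_pedigree_fixture("firstcousin_once_removed_offspring")
        q = 1e-5
        p_phi = lk.unlinked_phenotype_prob(ped, DiseaseModel.recessive(q))
        assert p_phi / q == pytest.approx(1 / 32, rel=2e-3)

    def test_outbred_singleton_q_squared(self):
        ped = Pedigree([Individual("X", affection=AFFECTED, typed=True)])
        assert lk.unlinked_phenotype_prob(ped, DiseaseModel.recessive(1e-3)) \
            == pytest.approx(1e-6)


def _uninformative_markers(n=3):
    return pd.DataFrame({
        "name": [f"m{i}" for i in range(n)], "chrom": "1",
        "bp": 1000 + np.arange(n), "alleleA": "A", "alleleB": "C",
        "freqA": 0.4, "cM": np.arange(n, dtype=float),
    })


class TestMultipointLod:
    def test_all_missing_genotypes_give_zero_track(self):
        ped = sib_pair_pedigree()
        mk = _uninformative_markers()
        geno = pd.DataFrame(np.nan, index=mk["name"], columns=["K1", "K2"])
        track = lk.multipoint_lod(ped, mk, geno, DiseaseModel.dominant())
        assert np.allclose(track.df["LOD"], 0.0, atol=1e-12)

    def test_all_phenotypes_unknown_give_zero_track(self):
        ped = Pedigree([Individual("FA", sex=1), Individual("MO", sex=2),
                        Individual("K1", "FA", "MO", typed=True)])
        mk = _uninformative_markers()
        geno = pd.DataFrame({"K1": [0.0, 1.0, 2.0]}, index=mk["name"])
        track = lk.multipoint_lod(ped, mk, geno, DiseaseModel.recessive())
        assert np.allclose(track.df["LOD"], 0.0, atol=1e-12)

    def test_mendelian_error_reported_with_marker_name(self):
        ped = trio_pedigree()
        mk = _uninformative_markers(2)
        geno = pd.DataFrame({"FA": [0.0, 0.0], "MO": [0.0, 0.0],
                             "K1": [0.0, 2.0]}, index=mk["name"])
        with pytest.raises(lk.MendelianError, match="m1"):
            lk.multipoint_lod(ped, mk, geno, DiseaseModel.recessive())

    def test_lod_bounded_by_unlinked_phenotype_prob(self):
        ped = pedsim.make_pedigree_fixture("firstcousin_offspring")
        fi = pedsim.fully_informative_markers(ped, n_blocks=20, seed=5)
        dm = DiseaseModel.recessive()
        track = lk.multipoint_lod(ped, fi.markers, fi.genotypes, dm)
        bound = np.log10(1.0 / lk.unlinked_phenotype_prob(ped, dm))
        assert (track.df["LOD"] <= bound + 1e-9).all()

    def test_map_mirror_symmetry(self):
        """Reversing the genetic map mirrors the LOD track (forward and
        backward passes are equivalent)."""
        ped = sib_pair_pedigree()
        rng = np.random.default_rng(2)
        mk = _uninformative_markers(3)
        mk["freqA"] = [0.2, 0.5, 0.7]
        cfg = pedsim.SimConfig(condition_on_phenotype=False, seed=8)
        _, geno = pedsim.gene_drop(ped, mk, DiseaseModel.dominant(), cfg)
        grid = GridSpec(positions={"1": np.array([0.0, 0.7, 1.3, 2.0])})
        fwd = lk.multipoint_lod(ped, mk, geno, DiseaseModel.dominant(), grid)
        L = mk["cM"].max()
        mk_rev = mk.copy()
        mk_rev["cM"] = L - mk_rev["cM"].to_numpy()
        grid_rev = GridSpec(positions={"1": np.sort(L - np.array([0.0, 0.7, 1.3, 2.0]))})
        rev = lk.multipoint_lod(ped, mk_rev, geno, DiseaseModel.dominant(), grid_rev)
        assert np.allclose(fwd.df["LOD"].to_numpy(),
                           rev.df["LOD"].to_numpy()[::-1], atol=1e-9)


class TestTransportKernel:
    def test_theta_zero_is_identity(self):
        rng = np.random.default_rng(0)
        d = rng.random(16)
        assert np.array_equal(lk._transport(d, 0.0, 4), d)

    def test_theta_half_decouples(self):
        """At theta = 1/2 the transported distribution is uniform: the
        posterior at a position then depends only on local data."""
        rng = np.random.default_rng(1)
        d = rng.random(16)
        out = lk._transport(d, 0.5, 4)
        assert np.allclose(out, d.sum() / 16)

    def test_mass_conserved(self):
        rng = np.random.default_rng(2)
        d = rng.random(64)
        out = lk._transport(d, 0.123, 6)
        assert out.sum() == pytest.approx(d.sum())
        assert (out >= 0).all()


class TestBruteForceOracle:
    def test_refuses_large_instances(self):
        ped = pedsim.make_pedigree_fixture("firstcousin_offspring")  # m=10
        mk = _uninformative_markers(1)
        geno = pd.DataFrame({"CH": [0.0]}, index=mk["name"])
        with pytest.raises(ValueError, match="m<=6"):
            lk.brute_force_lod(ped, mk, geno, DiseaseModel.recessive())

    def test_matches_engine_on_random_instances(self):
        """Dense HMM engine equals explicit path summation to 1e-9 on
        random small pedigree/marker/genotype instances."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            ped, mk, geno, dm, pos = random_small_instance(rng)
            grid = GridSpec(positions={"1": pos})
            a = lk.multipoint_lod(ped, mk, geno, dm, grid).df["LOD"].to_numpy()
            b = lk.brute_force_lod(ped, mk, geno, dm, grid).df["LOD"].to_numpy()
            assert np.max(np.abs(a - b)) < 1e-9


class TestAnalyticCeilings:
    """Fully informative markers drive the maximum LOD to the pedigree's
    analytic ceiling: log10(1/F) for autozygosity designs, log10 2 for the
    affected-parent sib pair."""

    @pytest.mark.parametrize("template,dm,ceiling", [
        ("firstcousin_offspring", DiseaseModel.recessive(), np.log10(16)),
        ("firstcousin_once_removed_offspring", DiseaseModel.recessive(), np.log10(32)),
        ("dominant_sibpair", DiseaseModel.dominant(), np.log10(2)),
    ])
    def test_max_lod_hits_ceiling(self, template, dm, ceiling):
        ped = pedsim.make_pedigree_fixture(template)
        fi = pedsim.fully_informative_markers(ped, n_blocks=40, seed=13)
        res = LinkageModel(ped, fi.markers, fi.genotypes, dm).fit()
        assert res.max_lod == pytest.approx(ceiling, abs=0.01)


class TestModelResults:
    def test_summary_and_track(self):
        ped = pedsim.make_pedigree_fixture("dominant_sibpair")
        fi = pedsim.fully_informative_markers(ped, n_blocks=10, seed=1)
        res = LinkageModel(ped, fi.markers, fi.genotypes, DiseaseModel.dominant()).fit()
        text = res.summary()
        assert "Max LOD" in text and "dominant" in text
        assert len(res.track) > 0

    def test_track_tsv_round_trip(self, tmp_path):
        ped = pedsim.make_pedigree_fixture("dominant_sibpair")
        fi = pedsim.fully_informative_markers(ped, n_blocks=5, seed=1)
        res = LinkageModel(ped, fi.markers, fi.genotypes, DiseaseModel.dominant()).fit()
        path = tmp_path / "t.tsv"
        res.track.to_tsv(path)
        back = lk.LodTrack.read_tsv(path)
        assert np.allclose(back.df["LOD"], res.track.df["LOD"].round(4))

    def test_engine_limits_enforced(self):
        inds = [Individual(f"F{i}", sex=1 + i % 2) for i in range(6)]
        with pytest.raises(PedigreeError, match="founders"):
            Pedigree(inds).check_engine_limits()
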