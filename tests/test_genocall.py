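import math

import numpy as np
import pandas as pd
import pytest

from exolink import genocall as gc
from exolink import pedsim
from exolink.markermap import MarkerMap
from exolink.pedigree import DiseaseModel

Q20 = [("A", 20, 60)]


def pile(reads):
    return gc.SitePileup("1", 100, tuple(reads))


def expected_likelihoods(bases, quals, alleles):
    """Independent oracle: direct arithmetic over the emission model."""
    laa = lab = lbb = 1.0
    for b, q in zip(bases, quals):
        e = 10 ** (-q / 10)
        paa = (1 - e) if b == alleles[0] else e / 3
        pbb = (1 - e) if b == alleles[1] else e / 3
        laa *= paa
        lbb *= pbb
        lab *= 0.5 * (paa + pbb)
    return laa, lab, lbb


class TestAmbiguity:
    @pytest.mark.parametrize("a,b,amb", [
        ("A", "T", True), ("C", "G", True), ("G", "C", True),
        ("A", "C", False), ("G", "T", False),
    ])
    def test_pairs(self, a, b, amb):
        assert gc.is_ambiguous(a, b) is amb

    def test_non_nucleotide(self):
        with pytest.raises(ValueError):
            gc.is_ambiguous("A", "N")


class TestLikelihoods:
    def test_five_ref_reads_q20(self):
        sl = gc.genotype_likelihoods(pile([("A", 20, 60)] * 5), ("A", "C"))
        exp = expected_likelihoods("AAAAA", [20] * 5, ("A", "C"))
        assert sl.depth == 5
        assert sl.likelihoods == pytest.approx(exp, rel=1e-12)
        assert sl.likelihoods[0] == pytest.approx(0.99 ** 5)

    def test_zero_reads_missing(self):
        sl = gc.genotype_likelihoods(pile([]), ("A", "C"))
        assert sl.likelihoods is None and sl.depth == 0

    def test_third_allele_reads_discarded(self):
        sl = gc.genotype_likelihoods(pile([("G", 30, 60)] * 4), ("A", "C"))
        assert sl.likelihoods is None
        assert sl.n_discarded == 4

    def test_quality_filters(self):
        reads = [("A", 12, 60), ("A", 20, 10), ("A", 20, 60)]
        sl = gc.genotype_likelihoods(pile(reads), ("A", "C"))
        assert sl.depth == 1


class TestCallGenotype:
    def test_hom_call_from_ref_reads(self):
        sl = gc.genotype_likelihoods(pile([("A", 20, 60)] * 5), ("A", "C"))
        call = gc.call_genotype(sl, gc.CallerConfig(t=0.5))
        assert call.genotype == "AA"
        assert sum(call.posteriors) == pytest.approx(1.0, abs=1e-12)

    def test_het_call_from_mixed_reads(self):
        sl = gc.genotype_likelihoods(
            pile([("A", 20, 60)] * 3 + [("C", 20, 60)] * 2), ("A", "C"))
        assert gc.call_genotype(sl, gc.CallerConfig(t=0.5)).genotype == "AB"

    def test_low_depth_missing(self):
        sl = gc.genotype_likelihoods(pile([("A", 20, 60)] * 4), ("A", "C"))
        assert gc.call_genotype(sl, gc.CallerConfig(min_depth=5)).is_missing

    def test_t_zero_never_het(self):
        sl = gc.genotype_likelihoods(
            pile([("A", 30, 60)] * 10 + [("C", 30, 60)] * 10), ("A", "C"))
        call = gc.call_genotype(sl, gc.CallerConfig(t=0.0))
        assert call.genotype != "AB"

    def test_haploid_never_het(self):
        sl = gc.genotype_likelihoods(
            pile([("A", 30, 60)] * 10 + [("C", 30, 60)] * 10), ("A", "C"))
        call = gc.call_genotype(sl, gc.CallerConfig(), ploidy="haploid")
        assert call.genotype != "AB"

    def test_posterior_het_monotone_in_t(self):
        sl = gc.genotype_likelihoods(
            pile([("A", 20, 60)] * 6 + [("C", 20, 60)] * 2), ("A", "C"))
        last = -1.0
        for t in [0.001, 0.01, 0.1, 0.3, 0.5, 0.8]:
            call = gc.call_genotype(sl, gc.CallerConfig(t=t))
            assert call.posteriors[1] >= last
            last = call.posteriors[1]

    def test_symmetric_evidence_tie_refused(self):
        sl = gc.genotype_likelihoods(
            pile([("A", 20, 60), ("C", 20, 60)]), ("A", "C"))
        assert gc.call_genotype(sl, gc.CallerConfig(t=0.0, min_depth=1)).is_missing


class TestVcfExtraction:
    def _write_vcf(self, tmp_path, body):
        path = tmp_path / "s.vcf"
        header = ("##fileformat=VCFv4.2\n"
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
                  '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
                  "##contig=<ID=1>\n##contig=<ID=2>\n"
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n")
        path.write_text(header + body)
        return path

    def test_matching_site_extracted(self, tmp_path, marker_map):
        vcf = self._write_vcf(tmp_path, "1\t100\t.\tA\tC\t50\tPASS\t.\tGT:DP\t0/1:10\n")
        calls, stats = gc.extract_genotypes_from_vcf(vcf, marker_map)
        by = {c.marker: c for c in calls}
        assert by["rs1"].genotype == "AB"
        assert by["rs1"].depth == 10
        assert stats.n_called == 1

    def test_allele_mismatch_dropped(self, tmp_path, marker_map):
        vcf = self._write_vcf(tmp_path, "1\t100\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:10\n")
        calls, stats = gc.extract_genotypes_from_vcf(vcf, marker_map)
        assert stats.n_allele_mismatch == 1
        assert {c.marker: c for c in calls}["rs1"].is_missing

    def test_indel_dropped(self, tmp_path, marker_map):
        vcf = self._write_vcf(tmp_path, "1\t100\t.\tA\tAC\t50\tPASS\t.\tGT:DP\t0/1:10\n")
        _, stats = gc.extract_genotypes_from_vcf(vcf, marker_map)
        assert stats.n_indel_dropped == 1

    def test_low_depth_missing_and_ambiguous_excluded(self, tmp_path, marker_map):
        body = ("1\t100\t.\tA\tC\t50\tPASS\t.\tGT:DP\t1/1:3\n"
                "1\t300\t.\tA\tT\t50\tPASS\t.\tGT:DP\t0/1:30\n")
        calls, stats = gc.extract_genotypes_from_vcf(vcf_path := self._write_vcf(tmp_path, body), marker_map)
        by = {c.marker: c for c in calls}
        assert by["rs1"].is_missing          # DP 3 < 5
        assert "rs3" not in by               # A/T ambiguous, dropped
        assert stats.n_ambiguous_dropped == 1

    def test_swapped_ref_alt_orientation(self, tmp_path, marker_map):
        # rs6 annotated (A, G); VCF REF=G ALT=A hom-ref -> BB in A/B space
        vcf = self._write_vcf(tmp_path, "2\t250\t.\tG\tA\t50\tPASS\t.\tGT:DP\t0/0:20\n")
        calls, _ = gc.extract_genotypes_from_vcf(vcf, marker_map)
        assert {c.marker: c for c in calls}["rs6"].genotype == "BB"


class TestConcordance:
    def _calls(self, genos, sample="X"):
        return [gc.GenotypeCall(m, sample, g) for m, g in genos.items()]

    def test_identical_sets(self):
        a = self._calls({f"m{i}": "AA" for i in range(100)})
        rep = gc.concordance(a, self._calls({f"m{i}": "AA" for i in range(100)}, "Y"))
        assert rep.concordance == 1.0 and rep.n_compared == 100

    def test_three_of_four(self):
        x = self._calls({"a": "AA", "b": "AB", "c": "BB", "d": "AA"})
        y = self._calls({"a": "AA", "b": "AB", "c": "BB", "d": "BB"}, "Y")
        rep = gc.concordance(x, y)
        assert rep.concordance == 0.75

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError):
            gc.concordance(self._calls({"a": "AA"}), self._calls({"b": "AA"}, "Y"))

    def test_ambiguous_markers_excluded_with_map(self, marker_map):
        x = self._calls({"rs1": "AA", "rs3": "AB"})
        y = self._calls({"rs1": "AA", "rs3": "BB"}, "Y")
        rep = gc.concordance(x, y, marker_map, drop_ambiguous=True)
        assert rep.n_compared == 1 and rep.concordance == 1.0
        rep2 = gc.concordance(x, y, marker_map, drop_ambiguous=False)
        assert rep2.n_compared == 2
        assert rep2.by_class["ambiguous"] == (1, 0)


def _simulated_truth_and_pileups(n_sites, seed, depth_mean=20.0, base_q=30):
    rng = np.random.default_rng(seed)
    markers = pedsim.synthetic_marker_table(n_sites, 0.05, "1", rng,
                                            freq_low=0.2, freq_high=0.5)
    truth_g = pd.DataFrame(
        {"S": rng.binomial(2, 1.0 - markers["freqA"]).astype(float)},
        index=pd.Index(markers["name"], name="marker"))
    cfg = pedsim.SimConfig(depth_mean=depth_mean, base_quality=base_q, seed=seed)
    piles = pedsim.simulate_pileups(markers, truth_g, cfg, rng)["S"]
    mm = MarkerMap.from_frame(markers)
    truth_calls = [gc.GenotypeCall(m, "S", ["AA", "AB", "BB"][int(g)])
                   for m, g in truth_g["S"].items()]
    return mm, piles, truth_calls


class TestSweepAndRecovery:
    def test_sweep_table_shape(self):
        mm, piles, truth = _simulated_truth_and_pileups(50, seed=11)
        tab = gc.concordance_sweep(piles, truth, [0.001, 0.5], mm)
        assert list(tab.columns) == ["t", "concordance", "n"]
        assert len(tab) == 2

    def test_high_t_beats_low_t_on_het_rich_truth(self):
        """Raising the heterozygote prior from near zero to 1/2 improves
        concordance when the truth contains heterozygotes (1000 sites)."""
        mm, piles, truth = _simulated_truth_and_pileups(1000, seed=7, depth_mean=8.0,
                                                        base_q=20)
        tab = gc.concordance_sweep(piles, truth, [0.00001, 0.5], mm)
        assert tab.concordance.iloc[1] > tab.concordance.iloc[0]

    def test_t_one_hurts_on_homozygous_truth(self):
        rng = np.random.default_rng(5)
        markers = pedsim.synthetic_marker_table(400, 0.05, "1", rng,
                                                freq_low=0.2, freq_high=0.5)
        truth_g = pd.DataFrame(
            {"S": (2.0 * rng.integers(0, 2, size=400)).astype(float)},
            index=pd.Index(markers["name"], name="marker"))
        cfg = pedsim.SimConfig(depth_mean=8.0, base_quality=20, seed=5)
        piles = pedsim.simulate_pileups(markers, truth_g, cfg, rng)["S"]
        mm = MarkerMap.from_frame(markers)
        truth_calls = [gc.GenotypeCall(m, "S", ["AA", "AB", "BB"][int(g)])
                       for m, g in truth_g["S"].items()]
        tab = gc.concordance_sweep(piles, truth_calls, [0.5, 1.0], mm)
        assert tab.concordance.iloc[1] < tab.concordance.iloc[0]

    def test_recovery_at_default_settings(self):
        """Depth-20 Q30 pileups recover the simulated truth essentially
        perfectly at t = 0.5."""
        mm, piles, truth = _simulated_truth_and_pileups(1000, seed=3)
        tab = gc.concordance_sweep(piles, truth, [0.5], mm)
        assert tab.concordance.iloc[0] >= 0.99


class TestHaploidRate:
    def _x_map(self, n=10):
        return MarkerMap.from_frame(pd.DataFrame({
            "name": [f"x{i}" for i in range(n)],
            "chrom": "X", "bp": np.arange(1, n + 1) * 100,
            "alleleA": "A", "alleleB": "C",
            "freqA": 0.5, "cM": np.arange(n, dtype=float),
        }))

    def test_rates(self):
        mm = self._x_map(10)
        calls = [gc.GenotypeCall(f"x{i}", "S", "AB" if i == 0 else "AA")
                 for i in range(10)]
        rep = gc.haploid_het_rate(calls, sex=1, marker_map=mm)
        assert rep.n_het == 1 and rep.n_total == 10
        assert rep.rate == pytest.approx(0.1)
        # the printed-scale arithmetic: 1/635 and 5/1026
        assert 1 / 635 == pytest.approx(0.0016, abs=5e-5)
        assert 5 / 1026 == pytest.approx(0.0049, abs=5e-5)

    def test_female_sample_rejected(self):
        with pytest.raises(ValueError):
            gc.haploid_het_rate([], sex=2, marker_map=self._x_map())

    def test_zero_hets(self):
        mm = self._x_map(10)
        calls = [gc.GenotypeCall(f"x{i}", "S", "BB") for i in range(10)]
        assert gc.haploid_het_rate(calls, sex=1, marker_map=mm).rate == 0.0


class TestTargetDistance:
    def test_distance_classes(self, marker_map):
        # rs1 at 100 inside [50,150); rs2 at 200 exactly 200 bp from a
        # target base at pos0 399 (target [399,500)); rs4 at 400 inside it
        targets = [("1", 50, 150), ("1", 399, 500)]
        df = gc.classify_by_target_distance(marker_map, targets)
        assert df.loc["0", "n_markers"] == 2          # rs1, rs4
        assert df.loc["1-200", "n_markers"] == 2      # rs2 (d=200), rs3 (d=99)
        assert df.loc[">200", "n_markers"] == 2       # chrom 2 markers

    def test_boundary_201_is_far(self):
        mm = MarkerMap.from_frame(pd.DataFrame({
            "name": ["a", "b"], "chrom": "1", "bp": [1000, 1202],
            "alleleA": "A", "alleleB": "C", "freqA": 0.5, "cM": [0.0, 0.1],
        }))
        df = gc.classify_by_target_distance(mm, [("1", 999, 1001)])
        # b is at pos0 1201, target last base 1000 -> d=201
        assert df.loc[">200", "n_markers"] == 1

    def test_empty_targets_warns(self, marker_map):
        with pytest.warns(UserWarning):
            df = gc.classify_by_target_distance(marker_map, [])
        assert df.loc[">200", "n_markers"] == 6

    def test_called_counts(self, marker_map):
        calls = [gc.GenotypeCall("rs1", "S", "AA"),
                 gc.GenotypeCall("rs2", "S", "missing")]
        df = gc.classify_by_target_distance(marker_map, [("1", 50, 150)], calls)
        assert df.loc["0", "n_called"] == 1


class TestGenotypeTsvRoundTrip:
    def test_round_trip(self, tmp_path):
        calls = [gc.GenotypeCall("m1", "S", "AB", 12, (0.1, 0.8, 0.1)),
                 gc.GenotypeCall("m2", "S", "missing", 0)]
        path = tmp_path / "g.tsv"
        gc.write_genotype_tsv(calls, path)
        back = gc.read_genotype_tsv(path)
        assert back[0].genotype == "AB" and back[0].depth == 12
        assert back[1].is_missing
        mat = gc.calls_to_matrix(back)
        assert mat.at["m1", "S"] == 1.0
        assert math.isnan(mat.at["m2", "S"])
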