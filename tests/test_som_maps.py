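import numpy as np
import pytest

from episegsom.errors import BoundsError, ValidationError
from episegsom.format_io import ExpressionTable, GeneModel, GenomeLayout
from episegsom.segmentation import Segment, SegmentationConfig, SegmentationResult
from episegsom.som_maps import (
    chromosome_maps,
    coverage_atlas,
    cpg_density,
    cpg_density_map,
    extend_transcript,
    gene_set_fraction_map,
    island_labeling,
    population_map,
    present_call_map,
    segment_length_map,
)

SHAPE = (4, 4)  # 16 nodes


def make_segment(chrom="chr1", start=0, end=400, bits=(1, 0), coverage=(0.0,)):
    seg = Segment(chrom, start, end, np.array(bits, dtype=np.int8))
    seg.coverage = np.array(coverage, dtype=float)
    return seg


class TestPopulationMap:
    def test_all_on_one_node(self):
        pm = population_map(np.zeros(10, dtype=int), SHAPE)
        assert pm.values[0] == 10
        assert pm.values[1:].sum() == 0
        assert pm.scale == "log"

    def test_conservation(self):
        rng = np.random.default_rng(0)
        assignment = rng.integers(0, 16, 500)
        pm = population_map(assignment, SHAPE)
        assert pm.values.sum() == 500

    def test_uniform_chi_square_sanity(self):
        rng = np.random.default_rng(1)
        n = 16_000
        assignment = rng.integers(0, 16, n)
        pm = population_map(assignment, SHAPE)
        expected = n / 16
        chi2 = float(((pm.values - expected) ** 2 / expected).sum())
        # 15 dof: far tails only
        assert chi2 < 50

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValidationError):
            population_map(np.array([], dtype=int), SHAPE)


class TestIslandLabeling:
    def test_single_island(self):
        assignment = np.repeat(0, 20)
        labeling = island_labeling(assignment, ["ES100"] * 20, SHAPE)
        assert labeling.labels == {0: "ES100"}

    def test_split_cep_gets_postfixes(self):
        # two blobs of the same CEP separated by empty nodes; larger gets 'a'
        assignment = np.concatenate([np.repeat(0, 30), np.repeat(1, 20), np.repeat(15, 25)])
        labels = ["ES110"] * 75
        labeling = island_labeling(assignment, labels, SHAPE)
        by_label = {v: k for k, v in labeling.labels.items()}
        assert set(by_label) == {"ES110a", "ES110b"}
        # nodes 0 and 1 are 4-connected -> island of 2 nodes -> postfix 'a'
        assert labeling.sizes[by_label["ES110a"]] == 2
        assert labeling.sizes[by_label["ES110b"]] == 1

    def test_no_island_below_threshold(self):
        assignment = np.arange(16)  # occupancy 1 everywhere
        labeling = island_labeling(assignment, ["ES000"] * 16, SHAPE)
        assert labeling.labels == {}
        assert np.all(labeling.node_island == -1)

    def test_threshold_strictly_greater(self):
        assignment = np.repeat(0, 10)  # exactly 10 EPs -> not an island
        assert island_labeling(assignment, ["ES1"] * 10, SHAPE).labels == {}
        assignment = np.repeat(0, 11)
        assert island_labeling(assignment, ["ES1"] * 11, SHAPE).labels == {0: "ES1"}

    def test_mixed_island_warns(self):
        assignment = np.repeat(0, 30)
        labels = ["ES100"] * 15 + ["ES000"] * 15
        with pytest.warns(UserWarning, match="mixed"):
            labeling = island_labeling(assignment, labels, SHAPE)
        assert labeling.labels[0] == "mixed"


class TestCoverageAtlas:
    def make_result(self):
        cfg = SegmentationConfig("ES", "ESC")
        segments = [
            make_segment(bits=(1, 0), coverage=(0.2,)),
            make_segment(bits=(1, 0), coverage=(0.4,)),
            make_segment(bits=(0, 1), coverage=(1.0,)),
        ]
        return SegmentationResult(
            segments, [], [("K4", "ESC"), ("K27", "ESC")], [("K4", "MEF")], cfg
        )

    def test_reference_state_is_binary(self):
        result = self.make_result()
        maps = coverage_atlas(np.array([0, 0, 1]), result, SHAPE)
        assert maps[("K4", "ESC")].values[0] == 1.0
        assert maps[("K4", "ESC")].values[1] == 0.0

    def test_mean_coverage(self):
        result = self.make_result()
        maps = coverage_atlas(np.array([0, 0, 1]), result, SHAPE)
        assert maps[("K4", "MEF")].values[0] == pytest.approx(0.3)
        assert maps[("K4", "MEF")].values[1] == pytest.approx(1.0)

    def test_empty_node_masked(self):
        result = self.make_result()
        maps = coverage_atlas(np.array([0, 0, 1]), result, SHAPE)
        assert maps[("K4", "ESC")].mask[5]
        assert np.isnan(maps[("K4", "ESC")].values[5])

    def test_atlas_covers_all_states(self):
        maps = coverage_atlas(np.array([0, 0, 1]), self.make_result(), SHAPE)
        assert set(maps) == {("K4", "ESC"), ("K27", "ESC"), ("K4", "MEF")}


class TestSegmentLengthMap:
    def test_mean_length(self):
        segments = [make_segment(end=200), make_segment(end=400)]
        lm = segment_length_map(np.array([0, 0]), segments, SHAPE)
        assert lm.values[0] == 300
        assert lm.inverted

    def test_single_segment(self):
        lm = segment_length_map(np.array([3]), [make_segment(end=777)], SHAPE)
        assert lm.values[3] == 777

    def test_min_value_with_default_filter(self):
        segments = [make_segment(end=200), make_segment(start=0, end=250)]
        lm = segment_length_map(np.array([0, 1]), segments, SHAPE)
        finite = lm.values[np.isfinite(lm.values)]
        assert finite.min() >= 200


class TestCpgDensity:
    def test_exhaustive_scan_examples(self):
        def oracle(seq):
            seq = seq.upper()
            return sum(
                1 for p in range(len(seq) - 1) if seq[p] == "C" and seq[p + 1] == "G"
            ) / len(seq)

        for seq, expected in [("CGCG", 0.5), ("AAAA", 0.0), ("CGC", 1 / 3)]:
            assert cpg_density(seq) == pytest.approx(expected)
            assert cpg_density(seq) == pytest.approx(oracle(seq))

    def test_ambiguous_bases_never_match(self):
        assert cpg_density("CNGN") == 0.0
        assert cpg_density("NCGN") == pytest.approx(0.25)

    def test_case_insensitive(self):
        assert cpg_density("cgcg") == 0.5

    def test_map_and_bounds(self):
        layout = GenomeLayout({"chr1": 8})
        genome = {"chr1": "ACGCGTTA"}
        seg = make_segment(end=8)
        cm = cpg_density_map(np.array([0]), [seg], genome, SHAPE)
        assert cm.values[0] == pytest.approx(2 / 8)
        with pytest.raises(BoundsError):
            cpg_density_map(np.array([0]), [make_segment(end=9)], genome, SHAPE)
        with pytest.raises(BoundsError):
            cpg_density_map(np.array([0]), [make_segment(chrom="chrZ")], genome, SHAPE)

    def test_random_sequences_match_oracle(self):
        rng = np.random.default_rng(5)
        alphabet = np.array(list("ACGTN"))
        for _ in range(200):
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(2, 60))))
            expected = sum(
                1
                for p in range(len(seq) - 1)
                if seq[p : p + 2].upper() == "CG"
            ) / len(seq)
            assert cpg_density(seq) == pytest.approx(expected)


class TestPresentCallMap:
    LAYOUT = GenomeLayout({"chr1": 20_000})

    def test_strand_extension(self):
        assert extend_transcript(5000, 8000, "+", 20_000) == (3000, 8000)
        assert extend_transcript(5000, 8000, "-", 20_000) == (5000, 10_000)
        assert extend_transcript(500, 800, "+", 20_000) == (0, 800)
        assert extend_transcript(5000, 19_500, "-", 20_000) == (5000, 20_000)

    def make_inputs(self):
        genes = [
            GeneModel("g1", "chr1", [(4000, 6000, "+")]),
            GeneModel("g2", "chr1", [(4500, 6500, "+")]),
        ]
        expr = ExpressionTable(
            ["A", "B"],
            {"g1": {"A": 1, "B": 1}, "g2": {"A": 0, "B": 1}},
        )
        return genes, expr

    def test_all_present_gene_active(self):
        genes, expr = self.make_inputs()
        seg = make_segment(start=5000, end=5400)
        pm = present_call_map(
            np.array([0]), [seg], [genes[0]], expr, self.LAYOUT, SHAPE
        )
        assert pm.values[0] == 1.0

    def test_half_present_not_active(self):
        genes, expr = self.make_inputs()
        seg = make_segment(start=5000, end=5400)
        pm = present_call_map(np.array([0]), [seg], genes, expr, self.LAYOUT, SHAPE)
        # score 0.5 < threshold 1.0 -> inactive; node fraction 0/1
        assert pm.values[0] == 0.0

    def test_segment_without_gene_excluded(self):
        genes, expr = self.make_inputs()
        far = make_segment(start=15_000, end=15_400)
        pm = present_call_map(np.array([5]), [far], genes, expr, self.LAYOUT, SHAPE)
        assert pm.mask[5]

    def test_upstream_extension_creates_overlap(self):
        genes, expr = self.make_inputs()
        # segment ends at 3500 < gene start 4000 but within the 2000 nt extension
        seg = make_segment(start=3000, end=3500)
        pm = present_call_map(
            np.array([0]), [seg], [genes[0]], expr, self.LAYOUT, SHAPE
        )
        assert pm.values[0] == 1.0


class TestGeneSetFractionMap:
    LAYOUT = GenomeLayout({"chr1": 20_000})

    def make_genes(self):
        return [
            GeneModel("g1", "chr1", [(4000, 6000, "+")]),
            GeneModel("g2", "chr1", [(4500, 6500, "+")]),
        ]

    def test_half_in_set(self):
        seg = make_segment(start=5000, end=5400)
        gm = gene_set_fraction_map(
            np.array([0]), [seg], self.make_genes(), {"g1"}, self.LAYOUT, SHAPE
        )
        assert gm.values[0] == 0.5

    def test_node_without_genes_masked(self):
        seg = make_segment(start=15_000, end=15_400)
        gm = gene_set_fraction_map(
            np.array([2]), [seg], self.make_genes(), {"g1"}, self.LAYOUT, SHAPE
        )
        assert gm.mask[2]

    def test_full_set_everywhere_one(self):
        seg = make_segment(start=5000, end=5400)
        gm = gene_set_fraction_map(
            np.array([0]), [seg], self.make_genes(), {"g1", "g2"}, self.LAYOUT, SHAPE
        )
        assert gm.values[0] == 1.0


class TestChromosomeMaps:
    def test_saturation_log_zero(self):
        segments = [make_segment() for _ in range(20)]
        assignment = np.arange(20) % 16
        pop, enr = chromosome_maps(assignment, segments, "chr1", SHAPE)
        occupied = ~enr.mask
        assert np.allclose(enr.values[occupied], 0.0)
        assert pop.values.sum() == pytest.approx(1.0)

    def test_closed_form(self):
        # N=100, node 0 has N_k=10, chromosome c has N_c=20 with n_kc=4
        segments = []
        assignment = []
        # node 0: 4 from chrC, 6 from chrO
        segments += [make_segment(chrom="chrC")] * 4 + [make_segment(chrom="chrO")] * 6
        assignment += [0] * 10
        # node 1: remaining 16 chrC and 74 chrO spread over other nodes
        segments += [make_segment(chrom="chrC")] * 16 + [make_segment(chrom="chrO")] * 74
        assignment += [1] * 16 + [2] * 74
        _, enr = chromosome_maps(np.array(assignment), segments, "chrC", SHAPE)
        assert enr.values[0] == pytest.approx(1.0)  # log2(4/2)

    def test_zero_observed_masked(self):
        segments = [make_segment(chrom="chrC"), make_segment(chrom="chrO")]
        pop, enr = chromosome_maps(np.array([0, 1]), segments, "chrC", SHAPE)
        assert enr.mask[1]
        assert not enr.mask[0]

    def test_no_segments_on_chromosome_error(self):
        with pytest.raises(ValidationError):
            chromosome_maps(np.array([0]), [make_segment(chrom="chr1")], "chrX", SHAPE)

    def test_expectation_conserves_marginal(self):
        rng = np.random.default_rng(9)
        chroms = rng.choice(["c1", "c2", "c3"], 300)
        segments = [make_segment(chrom=c) for c in chroms]
        assignment = rng.integers(0, 16, 300)
        n_k = np.bincount(assignment, minlength=16)
        pop_total = np.zeros(16)
        for chrom in ["c1", "c2", "c3"]:
            n_c = int((chroms == chrom).sum())
            pop, _ = chromosome_maps(assignment, segments, chrom, SHAPE)
            expected = n_k * n_c / 300
            assert expected.sum() == pytest.approx(n_c)
            assert pop.values.sum() * n_c == pytest.approx(n_c)
            pop_total += pop.values * n_c
        assert np.allclose(pop_total, n_k)

    def test_uniform_scatter_centered(self):
        rng = np.random.default_rng(30)
        n_c, n_other = 5000, 5000
        segments = [make_segment(chrom="cU")] * n_c + [make_segment(chrom="cO")] * n_other
        assignment = rng.integers(0, 16, n_c + n_other)
        _, enr = chromosome_maps(assignment, segments, "cU", SHAPE)
        occupied = ~enr.mask
        assert abs(float(np.nanmean(enr.values[occupied]))) < 0.1
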