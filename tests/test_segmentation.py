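import numpy as np
import pytest

from conftest import oracle_coverage, oracle_segment_chromosome, random_region_set
from episegsom.errors import ValidationError
from episegsom.format_io import GenomeLayout, RegionSet
from episegsom.segmentation import (
    Segment,
    SegmentationConfig,
    StatePanel,
    assemble_profiles,
    build_segments,
    cep_label,
    compute_coverage,
    segment_genome,
    select_reference_states,
)

MARKS = ["K4", "K27", "K9"]
CELLS = ["ESC", "MEF", "NPC"]


def empty_panel(layout, marks=MARKS, cells=CELLS):
    states = {
        (m, c): RegionSet(f"{m}:{c}", layout, {}) for m in marks for c in cells
    }
    return StatePanel(marks, cells, layout, states)


class TestSelectReferenceStates:
    def test_es_mode(self, toy_layout):
        panel = empty_panel(toy_layout)
        cfg = SegmentationConfig("ES", "ESC")
        ref_ids, ref, comp_ids, comp = select_reference_states(panel, cfg)
        assert ref_ids == [("K4", "ESC"), ("K27", "ESC"), ("K9", "ESC")]
        assert len(comp_ids) == 6
        assert ("K4", "MEF") in comp_ids and ("K4", "ESC") not in comp_ids

    def test_ev_mode(self, toy_layout):
        panel = empty_panel(toy_layout)
        cfg = SegmentationConfig("EV", "K4")
        ref_ids, _, comp_ids, _ = select_reference_states(panel, cfg)
        assert ref_ids == [("K4", "ESC"), ("K4", "MEF"), ("K4", "NPC")]
        assert len(comp_ids) == 6

    def test_degenerate_single_state(self, toy_layout):
        panel = empty_panel(toy_layout, marks=["K4"], cells=["ESC"])
        ref_ids, _, comp_ids, _ = select_reference_states(
            panel, SegmentationConfig("ES", "ESC")
        )
        assert len(ref_ids) == 1 and comp_ids == []

    def test_missing_reference(self, toy_layout):
        panel = empty_panel(toy_layout)
        with pytest.raises(ValidationError):
            select_reference_states(panel, SegmentationConfig("ES", "HeLa"))


class TestBuildSegments:
    def test_two_state_example(self):
        layout = GenomeLayout({"chr1": 600})
        a = RegionSet("A", layout, {"chr1": [(0, 300)]})
        b = RegionSet("B", layout, {"chr1": [(200, 500)]})
        # oracle: per-base labeling then length filter
        expected = oracle_segment_chromosome([a.to_mask("chr1"), b.to_mask("chr1")], 200)
        # candidates [0,200) 10, [200,300) 11, [300,500) 01, [500,600) 00;
        # the two length-100 candidates fall below the 200 bp limit
        assert expected == [(0, 200, (1, 0)), (300, 500, (0, 1))]
        segments, discarded = build_segments([a, b], layout, SegmentationConfig("ES", "x"))
        got = [(s.start, s.end, tuple(s.cep)) for s in segments]
        assert got == expected
        assert ("chr1", 200, 300) in discarded
        assert ("chr1", 500, 600) in discarded

    def test_unmodified_genome_single_segment(self):
        layout = GenomeLayout({"chr1": 1000})
        states = [RegionSet("A", layout, {}), RegionSet("B", layout, {})]
        segments, discarded = build_segments(states, layout, SegmentationConfig("ES", "x"))
        assert len(segments) == 1 and not discarded
        seg = segments[0]
        assert (seg.start, seg.end) == (0, 1000)
        assert seg.cep.tolist() == [0, 0]

    def test_short_chromosome_filtered(self):
        layout = GenomeLayout({"chr1": 150})
        segments, discarded = build_segments(
            [RegionSet("A", layout, {"chr1": [(10, 120)]})], layout,
            SegmentationConfig("ES", "x"),
        )
        assert segments == []
        assert len(discarded) == 3

    def test_lossless_partition(self, toy_layout):
        rng = np.random.default_rng(5)
        states = [random_region_set(rng, toy_layout, label=f"s{i}") for i in range(3)]
        segments, discarded = build_segments(states, toy_layout, SegmentationConfig("ES", "x"))
        pieces = [(s.chrom, s.start, s.end) for s in segments] + discarded
        for chrom in toy_layout:
            on_c = sorted((s, e) for c, s, e in pieces if c == chrom)
            assert on_c[0][0] == 0
            assert on_c[-1][1] == toy_layout[chrom]
            for (s1, e1), (s2, e2) in zip(on_c, on_c[1:]):
                assert e1 == s2  # disjoint and gap-free

    def test_at_most_2n_ceps(self, toy_layout):
        rng = np.random.default_rng(11)
        states = [random_region_set(rng, toy_layout, label=f"s{i}") for i in range(3)]
        segments, _ = build_segments(states, toy_layout, SegmentationConfig("ES", "x"))
        ceps = {tuple(s.cep) for s in segments}
        assert len(ceps) <= 8

    def test_reference_coverage_binarity(self, toy_layout):
        rng = np.random.default_rng(13)
        states = [random_region_set(rng, toy_layout, label=f"s{i}") for i in range(3)]
        segments, _ = build_segments(states, toy_layout, SegmentationConfig("ES", "x"))
        masks = {i: s.to_mask("chr1") for i, s in enumerate(states)}
        for seg in segments:
            if seg.chrom != "chr1":
                continue
            for k in range(3):
                cov = oracle_coverage(masks[k], seg.start, seg.end)
                assert cov in (0.0, 1.0)
                assert int(cov) == seg.cep[k]


class TestComputeCoverage:
    def test_fractional(self):
        layout = GenomeLayout({"chr1": 400})
        seg = Segment("chr1", 0, 400, np.array([1], dtype=np.int8))
        state = RegionSet("c", layout, {"chr1": [(100, 200), (300, 350)]})
        compute_coverage(seg, [state])
        expected = oracle_coverage(state.to_mask("chr1"), 0, 400)
        assert seg.coverage[0] == pytest.approx(expected) == pytest.approx(0.375)

    def test_no_overlap_zero(self):
        layout = GenomeLayout({"chr1": 400})
        seg = Segment("chr1", 0, 200, np.array([0], dtype=np.int8))
        state = RegionSet("c", layout, {"chr1": [(300, 350)]})
        compute_coverage(seg, [state])
        assert seg.coverage[0] == 0.0

    def test_superset_one(self):
        layout = GenomeLayout({"chr1": 400})
        seg = Segment("chr1", 100, 300, np.array([0], dtype=np.int8))
        state = RegionSet("c", layout, {"chr1": [(0, 400)]})
        compute_coverage(seg, [state])
        assert seg.coverage[0] == 1.0


class TestAssembleProfiles:
    def make_segment(self):
        seg = Segment("chr1", 0, 400, np.array([1, 1, 1], dtype=np.int8))
        seg.coverage = np.array([0.5, 0.2, 0.0, 0.0, 1.0, 0.9])
        return seg

    def test_weight_one(self):
        ep = assemble_profiles([self.make_segment()], SegmentationConfig("ES", "x"))
        assert ep[0].tolist() == [1, 1, 1, 0.5, 0.2, 0, 0, 1, 0.9]

    def test_weight_zero_annihilates(self):
        cfg = SegmentationConfig("ES", "x", coverage_weight=0.0)
        ep = assemble_profiles([self.make_segment()], cfg)
        assert ep[0].tolist() == [1, 1, 1, 0, 0, 0, 0, 0, 0]

    def test_weight_two_doubles(self):
        cfg = SegmentationConfig("ES", "x", coverage_weight=2.0)
        ep = assemble_profiles([self.make_segment()], cfg)
        assert ep[0][3:].tolist() == [1.0, 0.4, 0.0, 0.0, 2.0, 1.8]


class TestCepLabel:
    @pytest.mark.parametrize(
        "mode,bits,expected",
        [
            ("ES", (0, 0, 0), "ES000"),
            ("EV", (1, 1, 1), "EV111"),
            ("ES", (1, 0, 0), "ES100"),
        ],
    )
    def test_labels(self, mode, bits, expected):
        seg = Segment("chr1", 0, 300, np.array(bits, dtype=np.int8))
        ref = "ESC" if mode == "ES" else "K4"
        assert cep_label(seg, SegmentationConfig(mode, ref)) == expected


class TestOracleEquivalence:
    def test_random_panels_match_oracle(self, toy_layout):
        rng = np.random.default_rng(99)
        cfg = SegmentationConfig("ES", "ESC")
        for _ in range(25):
            ref = [random_region_set(rng, toy_layout, label=f"r{i}") for i in range(3)]
            comp = [random_region_set(rng, toy_layout, label=f"c{j}") for j in range(6)]
            segments, _ = build_segments(ref, toy_layout, cfg)
            for seg in segments:
                compute_coverage(seg, comp)
            for chrom in toy_layout:
                expected = oracle_segment_chromosome(
                    [s.to_mask(chrom) for s in ref], cfg.min_segment_length
                )
                got = [
                    (s.start, s.end, tuple(int(b) for b in s.cep))
                    for s in segments
                    if s.chrom == chrom
                ]
                assert got == expected
                comp_masks = [c.to_mask(chrom) for c in comp]
                for seg in (s for s in segments if s.chrom == chrom):
                    for j, mask in enumerate(comp_masks):
                        assert seg.coverage[j] == pytest.approx(
                            oracle_coverage(mask, seg.start, seg.end)
                        )


def test_segment_genome_full(toy_layout):
    rng = np.random.default_rng(2)
    states = {
        (m, c): random_region_set(rng, toy_layout, label=f"{m}:{c}")
        for m in MARKS
        for c in CELLS
    }
    panel = StatePanel(MARKS, CELLS, toy_layout, states)
    result = segment_genome(panel, SegmentationConfig("ES", "ESC"))
    assert result.profiles.shape == (len(result.segments), 9)
    assert np.all((result.profiles[:, :3] == 0) | (result.profiles[:, :3] == 1))
    assert np.all(result.profiles[:, 3:] >= 0) and np.all(result.profiles[:, 3:] <= 1)
    assert all(lbl.startswith("ES") for lbl in result.cep_labels())
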