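"""Combinatorial genome segmentation from binary modification states.

Two variants share the same machinery: ES-segmentation takes all marks of one
reference cell type as reference states, EV-segmentation takes one reference
mark across all cell types. Boundaries of all reference regions (plus the
chromosome ends) partition each chromosome; retained segments carry a binary
combinatorial profile (CEP) over the reference states and fractional coverage
values over the complementary states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .format_io import GenomeLayout, RegionSet

__all__ = [
    "StateId",
    "StatePanel",
    "SegmentationConfig",
    "Segment",
    "SegmentationResult",
    "select_reference_states",
    "build_segments",
    "compute_coverage",
    "assemble_profiles",
    "cep_label",
    "segment_genome",
    "write_segments_bed",
    "write_profiles_tsv",
    "read_profiles_tsv",
]

StateId = tuple[str, str]  # (mark, cell type)


@dataclass
class StatePanel:
    """All m x n modification states on one genome layout."""

    marks: list[str]
    cells: list[str]
    layout: GenomeLayout
    states: dict[StateId, RegionSet]

    def __post_init__(self):
        for mark in self.marks:
            for cell in self.cells:
                if (mark, cell) not in self.states:
                    raise ValidationError(f"missing modification state ({mark}, {cell})")
        for key, rs in self.states.items():
            if rs.layout != self.layout:
                raise ValidationError(f"state {key} is on a different genome layout")

    @property
    def m(self) -> int:
        return len(self.marks)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def state(self, mark: str, cell: str) -> RegionSet:
        return self.states[(mark, cell)]


@dataclass
class SegmentationConfig:
    mode: str = "ES"
    reference: str = ""
    min_segment_length: int = 200
    coverage_weight: float = 1.0

    def __post_init__(self):
        if self.mode not in ("ES", "EV"):
            raise ValidationError(f"mode must be 'ES' or 'EV', got {self.mode!r}")
        if self.min_segment_length <= 0:
            raise ValidationError("min_segment_length must be > 0")
        if self.coverage_weight < 0:
            raise ValidationError("coverage_weight must be >= 0")


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    cep: np.ndarray  # n-bit reference profile
    coverage: np.ndarray | None = None  # (m*n - n) fractions in [0, 1]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    segments: list[Segment]
    discarded: list[tuple[str, int, int]]
    reference_ids: list[StateId]
    complementary_ids: list[StateId]
    config: SegmentationConfig
    profiles: np.ndarray | None = None

    @property
    def state_order(self) -> list[StateId]:
        return self.reference_ids + self.complementary_ids

    def cep_labels(self) -> list[str]:
        return [cep_label(seg, self.config) for seg in self.segments]


def select_reference_states(
    panel: StatePanel, cfg: SegmentationConfig
) -> tuple[list[StateId], list[RegionSet], list[StateId], list[RegionSet]]:
    """Split the panel into reference and complementary states in canonical order.

    ES mode: the reference cell type's states ordered by mark declaration.
    EV mode: the reference mark's states ordered by cell-type declaration.
    Complementary states follow mark order (outer) then cell order (inner).
    """
    if cfg.mode == "ES":
        if cfg.reference not in panel.cells:
            raise ValidationError(f"reference cell type {cfg.reference!r} not in panel")
        ref_ids = [(mark, cfg.reference) for mark in panel.marks]
    else:
        if cfg.reference not in panel.marks:
            raise ValidationError(f"reference mark {cfg.reference!r} not in panel")
        ref_ids = [(cfg.reference, cell) for cell in panel.cells]
    ref_set = set(ref_ids)
    comp_ids = [
        (mark, cell)
        for mark in panel.marks
        for cell in panel.cells
        if (mark, cell) not in ref_set
    ]
    ref_states = [panel.states[i] for i in ref_ids]
    comp_states = [panel.states[i] for i in comp_ids]
    return ref_ids, ref_states, comp_ids, comp_states


def _containment_bits(
    state: RegionSet, chrom: str, seg_starts: np.ndarray, seg_ends: np.ndarray
) -> np.ndarray:
    """1 where [start, end) lies inside a region of ``state``; assert no partial overlap."""
    ivs = state.intervals(chrom)
    if len(ivs) == 0:
        return np.zeros(len(seg_starts), dtype=np.int8)
    starts, ends = ivs[:, 0], ivs[:, 1]
    idx = np.searchsorted(starts, seg_starts, side="right") - 1
    valid = idx >= 0
    idx_c = np.clip(idx, 0, None)
    covers_start = valid & (seg_starts < ends[idx_c])
    inside = covers_start & (seg_ends <= ends[idx_c])
    partial_left = covers_start & ~inside
    # a region starting strictly inside the segment would also be partial
    nxt = np.searchsorted(starts, seg_starts, side="right")
    partial_right = (nxt < len(starts)) & (starts[np.clip(nxt, 0, len(starts) - 1)] < seg_ends)
    if np.any(partial_left | (partial_right & ~inside)):
        raise AssertionError(
            "reference state partially overlaps a boundary segment; "
            "boundary projection is inconsistent"
        )
    return inside.astype(np.int8)


def build_segments(
    reference_states: list[RegionSet],
    layout: GenomeLayout,
    cfg: SegmentationConfig,
) -> tuple[list[Segment], list[tuple[str, int, int]]]:
    """Project all reference-region boundaries onto the genome and cut segments.

    Chromosome ends count as boundaries so flanking unmodified chromatin forms
    segments. Segments shorter than ``cfg.min_segment_length`` are returned in
    the discarded list. Reference coverage of every retained segment is exactly
    0 or 100% by construction; this is asserted.
    """
    segments: list[Segment] = []
    discarded: list[tuple[str, int, int]] = []
    for chrom in layout:
        length = layout[chrom]
        bounds = [np.array([0, length], dtype=np.int64)]
        for state in reference_states:
            ivs = state.intervals(chrom)
            if len(ivs):
                bounds.append(ivs.ravel())
        cuts = np.unique(np.concatenate(bounds))
        seg_starts = cuts[:-1]
        seg_ends = cuts[1:]
        keep = (seg_ends - seg_starts) >= cfg.min_segment_length
        for s, e in zip(seg_starts[~keep], seg_ends[~keep]):
            discarded.append((chrom, int(s), int(e)))
        ks, ke = seg_starts[keep], seg_ends[keep]
        if len(ks) == 0:
            continue
        bits = np.stack(
            [_containment_bits(state, chrom, ks, ke) for state in reference_states], axis=1
        )
        for i in range(len(ks)):
            segments.append(Segment(chrom, int(ks[i]), int(ke[i]), bits[i].copy()))
    return segments, discarded


def _overlap_bases(ivs: np.ndarray, start: int, end: int) -> int:
    """Total bases of [start, end) covered by sorted non-overlapping intervals."""
    if len(ivs) == 0:
        return 0
    lo = np.searchsorted(ivs[:, 1], start, side="right")
    hi = np.searchsorted(ivs[:, 0], end, side="left")
    if lo >= hi:
        return 0
    window = ivs[lo:hi]
    return int(
        np.sum(np.minimum(window[:, 1], end) - np.maximum(window[:, 0], start))
    )


def compute_coverage(segment: Segment, complementary_states: list[RegionSet]) -> Segment:
    """Fill coverage_j = overlapped bases by complementary state j / segment length."""
    cov = np.empty(len(complementary_states), dtype=float)
    for j, state in enumerate(complementary_states):
        cov[j] = _overlap_bases(state.intervals(segment.chrom), segment.start, segment.end)
    segment.coverage = cov / segment.length
    return segment


def assemble_profiles(segments: list[Segment], cfg: SegmentationConfig) -> np.ndarray:
    """EP matrix: cep bits followed by weight * coverage, one row per segment."""
    if not segments:
        return np.empty((0, 0))
    rows = []
    for seg in segments:
        if seg.coverage is None:
            raise ValidationError("segment coverage not computed")
        rows.append(np.concatenate([seg.cep.astype(float), cfg.coverage_weight * seg.coverage]))
    return np.vstack(rows)


def cep_label(segment: Segment, cfg: SegmentationConfig) -> str:
    """Mode prefix plus the CEP bits in canonical order, e.g. (1,1,0) -> 'ES110'."""
    return cfg.mode + "".join(str(int(b)) for b in segment.cep)


def segment_genome(panel: StatePanel, cfg: SegmentationConfig) -> SegmentationResult:
    """Full segmentation: reference selection, boundary cut, coverage, profiles."""
    ref_ids, ref_states, comp_ids, comp_states = select_reference_states(panel, cfg)
    segments, discarded = build_segments(ref_states, panel.layout, cfg)
    for seg in segments:
        compute_coverage(seg, comp_states)
    profiles = assemble_profiles(segments, cfg)
    return SegmentationResult(segments, discarded, ref_ids, comp_ids, cfg, profiles)


def write_segments_bed(result: SegmentationResult, path) -> None:
    with open(path, "w") as fh:
        for seg in result.segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{cep_label(seg, result.config)}\n")


def write_profiles_tsv(result: SegmentationResult, path) -> None:
    """One EP row per segment; columns named <mark>:<cell> in canonical order."""
    if result.profiles is None:
        raise ValidationError("profiles not assembled")
    cols = [f"{m}:{c}" for m, c in result.state_order]
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(cols) + "\n")
        for seg, row in zip(result.segments, result.profiles):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{vals}\n")


def read_profiles_tsv(path) -> tuple[np.ndarray, list[tuple[str, int, int]], list[str]]:
    """Read a profiles TSV; returns (EP matrix, segment coords, state column names)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    coords = list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))
    cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return df[cols].to_numpy(dtype=float), coords, cols
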