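"""Per-node SOM-images and supporting maps built from a trained SOM.

Every map is a NodeMap: one scalar per node plus rendering metadata. All
coverage-derived maps use the unweighted coverage stored on the segments,
not the learned codebook.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import BoundsError, ValidationError
from .format_io import ExpressionTable, GeneModel, GenomeLayout
from .segmentation import Segment, SegmentationResult, StateId

__all__ = [
    "NodeMap",
    "IslandLabeling",
    "population_map",
    "island_labeling",
    "coverage_atlas",
    "segment_length_map",
    "cpg_density_map",
    "cpg_density",
    "extend_transcript",
    "present_call_map",
    "gene_set_fraction_map",
    "chromosome_maps",
]


@dataclass
class NodeMap:
    """One scalar per SOM node with rendering metadata."""

    shape: tuple[int, int]  # (height, width)
    values: np.ndarray  # (K,) float; masked entries are NaN
    mask: np.ndarray  # (K,) bool, True = masked
    scale: str = "linear"  # 'linear' | 'log'
    inverted: bool = False
    label: str = ""

    def __post_init__(self):
        k = self.shape[0] * self.shape[1]
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.size != k or self.mask.size != k:
            raise ValidationError(f"value count {self.values.size} != grid size {k}")
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    def grid(self) -> np.ndarray:
        return self.values.reshape(self.shape)


@dataclass
class IslandLabeling:
    """Connected components of densely occupied nodes, labeled by their CEP."""

    shape: tuple[int, int]
    node_island: np.ndarray  # (K,) int; -1 = border / sparse
    labels: dict[int, str] = field(default_factory=dict)
    sizes: dict[int, int] = field(default_factory=dict)

    def island_ids(self) -> list[int]:
        return sorted(self.labels)


def _node_means(
    assignment: np.ndarray, values: np.ndarray, n_nodes: int
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(assignment, minlength=n_nodes).astype(float)
    sums = np.bincount(assignment, weights=values, minlength=n_nodes)
    mask = counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return means, mask


def population_map(assignment: np.ndarray, shape: tuple[int, int]) -> NodeMap:
    """Number of EPs per node; log scale hint."""
    assignment = np.asarray(assignment)
    if assignment.size == 0:
        raise ValidationError("assignment is empty")
    k = shape[0] * shape[1]
    counts = np.bincount(assignment, minlength=k).astype(float)
    return NodeMap(shape, counts, np.zeros(k, dtype=bool), scale="log", label="population")


def island_labeling(
    assignment: np.ndarray,
    cep_labels: list[str],
    shape: tuple[int, int],
    occupancy_threshold: int = 10,
    connectivity: int = 4,
) -> IslandLabeling:
    """Detect islands of nodes with occupancy strictly above the threshold.

    Islands are connected components (4-neighborhood by default) of dense
    nodes. Each island is labeled by the CEP shared by all its member
    segments; a CEP spanning several islands gets postfixes a, b, ... in
    descending island size. A mixed island is labeled 'mixed' with a warning.
    """
    height, width = shape
    k = height * width
    occupancy = np.bincount(np.asarray(assignment), minlength=k)
    dense = (occupancy > occupancy_threshold).reshape(shape)
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    else:
        raise ValidationError("connectivity must be 4 or 8")
    labeled, n_islands = ndimage.label(dense, structure=structure)
    node_island = labeled.ravel() - 1  # -1 = border
    cep_arr = np.asarray(cep_labels, dtype=object)
    raw: dict[int, str] = {}
    sizes: dict[int, int] = {}
    for isl in range(n_islands):
        nodes = np.flatnonzero(node_island == isl)
        sizes[isl] = len(nodes)
        member = np.isin(np.asarray(assignment), nodes)
        ceps = set(cep_arr[member])
        if len(ceps) == 1:
            raw[isl] = next(iter(ceps))
        elif len(ceps) == 0:
            raw[isl] = "empty"
        else:
            warnings.warn(
                f"island {isl} contains {len(ceps)} distinct CEPs; labeling as 'mixed'",
                stacklevel=2,
            )
            raw[isl] = "mixed"
    labels: dict[int, str] = {}
    by_cep: dict[str, list[int]] = {}
    for isl, cep in raw.items():
        by_cep.setdefault(cep, []).append(isl)
    for cep, islands in by_cep.items():
        if len(islands) == 1:
            labels[islands[0]] = cep
        else:
            for i, isl in enumerate(sorted(islands, key=lambda x: (-sizes[x], x))):
                labels[isl] = cep + chr(ord("a") + i)
    return IslandLabeling(shape, node_island, labels, sizes)


def coverage_atlas(
    assignment: np.ndarray, result: SegmentationResult, shape: tuple[int, int]
) -> dict[StateId, NodeMap]:
    """One map per modification state: mean coverage of the segments per node.

    Reference states contribute their CEP bit (0/1), complementary states
    their unweighted coverage fraction. Maps are returned for all m*n states
    in panel order (marks outer, cells inner, following the canonical state
    order of the segmentation).
    """
    k = shape[0] * shape[1]
    assignment = np.asarray(assignment)
    n_ref = len(result.reference_ids)
    maps: dict[StateId, NodeMap] = {}
    for pos, state_id in enumerate(result.state_order):
        if pos < n_ref:
            vals = np.array([seg.cep[pos] for seg in result.segments], dtype=float)
        else:
            vals = np.array(
                [seg.coverage[pos - n_ref] for seg in result.segments], dtype=float
            )
        means, mask = _node_means(assignment, vals, k)
        maps[state_id] = NodeMap(
            shape, means, mask, scale="linear", label=f"coverage {state_id[0]}:{state_id[1]}"
        )
    return maps


def segment_length_map(
    assignment: np.ndarray, segments: list[Segment], shape: tuple[int, int]
) -> NodeMap:
    """Mean segment length per node; color scale inverted (small values warm)."""
    lengths = np.array([seg.length for seg in segments], dtype=float)
    means, mask = _node_means(np.asarray(assignment), lengths, shape[0] * shape[1])
    return NodeMap(shape, means, mask, scale="linear", inverted=True, label="segment length")


def cpg_density(seq: str) -> float:
    """CG-dinucleotide count on the plus strand divided by sequence length.

    Case-insensitive; ambiguous bases never match; a dinucleotide straddling
    the segment end is excluded by construction.
    """
    if not seq:
        raise ValidationError("empty sequence")
    return seq.upper().count("CG") / len(seq)


def cpg_density_map(
    assignment: np.ndarray,
    segments: list[Segment],
    genome: dict[str, str],
    shape: tuple[int, int],
) -> NodeMap:
    """Mean per-segment CpG density per node, from plus-strand sequence."""
    dens = np.empty(len(segments))
    for i, seg in enumerate(segments):
        if seg.chrom not in genome:
            raise BoundsError(f"chromosome {seg.chrom!r} missing from genome")
        seq = genome[seg.chrom]
        if seg.end > len(seq):
            raise BoundsError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} beyond sequence length {len(seq)}"
            )
        dens[i] = cpg_density(seq[seg.start : seg.end])
    means, mask = _node_means(np.asarray(assignment), dens, shape[0] * shape[1])
    return NodeMap(shape, means, mask, scale="linear", label="CpG density")


def extend_transcript(
    start: int, end: int, strand: str, chrom_length: int, extension: int = 2000
) -> tuple[int, int]:
    """Add ``extension`` nt upstream of the 5' end, clipped to the chromosome."""
    if strand == "+":
        return max(0, start - extension), end
    if strand == "-":
        return start, min(chrom_length, end + extension)
    raise ValidationError(f"unknown strand {strand!r}")


def _genes_per_segment(
    segments: list[Segment],
    genes: list[GeneModel],
    layout: GenomeLayout,
    extension: int,
) -> list[list[int]]:
    """Indices of genes whose extended transcripts overlap each segment (>= 1 bp)."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, gene in enumerate(genes):
        length = layout[gene.chrom]
        for start, end, strand in gene.transcripts:
            s, e = extend_transcript(start, end, strand, length, extension)
            by_chrom.setdefault(gene.chrom, []).append((s, e, gi))
    for ivs in by_chrom.values():
        ivs.sort()
    out: list[list[int]] = []
    for seg in segments:
        hits: set[int] = set()
        for s, e, gi in by_chrom.get(seg.chrom, []):
            if s >= seg.end:
                break
            if e > seg.start:
                hits.add(gi)
        out.append(sorted(hits))
    return out


def present_call_map(
    assignment: np.ndarray,
    segments: list[Segment],
    genes: list[GeneModel],
    expr: ExpressionTable,
    layout: GenomeLayout,
    shape: tuple[int, int],
    extension: int = 2000,
    active_threshold: float = 1.0,
) -> NodeMap:
    """Fraction of gene-overlapping segments per node that are 'active'.

    A gene scores 1 iff present in every cell type of the expression table.
    A segment's score is the mean over overlapping genes (extended 2000 nt
    upstream of each transcript's 5' end); segments without genes are
    excluded. A segment is active when its score >= ``active_threshold``
    (default 1.0 = exclusive overlap with all-present genes).
    """
    k = shape[0] * shape[1]
    gene_hits = _genes_per_segment(segments, genes, layout, extension)
    present = np.array(
        [expr.present_in_all(g.gene_id) if g.gene_id in expr else 0 for g in genes],
        dtype=float,
    )
    n_overlap = np.zeros(k)
    n_active = np.zeros(k)
    for seg_idx, hits in enumerate(gene_hits):
        if not hits:
            continue
        node = assignment[seg_idx]
        n_overlap[node] += 1
        if float(np.mean(present[hits])) >= active_threshold:
            n_active[node] += 1
    mask = n_overlap == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = n_active / n_overlap
    return NodeMap(shape, values, mask, scale="linear", label="present call")


def gene_set_fraction_map(
    assignment: np.ndarray,
    segments: list[Segment],
    genes: list[GeneModel],
    gene_set: set[str] | list[str],
    layout: GenomeLayout,
    shape: tuple[int, int],
    extension: int = 2000,
) -> NodeMap:
    """Per node: genes from the set assigned to the node / all assigned genes.

    A gene is assigned to a node when it overlaps at least one segment
    assigned there (counted once per node). Nodes without genes are masked.
    """
    gene_set = set(gene_set)
    k = shape[0] * shape[1]
    gene_hits = _genes_per_segment(segments, genes, layout, extension)
    node_genes: dict[int, set[int]] = {}
    for seg_idx, hits in enumerate(gene_hits):
        if hits:
            node_genes.setdefault(int(assignment[seg_idx]), set()).update(hits)
    values = np.full(k, np.nan)
    mask = np.ones(k, dtype=bool)
    for node, gidx in node_genes.items():
        in_set = sum(1 for gi in gidx if genes[gi].gene_id in gene_set)
        values[node] = in_set / len(gidx)
        mask[node] = False
    return NodeMap(shape, values, mask, scale="log", label="gene-set fraction")


def chromosome_maps(
    assignment: np.ndarray,
    segments: list[Segment],
    chromosome: str,
    shape: tuple[int, int],
) -> tuple[NodeMap, NodeMap]:
    """Chromosome-specific population and hypergeometric enrichment maps.

    With N segments total, N_k at node k, N_c on the chromosome and n_kc
    observed, the expected count is E_kc = N_k * N_c / N (hypergeometric
    expectation). Population value = n_kc / N_c; enrichment = log2(n_kc/E_kc),
    masked where n_kc = 0 or N_k = 0.
    """
    k = shape[0] * shape[1]
    assignment = np.asarray(assignment)
    chroms = np.array([seg.chrom for seg in segments], dtype=object)
    on_c = chroms == chromosome
    n_c = int(on_c.sum())
    if n_c == 0:
        raise ValidationError(f"no segments on chromosome {chromosome!r}")
    n_total = len(segments)
    n_k = np.bincount(assignment, minlength=k).astype(float)
    n_kc = np.bincount(assignment[on_c], minlength=k).astype(float)
    pop = NodeMap(
        shape,
        n_kc / n_c,
        np.zeros(k, dtype=bool),
        scale="log",
        label=f"population {chromosome}",
    )
    expected = n_k * n_c / n_total
    mask = (n_kc == 0) | (n_k == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        enrich = np.log2(n_kc / expected)
    enrich[mask] = np.nan
    enr = NodeMap(shape, enrich, mask, scale="linear", label=f"enrichment {chromosome}")
    return pop, enr
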