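"""Synthetic inputs with known ground truth.

Generates modification-state panels with planted combinatorial blocks,
Poisson read-count tracks, gene models with present/absent flags and a
genome sequence with tunable CpG density. One global seed governs all
generators; identical seeds yield identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .format_io import (
    CountTrack,
    ExpressionTable,
    GeneModel,
    GenomeLayout,
    RegionSet,
)
from .segmentation import StateId, StatePanel

__all__ = [
    "PlantedBlock",
    "GeneSpec",
    "SyntheticSpec",
    "GroundTruthSegment",
    "reference_state_ids",
    "make_region_panel",
    "make_count_tracks",
    "make_genes_and_expression",
    "all_cep_spec",
    "cpg_transition_prob",
]


@dataclass
class PlantedBlock:
    """One genomic block with a target CEP and complementary coverage levels."""

    chrom: str
    start: int
    end: int
    bits: tuple[int, ...]
    coverage: dict[StateId, float] = field(default_factory=dict)


@dataclass
class GeneSpec:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    present: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticSpec:
    seed: int
    chrom_sizes: dict[str, int]
    marks: list[str]
    cells: list[str]
    mode: str = "ES"
    reference: str = ""
    blocks: list[PlantedBlock] = field(default_factory=list)
    background_rate: float = 3.0
    enrichment_factor: float = 10.0
    low_factor: float = 0.1
    min_segment_length: int = 200
    cpg_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    cpg_target: float = 0.06
    cpg_background: float = 0.005
    genes: list[GeneSpec] = field(default_factory=list)

    def __post_init__(self):
        if not self.reference:
            self.reference = self.cells[0] if self.mode == "ES" else self.marks[0]
        if self.background_rate <= 0 or self.enrichment_factor <= 0 or self.low_factor <= 0:
            raise ValidationError("read-depth rates must be > 0")
        layout = self.layout()
        n_ref = len(self.marks) if self.mode == "ES" else len(self.cells)
        by_chrom: dict[str, list[PlantedBlock]] = {}
        for block in self.blocks:
            layout.check_interval(block.chrom, block.start, block.end)
            if len(block.bits) != n_ref:
                raise ValidationError(
                    f"block bits {block.bits} should have {n_ref} entries"
                )
            for state_id, frac in block.coverage.items():
                if not 0 <= frac <= 1:
                    raise ValidationError(f"infeasible coverage fraction {frac} for {state_id}")
            by_chrom.setdefault(block.chrom, []).append(block)
        for chrom, blocks in by_chrom.items():
            blocks = sorted(blocks, key=lambda b: b.start)
            for a, b in zip(blocks, blocks[1:]):
                if b.start <= a.end:  # overlap or adjacency would merge states
                    raise ValidationError(
                        f"planted blocks overlap or touch on {chrom!r} near {b.start}"
                    )

    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chrom_sizes)


@dataclass
class GroundTruthSegment:
    chrom: str
    start: int
    end: int
    bits: tuple[int, ...]
    coverage: np.ndarray  # over complementary state ids, canonical order


def reference_state_ids(spec: SyntheticSpec) -> tuple[list[StateId], list[StateId]]:
    """Reference and complementary state ids in canonical panel order."""
    if spec.mode == "ES":
        ref = [(mark, spec.reference) for mark in spec.marks]
    else:
        ref = [(spec.reference, cell) for cell in spec.cells]
    ref_set = set(ref)
    comp = [
        (mark, cell)
        for mark in spec.marks
        for cell in spec.cells
        if (mark, cell) not in ref_set
    ]
    return ref, comp


def _planted_intervals(spec: SyntheticSpec) -> dict[StateId, dict[str, list[tuple[int, int]]]]:
    """Per state: the intervals planted by the blocks (full for reference bits,
    left-anchored sub-intervals realizing the coverage fraction for the rest)."""
    ref_ids, comp_ids = reference_state_ids(spec)
    out: dict[StateId, dict[str, list[tuple[int, int]]]] = {
        sid: {} for sid in ref_ids + comp_ids
    }
    for block in spec.blocks:
        for k, sid in enumerate(ref_ids):
            if block.bits[k]:
                out[sid].setdefault(block.chrom, []).append((block.start, block.end))
        for sid in comp_ids:
            frac = block.coverage.get(sid, 0.0)
            if frac > 0:
                sub_len = int(round(frac * (block.end - block.start)))
                if sub_len > 0:
                    out[sid].setdefault(block.chrom, []).append(
                        (block.start, block.start + sub_len)
                    )
    return out


def make_region_panel(spec: SyntheticSpec) -> tuple[StatePanel, list[GroundTruthSegment]]:
    """Build the StatePanel realizing the planted blocks plus its ground truth.

    The ground truth lists the segments a segmentation with the spec's mode,
    reference and minimum length must recover: planted blocks with a non-zero
    CEP become their own segments, everything between consecutive non-zero
    blocks (and the chromosome flanks) becomes an all-zero segment.
    """
    layout = spec.layout()
    planted = _planted_intervals(spec)
    ref_ids, comp_ids = reference_state_ids(spec)
    states = {
        sid: RegionSet(f"{sid[0]}:{sid[1]}", layout, ivs) for sid, ivs in planted.items()
    }
    panel = StatePanel(spec.marks, spec.cells, layout, states)

    truth: list[GroundTruthSegment] = []
    zero_bits = tuple(0 for _ in ref_ids)
    for chrom in layout:
        length = layout[chrom]
        marked = sorted(
            (b for b in spec.blocks if b.chrom == chrom and any(b.bits)),
            key=lambda b: b.start,
        )
        cuts = sorted({0, length} | {b.start for b in marked} | {b.end for b in marked})
        block_at = {(b.start, b.end): b for b in marked}
        for s, e in zip(cuts, cuts[1:]):
            if e - s < spec.min_segment_length:
                continue
            block = block_at.get((s, e))
            bits = block.bits if block is not None else zero_bits
            cov = np.zeros(len(comp_ids))
            for j, sid in enumerate(comp_ids):
                total = 0
                for ps, pe in planted[sid].get(chrom, []):
                    total += max(0, min(pe, e) - max(ps, s))
                cov[j] = total / (e - s)
            truth.append(GroundTruthSegment(chrom, s, e, tuple(bits), cov))
    return panel, truth


def make_count_tracks(
    spec: SyntheticSpec,
) -> tuple[dict[StateId, CountTrack], CountTrack]:
    """Poisson read counts per state plus a shared WCE control track.

    WCE counts are Poisson(background) at every position; modification counts
    are Poisson(background * enrichment_factor) inside the planted regions of
    the state and Poisson(background * low_factor) outside.
    """
    layout = spec.layout()
    rng = np.random.default_rng(spec.seed)
    planted = _planted_intervals(spec)
    ref_ids, comp_ids = reference_state_ids(spec)

    wce_data: dict[str, dict[int, int]] = {}
    for chrom in layout:
        counts = rng.poisson(spec.background_rate, layout[chrom])
        nz = np.flatnonzero(counts)
        if nz.size:
            wce_data[chrom] = dict(zip(nz.tolist(), counts[nz].tolist()))
    wce = CountTrack(layout, wce_data)

    tracks: dict[StateId, CountTrack] = {}
    for sid in ref_ids + comp_ids:
        data: dict[str, dict[int, int]] = {}
        for chrom in layout:
            length = layout[chrom]
            lam = np.full(length, spec.background_rate * spec.low_factor)
            for start, end in planted[sid].get(chrom, []):
                lam[start:end] = spec.background_rate * spec.enrichment_factor
            counts = rng.poisson(lam)
            nz = np.flatnonzero(counts)
            if nz.size:
                data[chrom] = dict(zip(nz.tolist(), counts[nz].tolist()))
        tracks[sid] = CountTrack(layout, data)
    return tracks, wce


def cpg_transition_prob(density: float) -> float:
    """P(G | previous base C) yielding the requested stationary CpG density.

    Derived from the stationary distribution of the first-order chain used by
    the genome generator: density = 0.25 * g / (1.25 - (1 - g) / 3).
    """
    if not 0 <= density < 0.25:
        raise ValidationError("target CpG density must be in [0, 0.25)")
    return density * (11.0 / 12.0) / (0.25 - density / 3.0)


def _markov_sequence(rng: np.random.Generator, length: int, g_prob: float) -> list[str]:
    """First-order chain: after a C, emit G with probability g_prob, otherwise
    uniform over A/C/T; after any other base, uniform over A/C/G/T."""
    bases = "ACGT"
    non_g = "ACT"
    u = rng.random(length)
    pick4 = rng.integers(0, 4, length)
    pick3 = rng.integers(0, 3, length)
    out = []
    prev = ""
    for i in range(length):
        if prev == "C":
            base = "G" if u[i] < g_prob else non_g[pick3[i]]
        else:
            base = bases[pick4[i]]
        out.append(base)
        prev = base
    return out


def make_genes_and_expression(
    spec: SyntheticSpec,
) -> tuple[list[GeneModel], ExpressionTable, dict[str, str]]:
    """Gene models with present/absent flags plus a genome sequence.

    The genome is CG-depleted background with elevated CG-dinucleotide
    frequency inside the spec's CpG-rich intervals (first-order Markov chain
    calibrated to the target density).
    """
    layout = spec.layout()
    rng = np.random.default_rng(spec.seed + 1)
    g_bg = cpg_transition_prob(spec.cpg_background)
    g_rich = cpg_transition_prob(spec.cpg_target)
    genome: dict[str, str] = {}
    for chrom in layout:
        length = layout[chrom]
        seq = _markov_sequence(rng, length, g_bg)
        for c, start, end in spec.cpg_intervals:
            if c != chrom:
                continue
            layout.check_interval(c, start, end)
            seq[start:end] = _markov_sequence(rng, end - start, g_rich)
        genome[chrom] = "".join(seq)

    genes: list[GeneModel] = []
    flags: dict[str, dict[str, int]] = {}
    for gs in spec.genes:
        layout.check_interval(gs.chrom, gs.start, gs.end)
        if gs.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {gs.strand!r} for gene {gs.gene_id}")
        genes.append(GeneModel(gs.gene_id, gs.chrom, [(gs.start, gs.end, gs.strand)]))
        flags[gs.gene_id] = {cell: int(gs.present.get(cell, 0)) for cell in spec.cells}
    expr = ExpressionTable(list(spec.cells), flags)
    return genes, expr, genome


def all_cep_spec(
    seed: int = 0,
    repeats: int = 1,
    block_len: int = 1000,
    gap: int = 500,
    marks: list[str] | None = None,
    cells: list[str] | None = None,
    mode: str = "ES",
    chrom: str = "chr1",
    with_coverage: bool = True,
    coverage_scale: float = 1.0,
) -> SyntheticSpec:
    """A spec planting every presence/absence combination of the 3 reference states.

    Blocks for all 2^3 CEPs (repeated ``repeats`` times) are laid out along one
    chromosome, separated by gaps; complementary coverage levels cycle through
    a fixed palette so profiles within one CEP still vary.
    """
    marks = marks or ["K4", "K27", "K9"]
    cells = cells or ["ESC", "MEF", "NPC"]
    reference = cells[0] if mode == "ES" else marks[0]
    n_ref = 3
    dummy = SyntheticSpec(
        seed=seed,
        chrom_sizes={chrom: 10},
        marks=marks,
        cells=cells,
        mode=mode,
        reference=reference,
    )
    _, comp_ids = reference_state_ids(dummy)
    palette = [0.0, 0.25, 0.5, 0.75, 1.0]
    blocks = []
    pos = gap
    idx = 0
    for _ in range(repeats):
        for combo in range(2**n_ref):
            bits = tuple((combo >> (n_ref - 1 - k)) & 1 for k in range(n_ref))
            cov = {}
            if with_coverage:
                for j, sid in enumerate(comp_ids):
                    cov[sid] = coverage_scale * palette[(idx + j) % len(palette)]
            blocks.append(PlantedBlock(chrom, pos, pos + block_len, bits, cov))
            pos += block_len + gap
            idx += 1
    return SyntheticSpec(
        seed=seed,
        chrom_sizes={chrom: pos + gap},
        marks=marks,
        cells=cells,
        mode=mode,
        reference=reference,
        blocks=blocks,
    )


def demo_spec(seed: int = 0, repeats: int = 2) -> SyntheticSpec:
    """An all-CEP spec enriched with CpG-rich intervals and genes.

    Blocks whose first reference bit is set get a CpG-rich interval; every
    block hosts one gene, present in all cell types when the block carries
    only the first reference mark (the activating one), absent otherwise.
    """
    import dataclasses

    spec = all_cep_spec(seed=seed, repeats=repeats)
    ref_ids, _ = reference_state_ids(spec)
    cpg_intervals = []
    genes = []
    for i, block in enumerate(spec.blocks):
        if block.bits[0]:
            cpg_intervals.append((block.chrom, block.start, block.end))
        strand = "+" if i % 2 == 0 else "-"
        margin = (block.end - block.start) // 4
        present_all = block.bits == (1, 0, 0)
        genes.append(
            GeneSpec(
                gene_id=f"g{i:03d}",
                chrom=block.chrom,
                start=block.start + margin,
                end=block.end - margin,
                strand=strand,
                present={cell: int(present_all) for cell in spec.cells},
            )
        )
    return dataclasses.replace(spec, cpg_intervals=cpg_intervals, genes=genes)


def write_fixtures(spec: SyntheticSpec, outdir) -> dict:
    """Emit every pipeline input as plain-text files; returns the file map.

    Writes chromosome sizes, per-state region BEDs and count bedGraphs, the
    WCE control, genome FASTA, gene models (BED6), the expression table, a
    gene-set list, the ground-truth segment table and a ready-to-run
    pipeline configuration.
    """
    import json
    from pathlib import Path

    from .format_io import write_count_track, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = spec.layout()
    panel, truth = make_region_panel(spec)
    tracks, wce = make_count_tracks(spec)
    genes, expr, genome = make_genes_and_expression(spec)

    files: dict[str, str] = {}
    sizes = outdir / "chrom_sizes.tsv"
    layout.to_tsv(sizes)
    files["chrom_sizes"] = str(sizes)

    panel_entries = []
    for (mark, cell), rs in panel.states.items():
        bed = outdir / f"regions_{mark}_{cell}.bed"
        rs.write_bed(bed)
        bg = outdir / f"counts_{mark}_{cell}.bedGraph"
        write_count_track(tracks[(mark, cell)], bg)
        panel_entries.append(
            {"mark": mark, "cell": cell, "bed": str(bed), "mod_bedgraph": str(bg)}
        )
    wce_path = outdir / "wce.bedGraph"
    write_count_track(wce, wce_path)
    files["wce"] = str(wce_path)

    fasta = outdir / "genome.fa"
    write_fasta(genome, fasta)
    files["genome"] = str(fasta)

    genes_path = outdir / "genes.bed"
    with open(genes_path, "w") as fh:
        for gene in genes:
            for start, end, strand in gene.transcripts:
                fh.write(f"{gene.chrom}\t{start}\t{end}\t{gene.gene_id}\t0\t{strand}\n")
    files["genes"] = str(genes_path)

    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(expr.cell_types) + "\n")
        for gene_id, flags in expr.flags.items():
            fh.write(gene_id + "\t" + "\t".join(str(flags[c]) for c in expr.cell_types) + "\n")
    files["expression"] = str(expr_path)

    gene_set_path = outdir / "gene_set.txt"
    with open(gene_set_path, "w") as fh:
        for gene in genes[::2]:
            fh.write(gene.gene_id + "\n")
    files["gene_set"] = str(gene_set_path)

    truth_path = outdir / "ground_truth.tsv"
    _, comp_ids = reference_state_ids(spec)
    with open(truth_path, "w") as fh:
        cols = "\t".join(f"{m}:{c}" for m, c in comp_ids)
        fh.write(f"chrom\tstart\tend\tcep\t{cols}\n")
        for gt in truth:
            bits = "".join(str(b) for b in gt.bits)
            cov = "\t".join(repr(float(v)) for v in gt.coverage)
            fh.write(f"{gt.chrom}\t{gt.start}\t{gt.end}\t{bits}\t{cov}\n")
    files["ground_truth"] = str(truth_path)

    config = {
        "seed": spec.seed,
        "chrom_sizes": str(sizes),
        "panel": [{k: v for k, v in e.items() if k != "mod_bedgraph"} for e in panel_entries],
        "mode": spec.mode,
        "reference": spec.reference,
        "min_segment_length": spec.min_segment_length,
        "maps": {
            "genome_fasta": str(fasta),
            "genes": str(genes_path),
            "genes_format": "bed12",
            "expression": str(expr_path),
            "gene_set": str(gene_set_path),
        },
    }
    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(config, indent=2) + "\n")
    files["config"] = str(config_path)
    return files
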