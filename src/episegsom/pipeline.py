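"""End-to-end pipeline driver: discretize -> segment -> train -> maps -> render.

The pipeline is configured by a single JSON/YAML mapping; every stage writes
plain-text outputs (TSV/BED) plus a manifest with the resolved configuration
and a content hash so a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .discretize import DiscretizationConfig, discretize_track
from .errors import ValidationError
from .format_io import (
    read_chrom_sizes,
    read_count_track,
    read_expression,
    read_fasta,
    read_gene_models,
    read_regions,
    write_node_matrix,
)
from .segmentation import (
    SegmentationConfig,
    StatePanel,
    segment_genome,
    write_profiles_tsv,
    write_segments_bed,
)
from .som_core import TrainingSchedule, default_schedule, linear_initialize, train
from .som_maps import (
    NodeMap,
    chromosome_maps,
    coverage_atlas,
    cpg_density_map,
    gene_set_fraction_map,
    island_labeling,
    population_map,
    present_call_map,
    segment_length_map,
)
from .viz import RenderSpec, render_heatmap

logger = logging.getLogger(__name__)

DEFAULTS = {
    "mode": "ES",
    "min_segment_length": 200,
    "coverage_weight": 1.0,
    "discretize": {
        "threshold": 3.0,
        "max_gap": 100,
        "min_len": 100,
        "wce_zero_policy": "exclude",
        "pseudocount": 1.0,
    },
    "som": {"width": 40, "height": 40, "epochs": None, "alpha": [0.05, 0.005], "sigma": None},
    "maps": {"islands_threshold": 10, "extension": 2000, "active_threshold": 1.0},
    "render": True,
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _resolve(config: dict) -> dict:
    resolved = json.loads(json.dumps(DEFAULTS))
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(resolved.get(key), dict):
            resolved[key].update(value)
        else:
            resolved[key] = value
    return resolved


def _save_map(node_map: NodeMap, outdir: Path, name: str, render: bool, islands=None) -> None:
    write_node_matrix(node_map, outdir / f"{name}.tsv")
    meta = {
        "label": node_map.label,
        "shape": list(node_map.shape),
        "scale": node_map.scale,
        "inverted": node_map.inverted,
        "masked_nodes": int(node_map.mask.sum()),
    }
    (outdir / f"{name}.json").write_text(json.dumps(meta, indent=2) + "\n")
    if render:
        render_heatmap(node_map, RenderSpec.for_map(node_map), outdir / f"{name}.png", islands)


def run_pipeline(config: dict | str | Path, outdir) -> Path:
    """Execute the configured pipeline and write all outputs under ``outdir``."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _resolve(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "configuration"
    try:
        layout = read_chrom_sizes(cfg["chrom_sizes"])
        dcfg = DiscretizationConfig(
            enrichment_threshold=cfg["discretize"]["threshold"],
            max_join_gap=cfg["discretize"]["max_gap"],
            min_region_length=cfg["discretize"]["min_len"],
            wce_zero_policy=cfg["discretize"]["wce_zero_policy"],
            pseudocount=cfg["discretize"]["pseudocount"],
        )

        stage = "discretize"
        marks: list[str] = []
        cells: list[str] = []
        states = {}
        for entry in cfg["panel"]:
            mark, cell = entry["mark"], entry["cell"]
            if mark not in marks:
                marks.append(mark)
            if cell not in cells:
                cells.append(cell)
            label = f"{mark}:{cell}"
            if "bed" in entry:
                states[(mark, cell)] = read_regions(entry["bed"], layout, label)
            elif "mod_bedgraph" in entry:
                mod = read_count_track(entry["mod_bedgraph"], layout)
                wce = read_count_track(entry["wce_bedgraph"], layout)
                h3 = (
                    read_count_track(entry["h3_bedgraph"], layout)
                    if entry.get("h3_bedgraph")
                    else None
                )
                states[(mark, cell)] = discretize_track(mod, wce, h3, dcfg, label)
            else:
                raise ValidationError(
                    f"panel entry for ({mark}, {cell}) needs 'bed' or 'mod_bedgraph'"
                )
        panel = StatePanel(marks, cells, layout, states)

        stage = "segment"
        scfg = SegmentationConfig(
            mode=cfg["mode"],
            reference=cfg["reference"],
            min_segment_length=cfg["min_segment_length"],
            coverage_weight=cfg["coverage_weight"],
        )
        result = segment_genome(panel, scfg)
        if not result.segments:
            raise ValidationError("segmentation produced no retained segments")
        write_segments_bed(result, outdir / "segments.bed")
        write_profiles_tsv(result, outdir / "profiles.tsv")
        with open(outdir / "discarded.bed", "w") as fh:
            for chrom, start, end in result.discarded:
                fh.write(f"{chrom}\t{start}\t{end}\n")

        stage = "train"
        som_cfg = cfg["som"]
        width, height = som_cfg["width"], som_cfg["height"]
        if som_cfg.get("epochs"):
            sigma = som_cfg.get("sigma") or [max(1.0, width / 4), 1.0]
            schedule = TrainingSchedule(
                epochs=int(som_cfg["epochs"]),
                alpha_start=som_cfg["alpha"][0],
                alpha_end=som_cfg["alpha"][1],
                sigma_start=sigma[0],
                sigma_end=sigma[1],
            )
        else:
            schedule = default_schedule(len(result.segments), width)
        grid = linear_initialize(result.profiles, (width, height))
        grid, assignment = train(result.profiles, grid, schedule)
        shape = (height, width)
        _write_som(grid, result, outdir / "som.tsv")
        _write_assignment(assignment, result, outdir / "assignment.tsv")

        stage = "maps"
        mcfg = cfg["maps"]
        render = bool(cfg["render"])
        islands = island_labeling(
            assignment, result.cep_labels(), shape, mcfg["islands_threshold"]
        )
        (outdir / "islands.json").write_text(
            json.dumps(
                {
                    "labels": {str(k): v for k, v in islands.labels.items()},
                    "sizes": {str(k): v for k, v in islands.sizes.items()},
                    "node_island": islands.node_island.tolist(),
                },
                indent=2,
            )
            + "\n"
        )
        _save_map(population_map(assignment, shape), outdir, "population", render, islands)
        for sid, amap in coverage_atlas(assignment, result, shape).items():
            _save_map(amap, outdir, f"atlas_{sid[0]}_{sid[1]}", render, islands)
        _save_map(segment_length_map(assignment, result.segments, shape), outdir, "length", render)
        if mcfg.get("genome_fasta"):
            genome = read_fasta(mcfg["genome_fasta"])
            _save_map(
                cpg_density_map(assignment, result.segments, genome, shape),
                outdir,
                "cpg_density",
                render,
            )
        genes = None
        if mcfg.get("genes"):
            genes = read_gene_models(mcfg["genes"], layout, mcfg.get("genes_format", "bed12"))
        if genes and mcfg.get("expression"):
            expr = read_expression(mcfg["expression"])
            _save_map(
                present_call_map(
                    assignment,
                    result.segments,
                    genes,
                    expr,
                    layout,
                    shape,
                    mcfg["extension"],
                    mcfg["active_threshold"],
                ),
                outdir,
                "present_call",
                render,
            )
        if genes and mcfg.get("gene_set"):
            gene_set = {
                line.strip()
                for line in Path(mcfg["gene_set"]).read_text().splitlines()
                if line.strip()
            }
            _save_map(
                gene_set_fraction_map(
                    assignment, result.segments, genes, gene_set, layout, shape,
                    mcfg["extension"],
                ),
                outdir,
                "gene_set",
                render,
            )
        for chrom in layout:
            if any(seg.chrom == chrom for seg in result.segments):
                pop, enr = chromosome_maps(assignment, result.segments, chrom, shape)
                _save_map(pop, outdir, f"chrom_population_{chrom}", render)
                _save_map(enr, outdir, f"chrom_enrichment_{chrom}", render)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    resolved_text = json.dumps(cfg, indent=2, sort_keys=True)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(resolved_text.encode()).hexdigest(),
        "n_segments": len(result.segments),
        "n_discarded": len(result.discarded),
        "grid": [height, width],
        "epochs": schedule.epochs,
    }
    (outdir / "config.resolved.json").write_text(resolved_text + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %d segments, outputs in %s", len(result.segments), outdir)
    return outdir


def _write_som(grid, result, path) -> None:
    cols = [f"{m}:{c}" for m, c in result.state_order]
    with open(path, "w") as fh:
        fh.write("row\tcol\t" + "\t".join(cols) + "\n")
        coords = grid.coords()
        for k in range(grid.n_nodes):
            vals = "\t".join(repr(float(v)) for v in grid.weights[k])
            fh.write(f"{coords[k, 0]}\t{coords[k, 1]}\t{vals}\n")


def _write_assignment(assignment: np.ndarray, result, path) -> None:
    with open(path, "w") as fh:
        fh.write("segment\tchrom\tstart\tend\tnode\n")
        for i, (seg, node) in enumerate(zip(result.segments, assignment)):
            fh.write(f"{i}\t{seg.chrom}\t{seg.start}\t{seg.end}\t{int(node)}\n")
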